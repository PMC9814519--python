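"""Periodic-boundary geometry primitives.

All routines assume orthorhombic boxes with lengths in nm. Vectors may be
single 3-vectors or ``(..., 3)`` arrays; broadcasting follows numpy rules.
"""

from __future__ import annotations

import numpy as np


def minimum_image(v: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Map displacement(s) ``v`` into the primary image of an orthorhombic box.

    Each component of the result lies in ``(-L/2, L/2]`` and is congruent to
    the input modulo the box length.

    Parameters
    ----------
    v : array_like, shape (..., 3)
        Displacement vector(s) in nm.
    box : array_like, shape (3,)
        Box edge lengths in nm, all > 0.
    """
    v = np.asarray(v, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError(f"box lengths must be positive, got {box}")
    r = v - box * np.round(v / box)
    # round() leaves -L/2 in place; fold it onto +L/2 so the interval is (-L/2, L/2]
    low = r <= -box / 2.0
    if np.any(low):
        r = np.where(low, r + box, r)
    return r


def wrap_positions(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap absolute positions into ``[0, L)`` per component."""
    box = np.asarray(box, dtype=float)
    w = coords - box * np.floor(coords / box)
    # guard against w == L from floating-point roundoff
    return np.where(w >= box, w - box, w)


def make_whole(coords: np.ndarray, groups, box: np.ndarray) -> np.ndarray:
    """Unwrap each molecule about its first atom so no bond crosses the box.

    ``groups`` is an iterable of integer index arrays, one per molecule. Atoms
    not covered by any group are left untouched. Valid for molecules smaller
    than half the box in every dimension.
    """
    out = np.array(coords, dtype=float, copy=True)
    for g in groups:
        g = np.asarray(g)
        if g.size < 2:
            continue
        ref = out[g[0]]
        out[g] = ref + minimum_image(out[g] - ref, box)
    return out


def angle_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Angle between vectors in degrees, in [0, 180]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.einsum("...i,...i->...", v1, v2) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
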