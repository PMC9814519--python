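"""Lipid headgroup orientation, membrane thickness maps and tail order.

Two angles characterise headgroup response to an adsorbed nanoparticle:

* alpha — the angle between a lipid's P->N headgroup vector and the outward
  bilayer normal of its leaflet (+Z for the upper leaflet, -Z for the
  lower). An unperturbed phosphatidylcholine membrane sits near 67 degrees.
* beta — the angle between the XY projections of (nanoparticle COM -> P)
  and (P -> N). Random headgroup azimuths give a mean of 90 degrees; values
  below 90 mean the choline nitrogen points away from the nanoparticle.

Both angles are accumulated on an XY grid (cell of the lipid's P site) to
map deformations around the binding spot, alongside a phosphate-to-phosphate
thickness map and the tail segment order parameter
S = <(3 cos^2 theta - 1) / 2>.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import angle_deg, minimum_image
from .io import Frame, Trajectory
from .monolayer import core_com
from .results import MapResult
from .system import AnnotatedSystem

_MIN_XY = 1e-6  # nm; shorter XY projections leave beta undefined


def leaflet_assignment(system: AnnotatedSystem, frame: Frame, tolerance: float = 0.3):
    """Per-lipid leaflet labels from the sign of z_P minus the midplane.

    The midplane is the mean phosphate z over both leaflets in this frame.
    Lipids within ``tolerance`` of the midplane are labelled ``"mid"``.
    Returns (labels array, midplane z).
    """
    if not system.lipids:
        raise ValueError("system has no lipids")
    z = frame.coordinates[system.lipid_p_sites][:, 2]
    mid = float(z.mean())
    labels = np.where(z > mid, "upper", "lower").astype(object)
    labels[np.abs(z - mid) < tolerance] = "mid"
    return labels, mid


def alpha_angle(system: AnnotatedSystem, lipid_index: int, frame: Frame, leaflet: str) -> float:
    """Headgroup tilt of one lipid relative to its outward leaflet normal."""
    lp = system.lipids[lipid_index]
    v = minimum_image(frame.coordinates[lp.n_site] - frame.coordinates[lp.p_site], frame.box)
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError(f"degenerate lipid {lp.resid}: coincident P and N sites")
    n_hat = np.array([0.0, 0.0, 1.0 if leaflet == "upper" else -1.0])
    return float(angle_deg(v, n_hat))


def beta_angle(system: AnnotatedSystem, lipid_index: int, frame: Frame, np_com) -> float | None:
    """In-plane headgroup orientation of one lipid relative to the NP COM.

    Returns None when either XY projection is too short to define an angle.
    """
    lp = system.lipids[lipid_index]
    coords = frame.coordinates
    v1 = minimum_image(coords[lp.p_site] - np.asarray(np_com, dtype=float), frame.box)[:2]
    v2 = minimum_image(coords[lp.n_site] - coords[lp.p_site], frame.box)[:2]
    if np.linalg.norm(v1) < _MIN_XY or np.linalg.norm(v2) < _MIN_XY:
        return None
    return float(angle_deg(v1, v2))


def _alpha_all(system: AnnotatedSystem, frame: Frame, labels) -> np.ndarray:
    p = frame.coordinates[system.lipid_p_sites]
    n = frame.coordinates[system.lipid_n_sites]
    v = minimum_image(n - p, frame.box)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-9):
        bad = system.lipids[int(np.argmin(norms))].resid
        raise ValueError(f"degenerate lipid {bad}: coincident P and N sites")
    sign = np.where(labels == "lower", -1.0, 1.0)
    cosa = np.clip(sign * v[:, 2] / norms, -1.0, 1.0)
    return np.degrees(np.arccos(cosa))


def _beta_all(system: AnnotatedSystem, frame: Frame, np_com) -> np.ndarray:
    coords = frame.coordinates
    p = coords[system.lipid_p_sites]
    n = coords[system.lipid_n_sites]
    v1 = minimum_image(p - np.asarray(np_com, dtype=float), frame.box)[:, :2]
    v2 = minimum_image(n - p, frame.box)[:, :2]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    out = np.full(len(p), np.nan)
    ok = (n1 >= _MIN_XY) & (n2 >= _MIN_XY)
    cosb = np.clip(np.einsum("ij,ij->i", v1[ok], v2[ok]) / (n1[ok] * n2[ok]), -1.0, 1.0)
    out[ok] = np.degrees(np.arccos(cosb))
    return out


@dataclass
class _Grid:
    x_edges: np.ndarray
    y_edges: np.ndarray

    @classmethod
    def for_box(cls, box, shape):
        nx, ny = shape
        return cls(np.linspace(0.0, box[0], nx + 1), np.linspace(0.0, box[1], ny + 1))

    def cell_of(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ix = np.clip(np.searchsorted(self.x_edges, xy[:, 0], side="right") - 1, 0, len(self.x_edges) - 2)
        iy = np.clip(np.searchsorted(self.y_edges, xy[:, 1], side="right") - 1, 0, len(self.y_edges) - 2)
        return ix, iy


def _np_com_xy(system: AnnotatedSystem, frame: Frame):
    if system.core_atoms.size == 0:
        return None
    return core_com(system, frame)


def _contact_split(grid: _Grid, values, counts, np_xy, contact_radius, box):
    if np_xy is None:
        return None, None
    xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
    yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    dx = gx - np_xy[0]
    dy = gy - np_xy[1]
    dx -= box[0] * np.round(dx / box[0])
    dy -= box[1] * np.round(dy / box[1])
    near = np.hypot(dx, dy) <= contact_radius
    good = counts > 0
    def wmean(mask):
        m = mask & good
        if not m.any():
            return None
        return float(np.sum(values[m] * counts[m]) / np.sum(counts[m]))
    return wmean(near), wmean(~near)


def angle_map(
    system: AnnotatedSystem,
    trajectory: Trajectory,
    quantity: str = "alpha",
    grid_shape: tuple[int, int] = (26, 26),
    window: slice | None = None,
    contact_radius: float = 2.5,
    leaflet: str | None = None,
) -> MapResult:
    """XY map of per-lipid alpha or beta angles over a frame window.

    Angles are accumulated into the grid cell of each lipid's P site; the
    per-cell value is the mean over all lipid-frames. The contact-region
    summary compares cells within ``contact_radius`` of the nanoparticle COM
    projection against the far field.
    """
    if quantity not in ("alpha", "beta"):
        raise ValueError("quantity must be 'alpha' or 'beta'")
    window = window if window is not None else slice(None)
    frames = range(*window.indices(trajectory.n_frames))
    if len(frames) == 0:
        raise ValueError("empty window")
    grid = _Grid.for_box(trajectory.boxes[frames[0]], grid_shape)
    sums = np.zeros(grid_shape)
    counts = np.zeros(grid_shape, dtype=int)
    np_xy = None
    for f in frames:
        frame = trajectory[f]
        labels, _ = leaflet_assignment(system, frame)
        if leaflet is not None:
            keep = labels == leaflet
        else:
            keep = labels != "mid"
        if quantity == "alpha":
            vals = _alpha_all(system, frame, labels)
        else:
            com = _np_com_xy(system, frame)
            if com is None:
                raise ValueError("beta maps require a nanoparticle in the system")
            np_xy = com[:2]
            vals = _beta_all(system, frame, com)
        keep = keep & np.isfinite(vals)
        p_xy = frame.coordinates[system.lipid_p_sites][:, :2]
        ix, iy = grid.cell_of(p_xy[keep])
        np.add.at(sums, (ix, iy), vals[keep])
        np.add.at(counts, (ix, iy), 1)
    values = np.full(grid_shape, np.nan)
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]
    box = trajectory.boxes[frames[0]]
    contact, far = _contact_split(grid, values, counts, np_xy, contact_radius, box)
    t0, t1 = float(trajectory.times[frames[0]]), float(trajectory.times[frames[-1]])
    return MapResult(
        x_edges=grid.x_edges,
        y_edges=grid.y_edges,
        values=values,
        counts=counts,
        quantity=quantity,
        window=(t0, t1),
        contact_mean=contact,
        farfield_mean=far,
        np_com_xy=tuple(np_xy) if np_xy is not None else None,
    )


def thickness_map(
    system: AnnotatedSystem,
    trajectory: Trajectory,
    grid_shape: tuple[int, int] = (26, 26),
    window: slice | None = None,
    contact_radius: float = 2.5,
) -> MapResult:
    """Phosphate-to-phosphate membrane thickness per XY grid cell.

    Per frame and cell, thickness is the mean upper-leaflet P z minus the
    mean lower-leaflet P z; cells represented by only one leaflet in a frame
    contribute nothing for that frame. Note the measure is a z-distance: a
    rigidly tilted membrane keeps its cell values unchanged only for the
    true (normal-projected) thickness, while this P-to-P z-distance grows
    with tilt — see the package docs.
    """
    window = window if window is not None else slice(None)
    frames = range(*window.indices(trajectory.n_frames))
    if len(frames) == 0:
        raise ValueError("empty window")
    grid = _Grid.for_box(trajectory.boxes[frames[0]], grid_shape)
    sums = np.zeros(grid_shape)
    counts = np.zeros(grid_shape, dtype=int)
    np_xy = None
    for f in frames:
        frame = trajectory[f]
        labels, _ = leaflet_assignment(system, frame)
        p = frame.coordinates[system.lipid_p_sites]
        ix, iy = grid.cell_of(p[:, :2])
        zsum = {"upper": np.zeros(grid_shape), "lower": np.zeros(grid_shape)}
        zcnt = {"upper": np.zeros(grid_shape, dtype=int), "lower": np.zeros(grid_shape, dtype=int)}
        for name in ("upper", "lower"):
            m = labels == name
            np.add.at(zsum[name], (ix[m], iy[m]), p[m, 2])
            np.add.at(zcnt[name], (ix[m], iy[m]), 1)
        both = (zcnt["upper"] > 0) & (zcnt["lower"] > 0)
        thick = np.zeros(grid_shape)
        thick[both] = zsum["upper"][both] / zcnt["upper"][both] - zsum["lower"][both] / zcnt["lower"][both]
        sums[both] += thick[both]
        counts[both] += 1
        if system.core_atoms.size:
            np_xy = core_com(system, frame)[:2]
    values = np.full(grid_shape, np.nan)
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]
    box = trajectory.boxes[frames[0]]
    contact, far = _contact_split(grid, values, counts, np_xy, contact_radius, box)
    t0, t1 = float(trajectory.times[frames[0]]), float(trajectory.times[frames[-1]])
    return MapResult(
        x_edges=grid.x_edges,
        y_edges=grid.y_edges,
        values=values,
        counts=counts,
        quantity="thickness",
        window=(t0, t1),
        contact_mean=contact,
        farfield_mean=far,
        np_com_xy=tuple(np_xy) if np_xy is not None else None,
    )


def order_parameter(
    system: AnnotatedSystem,
    trajectory: Trajectory,
    chain: str = "all",
    window: slice | None = None,
) -> np.ndarray:
    """Tail segment order parameter per carbon position.

    For tail bead i (excluding the chain ends) the segment vector is
    C_{i-1} -> C_{i+1} and S_i = <(3 cos^2 theta_i - 1)/2> with theta_i
    measured against the bilayer normal (z). Chains shorter than three beads
    are skipped. ``chain`` selects tail 0, 1, ... or ``"all"``.
    """
    window = window if window is not None else slice(None)
    frames = range(*window.indices(trajectory.n_frames))
    if len(frames) == 0:
        raise ValueError("empty window")
    max_len = 0
    for lp in system.lipids:
        for t in lp.tails:
            max_len = max(max_len, len(t))
    if max_len < 3:
        raise ValueError("no tail chain with >= 3 beads")
    sums = np.zeros(max_len - 2)
    counts = np.zeros(max_len - 2, dtype=int)
    which = None if chain == "all" else int(chain)
    for f in frames:
        frame = trajectory[f]
        coords = frame.coordinates
        for lp in system.lipids:
            tails = lp.tails if which is None else lp.tails[which : which + 1]
            for t in tails:
                if len(t) < 3:
                    continue
                pos = coords[list(t)]
                seg = minimum_image(pos[2:] - pos[:-2], frame.box)
                cost = seg[:, 2] / np.linalg.norm(seg, axis=1)
                s = 0.5 * (3.0 * cost**2 - 1.0)
                sums[: len(s)] += s
                counts[: len(s)] += 1
    out = np.full(max_len - 2, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out
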