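"""Ligand-shell statistics of the nanoparticle monolayer.

Covers the headgroup radial distribution about the gold-core centre of mass,
classification of coiled (folded-back) ligands, polar angular number-density
maps relative to a uniform spherical distribution, and shell occupancy
counts of monolayer-embedded species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import minimum_image
from .io import Frame, Trajectory
from .results import PolarDensityMap, ProfileResult, block_std
from .system import AnnotatedSystem


def core_com(
    system: AnnotatedSystem, frame: Frame, mass_weighted: bool = False, masses=None
) -> np.ndarray:
    """Centre of mass of the gold core, made whole across the box first.

    Pseudo-gold atoms all share one mass, so the default is the unweighted
    mean; pass ``masses`` (per-atom, full length) with ``mass_weighted`` for
    the general case.
    """
    idx = system.core_atoms
    if idx.size == 0:
        raise ValueError("system has no core atoms")
    coords = frame.coordinates
    ref = coords[idx[0]]
    local = ref + minimum_image(coords[idx] - ref, frame.box)
    if mass_weighted and masses is not None:
        w = np.asarray(masses, dtype=float)[idx]
        return np.average(local, axis=0, weights=w)
    return local.mean(axis=0)


def _head_distances(system: AnnotatedSystem, frame: Frame, atoms: np.ndarray) -> np.ndarray:
    com = core_com(system, frame)
    d = minimum_image(frame.coordinates[atoms] - com, frame.box)
    return np.linalg.norm(d, axis=1)


def headgroup_rdf(
    system: AnnotatedSystem,
    trajectory: Trajectory,
    bin_width: float = 0.05,
    r_max: float = 3.0,
    block_frames: int = 10,
    normalization: str = "density",
) -> ProfileResult:
    """Radial distribution of headgroup representatives about the core COM.

    With ``normalization="density"`` the profile is the mean number density
    n(r) / (4 pi r^2 dr) in nm^-3; ``"count"`` returns the raw mean per-bin
    count. Peak positions are identical for both. Per frame the binned counts
    sum to the number of ligands (mass conservation).
    """
    if trajectory.n_frames < 1:
        raise ValueError("need at least one frame")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    heads = system.head_reps
    if heads.size == 0:
        raise ValueError("system has no headgroups")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    per_frame = np.empty((trajectory.n_frames, len(edges) - 1))
    for f, frame in enumerate(trajectory):
        r = _head_distances(system, frame, heads)
        per_frame[f], _ = np.histogram(r, bins=edges)
    if normalization == "density":
        r_mid = 0.5 * (edges[:-1] + edges[1:])
        shell = 4.0 * np.pi * r_mid**2 * bin_width
        per_frame = per_frame / shell
        units = "nm^-3"
    elif normalization == "count":
        units = "counts"
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    values = per_frame.mean(axis=0)
    unc = np.asarray([block_std(per_frame[:, i], block_frames) for i in range(per_frame.shape[1])])
    return ProfileResult(
        bin_edges=edges,
        values=values,
        uncertainty=unc,
        n_frames=trajectory.n_frames,
        quantity="headgroup_rdf",
        units=units,
    )


@dataclass
class CoiledResult:
    """Per-frame coiled-ligand counts and the overall coiled fraction."""

    counts: np.ndarray  # per frame
    times: np.ndarray
    n_ligands: int
    r_threshold: float

    @property
    def fraction(self) -> float:
        """Coiled ligand-frames over total ligand-frames."""
        return float(self.counts.sum() / (self.n_ligands * len(self.counts)))


def classify_coiled(
    system: AnnotatedSystem, trajectory: Trajectory, r_threshold: float = 1.55
) -> CoiledResult:
    """Count ligands whose headgroup fell below ``r_threshold`` from the core
    COM — the folded-back ("coiled") conformation embedded in the monolayer.

    The default threshold 1.55 nm is the midpoint between the coiled
    (1.3 nm) and extended (1.8 nm) shell radii of the guanidinium monolayer.
    """
    heads = system.head_reps
    frame0 = trajectory[0]
    com0 = core_com(system, frame0)
    core_r = float(
        np.max(np.linalg.norm(minimum_image(frame0.coordinates[system.core_atoms] - com0, frame0.box), axis=1))
    )
    if r_threshold <= core_r:
        warnings.warn(
            f"coiled threshold {r_threshold} nm is inside the core (radius ~{core_r:.2f} nm); "
            "no ligand can be classified as coiled"
        )
    counts = np.empty(trajectory.n_frames, dtype=int)
    for f, frame in enumerate(trajectory):
        counts[f] = int(np.sum(_head_distances(system, frame, heads) < r_threshold))
    return CoiledResult(
        counts=counts, times=trajectory.times.copy(), n_ligands=len(heads), r_threshold=r_threshold
    )


_COMPONENT_ATOMS = {
    "headgroup": lambda s: s.head_reps,
    "counterion": lambda s: s.counterions,
    "water": lambda s: np.asarray(s.acceptors.get("water", s.waters)),
}


def _component_atoms(system: AnnotatedSystem, component: str) -> np.ndarray:
    try:
        atoms = _COMPONENT_ATOMS[component](system)
    except KeyError:
        raise ValueError(f"unknown component {component!r}") from None
    return np.asarray(atoms, dtype=int)


def _polar_axis(system: AnnotatedSystem, frame: Frame, axis) -> np.ndarray:
    """Unit axis from which the polar angle is measured.

    The convention puts the monolayer region facing the membrane at 180°
    ("south"): the axis points from the membrane COM towards the core COM.
    Without a membrane the box +Z axis is used.
    """
    if isinstance(axis, (list, tuple, np.ndarray)):
        a = np.asarray(axis, dtype=float)
        return a / np.linalg.norm(a)
    if axis != "auto":
        raise ValueError(f"unknown axis convention {axis!r}")
    if system.lipids:
        p_sites = system.lipid_p_sites
        mem_com = frame.coordinates[p_sites].mean(axis=0)
        v = minimum_image(core_com(system, frame) - mem_com, frame.box)
        return v / np.linalg.norm(v)
    return np.asarray([0.0, 0.0, 1.0])


def polar_density(
    system: AnnotatedSystem,
    trajectory: Trajectory,
    component: str = "headgroup",
    shell: tuple[float, float] = (0.9, 2.2),
    n_bins: int = 18,
    axis="auto",
    block_frames: int = 10,
) -> PolarDensityMap:
    """Angular number density of a monolayer component relative to uniform.

    For polar bin i the reported ratio is ``(count_i / total) / (dOmega_i /
    4 pi)`` with ``dOmega_i = 2 pi (cos theta_i - cos theta_{i+1})``; a ratio
    of 1 in every bin means a perfectly homogeneous spherical distribution.
    Only atoms whose distance from the core COM lies in ``[r_in, r_out)``
    are counted.
    """
    r_in, r_out = shell
    if not (r_out > r_in > 0):
        raise ValueError("need r_out > r_in > 0")
    atoms = _component_atoms(system, component)
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    domega = 2.0 * np.pi * (np.cos(np.radians(edges[:-1])) - np.cos(np.radians(edges[1:])))
    counts_pf = np.zeros((trajectory.n_frames, n_bins))
    for f, frame in enumerate(trajectory):
        com = core_com(system, frame)
        ax = _polar_axis(system, frame, axis)
        d = minimum_image(frame.coordinates[atoms] - com, frame.box)
        r = np.linalg.norm(d, axis=1)
        sel = (r >= r_in) & (r < r_out)
        if not sel.any():
            continue
        cost = np.clip(d[sel] @ ax / r[sel], -1.0, 1.0)
        theta = np.degrees(np.arccos(cost))
        counts_pf[f], _ = np.histogram(theta, bins=edges)
    total = counts_pf.sum()
    if total == 0:
        raise ValueError(f"no {component} atoms found in shell [{r_in}, {r_out}) in any frame")
    counts = counts_pf.sum(axis=0)
    ratio = (counts / total) / (domega / (4.0 * np.pi))
    # per-frame ratios for block uncertainties (frames with an empty shell
    # contribute zero counts)
    frame_tot = counts_pf.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio_pf = np.where(frame_tot > 0, (counts_pf / frame_tot) / (domega / (4.0 * np.pi)), 0.0)
    unc = np.asarray([block_std(ratio_pf[:, i], block_frames) for i in range(n_bins)])
    return PolarDensityMap(
        bin_edges=edges,
        values=ratio,
        uncertainty=unc,
        n_frames=trajectory.n_frames,
        quantity="polar_density_ratio",
        units="",
        component=component,
        shell=(r_in, r_out),
        counts=counts,
    )


@dataclass
class OccupancyResult:
    """Per-frame shell occupancy of one component."""

    counts: np.ndarray
    times: np.ndarray
    component: str
    shell: tuple[float, float]
    mean: float
    std: float


def shell_occupancy(
    system: AnnotatedSystem,
    trajectory: Trajectory,
    component: str,
    shell: tuple[float, float] = (0.9, 2.2),
    block_frames: int = 10,
) -> OccupancyResult:
    """Count atoms of a component inside the monolayer shell, per frame."""
    r_in, r_out = shell
    if not (r_out > r_in > 0):
        raise ValueError("need r_out > r_in > 0")
    atoms = _component_atoms(system, component)
    counts = np.zeros(trajectory.n_frames, dtype=int)
    for f, frame in enumerate(trajectory):
        com = core_com(system, frame)
        d = minimum_image(frame.coordinates[atoms] - com, frame.box)
        r = np.linalg.norm(d, axis=1)
        counts[f] = int(np.sum((r >= r_in) & (r < r_out)))
    return OccupancyResult(
        counts=counts,
        times=trajectory.times.copy(),
        component=component,
        shell=(r_in, r_out),
        mean=float(counts.mean()),
        std=block_std(counts, block_frames),
    )
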