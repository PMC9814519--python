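"""Geometric hydrogen-bond detection and bookkeeping.

A bond is registered for every (donor heavy atom, hydrogen, acceptor)
triplet whose minimum-image donor-acceptor distance is within ``d_cut`` and
whose hydrogen-donor-acceptor angle is within ``angle_cut`` — the geometric
criterion of the standard Gromacs H-bond tool, with its default cutoffs of
0.35 nm and 30 degrees. Counts are per bond, not per donor: a guanidinium
headgroup carries five donor hydrogens (two on each terminal eta nitrogen,
one on the linking epsilon nitrogen) and can form up to five bonds.

The ledger partitions per-frame counts by (donor class x acceptor class)
with eta/epsilon donors and water/phosphate acceptors, the partition used to
compare the solvated and membrane-bound states of the nanoparticle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import angle_deg, minimum_image, wrap_positions
from .io import Frame, Trajectory
from .results import block_std
from .system import AnnotatedSystem, AnnotationError

DEFAULT_D_CUT = 0.35  # nm, donor-acceptor
DEFAULT_ANGLE_CUT = 30.0  # deg, hydrogen-donor-acceptor


@dataclass(frozen=True)
class HBondRecord:
    frame: int
    donor: int
    hydrogen: int
    acceptor: int
    donor_class: str
    acceptor_class: str
    distance: float  # nm
    angle: float  # deg


def _acceptor_table(system: AnnotatedSystem) -> tuple[np.ndarray, np.ndarray]:
    idx_parts, cls_parts = [], []
    for cls, idx in system.acceptors.items():
        idx = np.asarray(idx, dtype=int)
        idx_parts.append(idx)
        cls_parts.extend([cls] * idx.size)
    if not idx_parts:
        return np.empty(0, dtype=int), np.empty(0, dtype=object)
    return np.concatenate(idx_parts), np.asarray(cls_parts, dtype=object)


def detect_hbonds(
    system: AnnotatedSystem,
    frame: Frame,
    d_cut: float = DEFAULT_D_CUT,
    angle_cut: float = DEFAULT_ANGLE_CUT,
    frame_index: int = 0,
    exclude_same_residue: bool = True,
) -> list[HBondRecord]:
    """All hydrogen bonds in one frame under the geometric criterion.

    Candidate donor-acceptor pairs are found with a periodic k-d tree, so the
    result is identical to the all-pairs minimum-image search.
    """
    if d_cut <= 0 or angle_cut <= 0:
        raise ValueError("cutoffs must be positive")
    for d in system.donors:
        if not d.hydrogens:
            raise AnnotationError(f"donor atom {d.heavy} has no attached hydrogen")
    acc_idx, acc_cls = _acceptor_table(system)
    if acc_idx.size == 0 or not system.donors:
        return []
    box = frame.box
    coords = frame.coordinates
    wrapped = wrap_positions(coords, box)
    tree = cKDTree(wrapped[acc_idx], boxsize=box)
    heavies = np.asarray([d.heavy for d in system.donors])
    neighbours = tree.query_ball_point(wrapped[heavies], r=d_cut)
    records: list[HBondRecord] = []
    for donor, near in zip(system.donors, neighbours):
        if not near:
            continue
        d_pos = coords[donor.heavy]
        for j in near:
            a = int(acc_idx[j])
            if a == donor.heavy:
                continue
            if exclude_same_residue and system.resids[a] == system.resids[donor.heavy]:
                continue
            da = minimum_image(coords[a] - d_pos, box)
            dist = float(np.linalg.norm(da))
            if dist > d_cut:
                continue
            for h in donor.hydrogens:
                dh = minimum_image(coords[h] - d_pos, box)
                ang = float(angle_deg(dh, da))
                if ang <= angle_cut:
                    records.append(
                        HBondRecord(
                            frame=frame_index,
                            donor=donor.heavy,
                            hydrogen=h,
                            acceptor=a,
                            donor_class=donor.donor_class,
                            acceptor_class=str(acc_cls[j]),
                            distance=dist,
                            angle=ang,
                        )
                    )
    return records


_CELLS = [("eta", "water"), ("eta", "phosphate"), ("epsilon", "water"), ("epsilon", "phosphate")]


@dataclass
class HBondLedger:
    """Per-frame H-bond counts partitioned by donor and acceptor class."""

    per_frame: pd.DataFrame  # columns: frame, time, donor_class, acceptor_class, count
    window: str = "custom"
    d_cut: float = DEFAULT_D_CUT
    angle_cut: float = DEFAULT_ANGLE_CUT
    block_frames: int = 10
    cells: dict = field(default_factory=dict)  # (donor,acceptor) -> {"mean","std"}

    def __post_init__(self):
        if not self.cells:
            for dc, ac in _CELLS:
                sel = self.per_frame[
                    (self.per_frame.donor_class == dc) & (self.per_frame.acceptor_class == ac)
                ]
                series = sel.sort_values("frame")["count"].to_numpy()
                self.cells[(dc, ac)] = {
                    "mean": float(series.mean()) if series.size else 0.0,
                    "std": block_std(series, self.block_frames) if series.size else 0.0,
                }

    def mean(self, donor_class: str, acceptor_class: str) -> float:
        return self.cells[(donor_class, acceptor_class)]["mean"]

    @property
    def eta_total(self) -> float:
        return self.mean("eta", "water") + self.mean("eta", "phosphate")

    @property
    def epsilon_total(self) -> float:
        return self.mean("epsilon", "water") + self.mean("epsilon", "phosphate")

    @property
    def np_bilayer_total(self) -> float:
        """Mean nanoparticle-bilayer bonds: all phosphate-class acceptors."""
        return self.mean("eta", "phosphate") + self.mean("epsilon", "phosphate")

    @property
    def grand_total(self) -> float:
        return self.eta_total + self.epsilon_total

    def summary(self) -> dict:
        return {
            "window": self.window,
            "d_cut_nm": self.d_cut,
            "angle_cut_deg": self.angle_cut,
            "cells": {
                f"{dc}-{ac}": self.cells[(dc, ac)] for dc, ac in _CELLS
            },
            "eta_total": self.eta_total,
            "epsilon_total": self.epsilon_total,
            "np_bilayer_total": self.np_bilayer_total,
            "grand_total": self.grand_total,
        }

    def write_csv(self, path) -> None:
        self.per_frame.to_csv(path, index=False)


def ledger(
    system: AnnotatedSystem,
    trajectory: Trajectory,
    window: slice | None = None,
    d_cut: float = DEFAULT_D_CUT,
    angle_cut: float = DEFAULT_ANGLE_CUT,
    label: str = "custom",
    block_frames: int = 10,
) -> HBondLedger:
    """H-bond ledger over a frame window, partitioned by donor/acceptor class.

    Every frame in the window is scanned with :func:`detect_hbonds`; counts
    are tabulated per (donor class, acceptor class) cell with the grand total
    guaranteed to equal the sum of the cells.
    """
    window = window if window is not None else slice(None)
    frames = range(*window.indices(trajectory.n_frames))
    if len(frames) == 0:
        raise ValueError("empty H-bond window")
    rows = []
    for f in frames:
        frame = trajectory[f]
        recs = detect_hbonds(system, frame, d_cut=d_cut, angle_cut=angle_cut, frame_index=f)
        tally: dict[tuple[str, str], int] = {c: 0 for c in _CELLS}
        for r in recs:
            key = (r.donor_class, r.acceptor_class)
            tally[key] = tally.get(key, 0) + 1
        for (dc, ac), n in tally.items():
            rows.append(
                {
                    "frame": f,
                    "time": float(trajectory.times[f]),
                    "donor_class": dc,
                    "acceptor_class": ac,
                    "count": n,
                }
            )
    per_frame = pd.DataFrame(rows)
    return HBondLedger(
        per_frame=per_frame,
        window=label,
        d_cut=d_cut,
        angle_cut=angle_cut,
        block_frames=block_frames,
    )


def brute_force_hbonds(
    system: AnnotatedSystem,
    frame: Frame,
    d_cut: float = DEFAULT_D_CUT,
    angle_cut: float = DEFAULT_ANGLE_CUT,
    exclude_same_residue: bool = True,
) -> int:
    """All-pairs O(N_donor x N_acceptor) bond count; the exactness oracle
    for the tree-accelerated detector."""
    acc_idx, _ = _acceptor_table(system)
    coords = frame.coordinates
    n = 0
    for donor in system.donors:
        for a in acc_idx:
            a = int(a)
            if a == donor.heavy:
                continue
            if exclude_same_residue and system.resids[a] == system.resids[donor.heavy]:
                continue
            da = minimum_image(coords[a] - coords[donor.heavy], frame.box)
            if np.linalg.norm(da) > d_cut:
                continue
            for h in donor.hydrogens:
                dh = minimum_image(coords[h] - coords[donor.heavy], frame.box)
                if angle_deg(dh, da) <= angle_cut:
                    n += 1
    return n
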