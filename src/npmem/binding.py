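"""Nanoparticle-membrane approach, binding-event detection, and RMSD traces.

Binding is defined operationally: a frame is "in contact" when any ligand
headgroup atom comes within ``d_contact`` of any lipid phosphorus site, and
the binding event is the start of the first contact episode that both
persists unbroken for at least ``persistence`` and keeps the nanoparticle in
contact for at least the occupancy fraction of all frames from that start to
the end of the trajectory. The detected time is therefore
parameter-dependent and is always reported together with its parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import minimum_image, wrap_positions
from .io import Frame, Trajectory
from .monolayer import core_com
from .system import AnnotatedSystem


@dataclass
class BindingEvent:
    time_ps: float
    first_contact_frame: int
    occupancy: float  # fraction of frames in contact from binding to end
    d_contact: float
    persistence_ps: float
    occupancy_threshold: float

    def to_dict(self) -> dict:
        return {
            "binding_time_ps": self.time_ps,
            "binding_time_ns": self.time_ps / 1000.0,
            "first_contact_frame": self.first_contact_frame,
            "occupancy": self.occupancy,
            "parameters": {
                "d_contact_nm": self.d_contact,
                "persistence_ns": self.persistence_ps / 1000.0,
                "occupancy_threshold": self.occupancy_threshold,
            },
        }


def _membrane_com(system: AnnotatedSystem, frame: Frame) -> np.ndarray:
    """COM over lipid P sites (the membrane's reference plane markers).

    Computed minimum-image about the first P site so a bilayer wrapped
    across the box boundary keeps a meaningful centre.
    """
    idx = system.lipid_p_sites
    if idx.size == 0:
        raise ValueError("system has no lipids")
    ref = frame.coordinates[idx[0]]
    local = ref + minimum_image(frame.coordinates[idx] - ref, frame.box)
    return local.mean(axis=0)


def com_distance_trace(
    system: AnnotatedSystem, trajectory: Trajectory, mode: str = "3d"
) -> np.ndarray:
    """Membrane-COM to gold-core-COM distance per frame.

    Returns an array of shape (n_frames, 2): time in ps, distance in nm.
    ``mode="3d"`` is the full minimum-image distance; ``mode="dz"`` is the
    absolute z-separation only.
    """
    out = np.empty((trajectory.n_frames, 2))
    for f, frame in enumerate(trajectory):
        d = minimum_image(core_com(system, frame) - _membrane_com(system, frame), frame.box)
        if mode == "dz":
            dist = abs(d[2])
        elif mode == "3d":
            dist = float(np.linalg.norm(d))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out[f] = (trajectory.times[f], dist)
    return out


def contact_trace(
    system: AnnotatedSystem, trajectory: Trajectory, d_contact: float = 0.4
) -> np.ndarray:
    """Boolean per-frame contact between headgroup atoms and lipid P sites."""
    heads = system.headgroup_atoms
    phos = system.lipid_p_sites
    if heads.size == 0 or phos.size == 0:
        raise ValueError("need both ligand headgroups and lipids for contact detection")
    flags = np.zeros(trajectory.n_frames, dtype=bool)
    for f, frame in enumerate(trajectory):
        w = wrap_positions(frame.coordinates, frame.box)
        tree = cKDTree(w[phos], boxsize=frame.box)
        d, _ = tree.query(w[heads], k=1)
        flags[f] = bool(np.min(d) <= d_contact)
    return flags


def detect_binding(
    system: AnnotatedSystem,
    trajectory: Trajectory,
    d_contact: float = 0.4,
    persistence_ns: float = 10.0,
    occupancy_threshold: float = 0.9,
) -> BindingEvent | None:
    """First persistent contact episode, or None if the NP never binds."""
    if d_contact <= 0:
        raise ValueError("d_contact must be > 0")
    persistence_ps = persistence_ns * 1000.0
    span = trajectory.times[-1] - trajectory.times[0]
    if persistence_ps > span:
        raise ValueError(
            f"persistence {persistence_ns} ns exceeds the trajectory span {span / 1000.0} ns"
        )
    flags = contact_trace(system, trajectory, d_contact=d_contact)
    n = len(flags)
    times = trajectory.times
    # episode starts: contact frames whose predecessor is not in contact
    starts = [i for i in range(n) if flags[i] and (i == 0 or not flags[i - 1])]
    for s in starts:
        run_end = s
        while run_end + 1 < n and flags[run_end + 1]:
            run_end += 1
        unbroken = times[run_end] - times[s]
        occupancy = float(np.mean(flags[s:]))
        if unbroken >= persistence_ps and occupancy >= occupancy_threshold:
            return BindingEvent(
                time_ps=float(times[s]),
                first_contact_frame=s,
                occupancy=occupancy,
                d_contact=d_contact,
                persistence_ps=persistence_ps,
                occupancy_threshold=occupancy_threshold,
            )
    return None


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation matrix, translation, rmsd). The rotation determinant
    is forced to +1 (proper rotation, no reflection).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(mobile) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    a = mobile - mc
    b = reference - rc
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    # rank-deficient H (collinear atoms) leaves the rotation underdetermined
    if np.sum(s > 1e-10 * s[0]) < 2:
        raise ValueError("superposition needs at least 3 non-collinear atoms")
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt
    aligned = a @ rot
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - b) ** 2, axis=1))))
    trans = rc - mc @ rot
    return rot, trans, rmsd


def rmsd_trace(
    trajectory: Trajectory, reference: Frame, selection: np.ndarray
) -> np.ndarray:
    """Per-frame RMSD after least-squares rigid superposition onto a reference.

    Returns shape (n_frames, 2): time ps, RMSD nm. The selection must contain
    at least three non-collinear atoms; rigid motion of the whole selection
    yields zero.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    ref = reference.coordinates[selection]
    out = np.empty((trajectory.n_frames, 2))
    for f, frame in enumerate(trajectory):
        _, _, rmsd = kabsch(frame.coordinates[selection], ref)
        out[f] = (trajectory.times[f], rmsd)
    return out
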