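"""Topology and trajectory I/O.

File handling is delegated to MDAnalysis (GRO/PDB topologies; XTC, DCD and
multi-frame XYZ trajectories). Internally everything is in nm and ps; the
Å-based formats are converted on read and write. Only orthorhombic boxes are
supported — triclinic input raises :class:`FormatError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .system import AnnotatedSystem, annotate

_A_PER_NM = 10.0


class FormatError(ValueError):
    """Unreadable or unsupported input file."""


@dataclass
class Frame:
    """One trajectory frame: coordinates (N, 3) nm, box lengths (3,) nm, time ps."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("frame has non-finite coordinates")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError(f"box lengths must be 3 positive values, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)


class Trajectory:
    """Ordered frames with constant atom count and strictly increasing times."""

    def __init__(self, coordinates: np.ndarray, boxes: np.ndarray, times: np.ndarray):
        self.coordinates = np.asarray(coordinates, dtype=float)
        self.boxes = np.asarray(boxes, dtype=float)
        self.times = np.asarray(times, dtype=float)
        if self.coordinates.ndim != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if len(self.boxes) != len(self.coordinates) or len(self.times) != len(self.coordinates):
            raise ValueError("boxes/times length mismatch with frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.coordinates)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.coordinates[i], self.boxes[i], self.times[i])
        return Frame(self.coordinates[i], self.boxes[i], float(self.times[i]))

    def __iter__(self):
        for i in range(self.n_frames):
            yield self[i]

    @classmethod
    def from_frames(cls, frames) -> "Trajectory":
        frames = list(frames)
        return cls(
            np.stack([f.coordinates for f in frames]),
            np.stack([f.box for f in frames]),
            np.asarray([f.time for f in frames]),
        )


def _check_orthorhombic(dimensions) -> np.ndarray:
    if dimensions is None or np.all(dimensions[:3] == 0):
        raise FormatError("file has no box information")
    if not np.allclose(dimensions[3:6], 90.0, atol=1e-3):
        raise FormatError(f"only orthorhombic boxes are supported (angles {dimensions[3:6]})")
    return np.asarray(dimensions[:3], dtype=float) / _A_PER_NM


def read_system(topology_path, roles_config) -> tuple[AnnotatedSystem, Frame]:
    """Read a GRO or PDB topology and annotate roles.

    ``roles_config`` is either a mapping (see :func:`npmem.system.annotate`)
    or the path of a YAML file holding one. Returns the annotated system and
    the coordinate frame stored in the topology file (nm).
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FileNotFoundError(topology_path)
    if isinstance(roles_config, (str, Path)):
        with open(roles_config) as fh:
            roles_config = yaml.safe_load(fh)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MDAnalysis guesses masses noisily
            u = mda.Universe(str(topology_path))
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise FormatError(f"cannot parse topology {topology_path}: {exc}") from exc
    names = [a.name for a in u.atoms]
    resnames = [a.resname for a in u.atoms]
    resids = [a.resid for a in u.atoms]
    try:
        elements = [getattr(a, "element", "") or "" for a in u.atoms]
        if not any(elements):
            elements = None
    except Exception:  # noqa: BLE001
        elements = None
    system = annotate(names, resnames, resids, roles_config, elements=elements)
    box = _check_orthorhombic(u.dimensions)
    frame = Frame(u.atoms.positions / _A_PER_NM, box, time=0.0)
    return system, frame


def read_trajectory(
    paths,
    topology=None,
    stride: int = 1,
    n_atoms: int | None = None,
    dt_ps: float = 10.0,
    default_box=None,
) -> Trajectory:
    """Read one or more trajectory files (XTC/DCD/XYZ) into memory.

    ``stride`` keeps every stride-th frame. For formats without time stamps
    (XYZ, some DCDs) frame times are assigned as ``index * dt_ps``. When the
    format carries no box either (XYZ), ``default_box`` (nm) is required.
    ``n_atoms`` (or a topology) enforces the expected atom count; a mismatch
    raises with the offending file.
    """
    import MDAnalysis as mda

    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [str(p) for p in paths]
    if stride < 1:
        raise ValueError("stride must be >= 1")
    coords, boxes, times = [], [], []
    frame_no = 0
    for p in paths:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(topology), p) if topology is not None else mda.Universe(p)
        if n_atoms is not None and len(u.atoms) != n_atoms:
            raise FormatError(
                f"{p}: atom count {len(u.atoms)} does not match expected {n_atoms}"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # readers without dt warn on time access
            for ts in u.trajectory:
                if frame_no % stride == 0:
                    coords.append(u.atoms.positions / _A_PER_NM)
                    if ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
                        boxes.append(_check_orthorhombic(ts.dimensions))
                    elif default_box is not None:
                        boxes.append(np.asarray(default_box, dtype=float))
                    else:
                        raise FormatError(f"{p}: no box in trajectory and no default_box given")
                    t = float(ts.time) if ts.time is not None and ts.dt != 1.0 else frame_no * dt_ps
                    times.append(t)
                frame_no += 1
    if not coords:
        raise FormatError("no frames left after applying stride")
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(coords), dtype=float) * dt_ps * stride
    return Trajectory(np.stack(coords), np.stack(boxes), times)


def _universe_from(system: AnnotatedSystem, frame: Frame):
    import MDAnalysis as mda

    n = system.n_atoms
    n_res = len(np.unique(system.resids))
    # residues must be contiguous for MDAnalysis residue mapping
    _, resindex = np.unique(system.resids, return_inverse=True)
    u = mda.Universe.empty(
        n, n_residues=n_res, atom_resindex=resindex, trajectory=True
    )
    u.add_TopologyAttr("names", system.names.astype(str))
    first = np.nonzero(np.r_[True, np.diff(system.resids) != 0])[0]
    u.add_TopologyAttr("resnames", system.resnames[first].astype(str))
    u.add_TopologyAttr("resids", system.resids[first].astype(int))
    u.atoms.positions = frame.coordinates * _A_PER_NM
    u.dimensions = np.r_[frame.box * _A_PER_NM, 90.0, 90.0, 90.0]
    return u


def write_gro(path, system: AnnotatedSystem, frame: Frame) -> None:
    """Write a single-frame GRO file (nm, 3 decimals — the format's precision)."""
    u = _universe_from(system, frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(path, system: AnnotatedSystem, trajectory: Trajectory) -> None:
    """Write a trajectory as multi-frame XYZ (Å) or XTC, chosen by extension."""
    import MDAnalysis as mda

    u = _universe_from(system, trajectory[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=system.n_atoms) as w:
            for fr in trajectory:
                u.atoms.positions = fr.coordinates * _A_PER_NM
                u.dimensions = np.r_[fr.box * _A_PER_NM, 90.0, 90.0, 90.0]
                u.trajectory.ts.time = fr.time
                w.write(u.atoms)
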