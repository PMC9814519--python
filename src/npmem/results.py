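"""Result containers shared by the analysis modules, with CSV/JSON export."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def block_std(per_frame: np.ndarray, block_frames: int) -> float:
    """Standard deviation of block means (uncertainty of a time average).

    Frames are grouped into consecutive blocks of ``block_frames``; a trailing
    partial block is dropped. With fewer than two full blocks the plain frame
    std is returned.
    """
    x = np.asarray(per_frame, dtype=float)
    n_blocks = len(x) // block_frames
    if n_blocks < 2:
        return float(np.std(x))
    means = x[: n_blocks * block_frames].reshape(n_blocks, block_frames).mean(axis=1)
    return float(np.std(means, ddof=1))


@dataclass
class ProfileResult:
    """A 1D binned statistic (RDF, polar density ratio, ...)."""

    bin_edges: np.ndarray
    values: np.ndarray
    uncertainty: np.ndarray
    n_frames: int
    quantity: str = ""
    units: str = ""

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        if len(self.values) != len(self.bin_edges) - 1:
            raise ValueError("values must have one entry per bin")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def peak(self) -> tuple[float, float]:
        """(bin center, value) of the global maximum."""
        i = int(np.argmax(self.values))
        return float(self.bin_centers[i]), float(self.values[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "value": self.values,
                "uncertainty": self.uncertainty,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PolarDensityMap(ProfileResult):
    """Angular number density relative to a uniform spherical distribution.

    ``values`` holds the per-bin ratio (1 = uniform); bins are polar-angle
    intervals over [0°, 180°] measured from the axis pointing away from the
    membrane, so the monolayer region facing the membrane is near 180°.
    """

    component: str = ""
    shell: tuple[float, float] = (0.0, 0.0)
    counts: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class MapResult:
    """An XY-gridded per-cell mean (angle or thickness map)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray  # (nx, ny); NaN where empty
    counts: np.ndarray  # (nx, ny) sample counts
    quantity: str
    window: tuple[float, float] | None = None
    contact_mean: float | None = None
    farfield_mean: float | None = None
    np_com_xy: tuple[float, float] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        empty = self.counts == 0
        if not np.all(np.isnan(self.values[empty])):
            raise ValueError("cells with zero samples must be NaN, not a value")

    @property
    def global_mean(self) -> float:
        """Count-weighted mean over all non-empty cells."""
        good = self.counts > 0
        return float(
            np.sum(self.values[good] * self.counts[good]) / np.sum(self.counts[good])
        )

    def write_csv(self, path) -> None:
        nx, ny = self.values.shape
        xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        df = pd.DataFrame(
            {
                "x_left": self.x_edges[xi.ravel()],
                "y_left": self.y_edges[yi.ravel()],
                "value": self.values.ravel(),
                "count": self.counts.ravel(),
            }
        )
        df.to_csv(path, index=False)

    def header(self) -> dict:
        return {
            "quantity": self.quantity,
            "x_edges": self.x_edges.tolist(),
            "y_edges": self.y_edges.tolist(),
            "window_ps": list(self.window) if self.window else None,
            "np_com_xy": list(self.np_com_xy) if self.np_com_xy else None,
            "contact_mean": self.contact_mean,
            "farfield_mean": self.farfield_mean,
            "global_mean": self.global_mean,
        }


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
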