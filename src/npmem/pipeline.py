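"""Config-driven end-to-end analysis pipeline.

Sequences the full protocol on a (topology, trajectory) pair or a synthetic
spec: role annotation -> monolayer statistics (RDF, coiled fraction, polar
density) -> approach trace and binding detection -> H-bond ledgers for the
before/after-binding windows -> membrane maps (alpha, beta, thickness) and
tail order parameters. Every output directory gets a machine-readable
``report.json`` stamped with the config hash and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .binding import com_distance_trace, detect_binding, rmsd_trace
from .hbonds import ledger
from .io import Trajectory, read_system, read_trajectory
from .membrane import angle_map, order_parameter, thickness_map
from .monolayer import classify_coiled, headgroup_rdf, polar_density, shell_occupancy
from .results import write_json
from .synth import SyntheticSpec, build_trajectory, load_spec
from .system import AnnotatedSystem

log = logging.getLogger("npmem.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """All knobs of one pipeline run. Times in ns, distances in nm."""

    # inputs: either file paths + roles, or a synthetic spec
    topology: str | None = None
    trajectory: str | list[str] | None = None
    roles: str | dict | None = None
    synthetic: str | dict | SyntheticSpec | None = None
    stride: int = 1
    # cutoffs
    hbond_d_cut: float = 0.35
    hbond_angle_cut: float = 30.0
    contact_d: float = 0.4
    persistence_ns: float = 10.0
    occupancy_threshold: float = 0.9
    coiled_threshold: float = 1.55
    # binning
    rdf_bin_width: float = 0.05
    rdf_r_max: float = 3.0
    shell: tuple[float, float] = (0.9, 2.2)
    polar_bins: int = 18
    grid_shape: tuple[int, int] = (26, 26)
    contact_radius: float = 2.5
    # windows
    equilibration_ns: float = 25.0
    post_binding_ns: float = 300.0
    block_frames: int = 10
    # misc
    out_dir: str = "npmem_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.shell, list):
            cfg.shell = tuple(cfg.shell)
        if isinstance(cfg.grid_shape, list):
            cfg.grid_shape = tuple(cfg.grid_shape)
        return cfg

    def digest(self) -> str:
        # output location does not influence results, so it is not hashed
        payload = {
            k: v for k, v in asdict(self).items() if k not in ("synthetic", "out_dir")
        }
        if isinstance(self.synthetic, SyntheticSpec):
            from .synth import spec_to_dict

            payload["synthetic"] = spec_to_dict(self.synthetic)
        else:
            payload["synthetic"] = self.synthetic
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: AnalysisConfig) -> tuple[AnnotatedSystem, Trajectory]:
    if config.synthetic is not None:
        spec = config.synthetic
        if isinstance(spec, (str, Path)):
            spec = load_spec(spec)
        elif isinstance(spec, dict):
            from .synth import spec_from_dict

            spec = spec_from_dict(spec)
        built = build_trajectory(spec)
        traj = built.trajectory
        if config.stride > 1:
            traj = Trajectory(
                traj.coordinates[:: config.stride],
                traj.boxes[:: config.stride],
                traj.times[:: config.stride],
            )
        return built.system, traj
    if config.topology is None or config.trajectory is None:
        raise ValueError("config needs either synthetic spec or topology+trajectory paths")
    system, frame0 = read_system(config.topology, config.roles)
    traj = read_trajectory(
        config.trajectory,
        topology=config.topology,
        stride=config.stride,
        n_atoms=system.n_atoms,
        default_box=frame0.box,
    )
    return system, traj


def _window_slice(traj: Trajectory, t0_ps: float, t1_ps: float) -> slice:
    idx = np.nonzero((traj.times >= t0_ps) & (traj.times <= t1_ps))[0]
    if idx.size == 0:
        return slice(0, 0)
    return slice(int(idx[0]), int(idx[-1]) + 1)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis protocol and write all outputs to ``out_dir``."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "config_hash": config.digest(),
        "warnings": [],
    }
    stage = "load_inputs"
    t_start = _time.time()
    try:
        system, traj = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc
    log.info("loaded %d atoms, %d frames (%.1f s)", system.n_atoms, traj.n_frames, _time.time() - t_start)
    report["roles"] = system.role_counts()
    report["n_frames"] = traj.n_frames
    report["span_ns"] = float((traj.times[-1] - traj.times[0]) / 1000.0)

    eq_ps = config.equilibration_ns * 1000.0
    analysis_window = _window_slice(traj, eq_ps, float(traj.times[-1]))
    if analysis_window == slice(0, 0):
        raise PipelineError(
            "windows", ValueError("no frames remain after the equilibration discard")
        )
    traj_eq = traj[analysis_window]

    def run_stage(name, fn):
        t0 = _time.time()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(name, exc) from exc
        log.info("stage %-16s done in %.2f s", name, _time.time() - t0)
        return result

    # --- monolayer ---------------------------------------------------------
    if system.ligands:
        rdf = run_stage(
            "rdf",
            lambda: headgroup_rdf(
                system,
                traj_eq,
                bin_width=config.rdf_bin_width,
                r_max=config.rdf_r_max,
                block_frames=config.block_frames,
            ),
        )
        rdf.write_csv(outdir / "headgroup_rdf.csv")
        peak_r, peak_v = rdf.peak()
        report["rdf"] = {"peak_nm": peak_r, "peak_value": peak_v, "n_frames": rdf.n_frames}

        coiled = run_stage(
            "coiled", lambda: classify_coiled(system, traj_eq, config.coiled_threshold)
        )
        report["coiled"] = {
            "fraction": coiled.fraction,
            "mean_count": float(coiled.counts.mean()),
            "r_threshold_nm": coiled.r_threshold,
        }

        polar = run_stage(
            "polar_density",
            lambda: polar_density(
                system,
                traj_eq,
                component="headgroup",
                shell=config.shell,
                n_bins=config.polar_bins,
                block_frames=config.block_frames,
            ),
        )
        polar.write_csv(outdir / "polar_density_headgroup.csv")
        report["polar_density"] = {
            "component": "headgroup",
            "max_ratio": float(np.max(polar.values)),
            "min_ratio": float(np.min(polar.values)),
        }
        if system.counterions.size:
            occ = run_stage(
                "shell_occupancy",
                lambda: shell_occupancy(system, traj_eq, "counterion", config.shell),
            )
            report["shell_occupancy"] = {
                "counterion_mean": occ.mean,
                "counterion_std": occ.std,
            }

    # --- binding -----------------------------------------------------------
    event = None
    if system.lipids and system.core_atoms.size:
        trace = run_stage("com_trace", lambda: com_distance_trace(system, traj))
        np.savetxt(
            outdir / "com_distance.csv",
            trace,
            delimiter=",",
            header="time_ps,distance_nm",
            comments="",
        )
        event = run_stage(
            "binding",
            lambda: detect_binding(
                system,
                traj,
                d_contact=config.contact_d,
                persistence_ns=min(config.persistence_ns, report["span_ns"] / 2),
                occupancy_threshold=config.occupancy_threshold,
            ),
        )
        report["binding"] = event.to_dict() if event else None
        if event is None:
            msg = "no binding event detected; membrane stages use the whole trajectory"
            warnings.warn(msg)
            report["warnings"].append(msg)

    # --- H-bond ledgers ----------------------------------------------------
    if system.donors:
        if event is not None:
            before = _window_slice(traj, eq_ps, event.time_ps - traj.times[1] + traj.times[0])
            after = _window_slice(
                traj, event.time_ps, event.time_ps + config.post_binding_ns * 1000.0
            )
            windows = [("before_binding", before), ("after_binding", after)]
        else:
            windows = [("unbound", analysis_window)]
        report["hbonds"] = {}
        for label, win in windows:
            if win == slice(0, 0):
                report["hbonds"][label] = None
                continue
            led = run_stage(
                f"hbonds_{label}",
                lambda win=win, label=label: ledger(
                    system,
                    traj,
                    window=win,
                    d_cut=config.hbond_d_cut,
                    angle_cut=config.hbond_angle_cut,
                    label=label,
                    block_frames=config.block_frames,
                ),
            )
            led.write_csv(outdir / f"hbonds_{label}.csv")
            report["hbonds"][label] = led.summary()

    # --- membrane maps -----------------------------------------------------
    if system.lipids:
        if event is not None:
            map_window = _window_slice(
                traj, event.time_ps, event.time_ps + config.post_binding_ns * 1000.0
            )
        else:
            map_window = analysis_window
        report["membrane"] = {}
        for qty in ("alpha", "beta") if system.core_atoms.size else ("alpha",):
            m = run_stage(
                f"map_{qty}",
                lambda qty=qty: angle_map(
                    system,
                    traj,
                    quantity=qty,
                    grid_shape=config.grid_shape,
                    window=map_window,
                    contact_radius=config.contact_radius,
                ),
            )
            m.write_csv(outdir / f"map_{qty}.csv")
            write_json(outdir / f"map_{qty}.json", m.header())
            report["membrane"][qty] = {
                "global_mean_deg": m.global_mean,
                "contact_mean_deg": m.contact_mean,
                "farfield_mean_deg": m.farfield_mean,
            }
        thick = run_stage(
            "thickness",
            lambda: thickness_map(
                system,
                traj,
                grid_shape=config.grid_shape,
                window=map_window,
                contact_radius=config.contact_radius,
            ),
        )
        thick.write_csv(outdir / "map_thickness.csv")
        report["membrane"]["thickness"] = {
            "global_mean_nm": thick.global_mean,
            "contact_mean_nm": thick.contact_mean,
            "farfield_mean_nm": thick.farfield_mean,
        }
        s = run_stage("order_parameter", lambda: order_parameter(system, traj, window=map_window))
        report["membrane"]["order_parameter"] = [None if np.isnan(v) else float(v) for v in s]

    # --- RMSD convergence ---------------------------------------------------
    if system.core_atoms.size and system.ligands:
        np_atoms = np.concatenate(
            [system.core_atoms] + [np.asarray(l.atoms) for l in system.ligands]
        )
        r = run_stage("rmsd", lambda: rmsd_trace(traj, traj[0], np_atoms))
        np.savetxt(
            outdir / "rmsd.csv", r, delimiter=",", header="time_ps,rmsd_nm", comments=""
        )
        report["rmsd"] = {"final_nm": float(r[-1, 1]), "max_nm": float(np.max(r[:, 1]))}

    write_json(outdir / "report.json", report)
    return report


def collate_reports(out_dirs) -> dict:
    """Merge the report.json files of several runs into one summary."""
    merged = {}
    for d in out_dirs:
        p = Path(d) / "report.json"
        if p.exists():
            with open(p) as fh:
                merged[str(d)] = json.load(fh)
    return merged
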