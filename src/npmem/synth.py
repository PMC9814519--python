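"""Synthetic annotated systems and trajectories with planted ground truth.

The generator emulates the geometry of a thiol-protected gold nanoparticle
near a phosphatidylcholine bilayer at the level the analysis code cares
about: a pseudo-gold core, 60 anchored ligand chains ending in planar
guanidinium-like headgroups (two eta nitrogens with two hydrogens each, one
epsilon nitrogen with one hydrogen), a two-leaflet grid of pseudo-lipids
each carrying one P and one N site plus tail beads, counterion/water point
clouds, explicitly planted hydrogen-bond triplets with exact requested
geometry, and a prescribed nanoparticle height-vs-time course.

Everything is kinematic: there is no energetics and no integrator. The value
of the construction is that every statistic the analysis modules compute has
a closed-form planted value here.

All randomness flows from one master seed through named, independently
spawned streams, so e.g. adding waters does not perturb ligand placement and
identical specs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .geometry import angle_deg, minimum_image
from .io import Frame, Trajectory, write_gro, write_trajectory
from .system import AnnotatedSystem, annotate

# guanidinium construction constants (nm); chosen once, shared with the
# planted-contact helpers below
_CN = 0.134  # C-N bond
_NH = 0.100  # N-H bond
# z-drop of the lowest headgroup atom below the headgroup centre for a
# ligand pointing along -z: NH at 60 deg off-axis plus its on-axis hydrogen
_SOUTH_EXTENT = _CN * 0.5 + _NH


class SpecError(ValueError):
    """An inconsistent synthetic-system specification."""


@dataclass(frozen=True)
class HBondPlant:
    """A planted donor-H-acceptor triplet with exact geometry.

    ``count`` identical triplets are planted on distinct donor hydrogens of
    the requested class. Outside the activity window the acceptor atoms are
    parked far from the nanoparticle so no bond is registered.
    """

    distance: float  # D-A distance, nm
    angle: float  # H-D-A angle, deg
    donor_class: str  # "eta" | "epsilon"
    acceptor_class: str  # "water" | "phosphate"
    count: int = 1
    active_from_ps: float | None = None
    active_until_ps: float | None = None

    def active(self, t_ps: float) -> bool:
        if self.active_from_ps is not None and t_ps < self.active_from_ps:
            return False
        if self.active_until_ps is not None and t_ps > self.active_until_ps:
            return False
        return True


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic system + trajectory.

    Distances in nm, times in ps, angles in degrees. Angle laws are tagged
    tuples: ``("delta", x)``, ``("uniform_cone", lo, hi)``,
    ``("empirical", [values...])`` for the polar law and
    ``("random_azimuth",)``, ``("point_outward", x, y)``,
    ``("fixed_offset", delta)`` for the azimuth law. The tail tilt law is
    ``("delta", x)`` or ``("isotropic",)``.
    """

    seed: int = 0
    # nanoparticle
    include_np: bool = True
    n_ligands: int = 60
    n_core: int = 32
    core_radius: float = 0.9
    extended_radius: float = 1.8
    coiled_radius: float = 1.3
    n_coiled: int = 2
    south_pole_ligand: bool = True
    ligand_tumbling: bool = False
    shell_counterions: int = 0
    shell_ion_radius: float = 1.4
    # membrane
    include_membrane: bool = True
    lipid_grid: tuple[int, int] = (16, 16)
    lipid_spacing: float = 0.8
    leaflet_separation: float = 4.0
    pn_distance: float = 0.45
    alpha_law: tuple = ("delta", 67.0)
    beta_law: tuple = ("random_azimuth",)
    n_tail_beads: int = 8
    tail_bead_spacing: float = 0.125
    tail_tilt_law: tuple = ("delta", 0.0)
    # Gaussian depression of the upper leaflet under the NP column
    # (local membrane slimming); depth in nm, width sigma in nm
    dimple_depth: float = 0.0
    dimple_sigma: float = 1.5
    # environment
    n_waters: int = 0
    n_counterions: int = 0
    # keep bulk clouds out of the NP column / bilayer slab so they cannot
    # perturb planted shell or H-bond counts; disable for uniform-gas tests
    cloud_excludes_np: bool = True
    # planted H-bonds
    hbond_plants: tuple[HBondPlant, ...] = ()
    plant_d_cut: float = 0.35
    plant_angle_cut: float = 30.0
    # nanoparticle path: breakpoints (t_ps, height above midplane in nm);
    # linear interpolation. None -> constant np_height.
    np_path: tuple[tuple[float, float], ...] | None = None
    np_height: float = 6.0
    n_frames: int = 50
    frame_dt: float = 10.0

    def __post_init__(self):
        if self.frame_dt <= 0:
            raise SpecError("frame_dt must be > 0")
        if not (0 <= self.n_coiled <= self.n_ligands):
            raise SpecError("need 0 <= n_coiled <= n_ligands")
        if self.coiled_radius >= self.extended_radius:
            raise SpecError("coiled_radius must be < extended_radius")
        if min(self.coiled_radius, self.extended_radius) <= self.core_radius:
            raise SpecError("headgroup radii must exceed core_radius")
        if self.lipid_spacing <= 0:
            raise SpecError("lipid grid spacing must be > 0")
        if self.ligand_tumbling and self.hbond_plants:
            raise SpecError("planted H-bonds require a rigid ligand shell (no tumbling)")
        if self.dimple_depth < 0:
            raise SpecError("dimple_depth must be >= 0")
        if self.np_path is not None:
            t_end = (self.n_frames - 1) * self.frame_dt
            ts = [p[0] for p in self.np_path]
            if ts[0] > 0 or ts[-1] < t_end:
                raise SpecError("np_path must cover [0, trajectory end]")
            if list(ts) != sorted(ts):
                raise SpecError("np_path breakpoints must be time-ordered")
            zmin = min(self.np_heights(self.frame_times()))
            if self.include_membrane and zmin <= 0:
                raise SpecError("np_path penetrates the membrane mid-plane")

    # -- derived quantities -------------------------------------------------
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_dt

    def np_heights(self, times) -> np.ndarray:
        """Nanoparticle-centre height above the bilayer midplane, per time."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if self.np_path is None:
            return np.full(len(times), self.np_height)
        ts = np.asarray([p[0] for p in self.np_path], dtype=float)
        zs = np.asarray([p[1] for p in self.np_path], dtype=float)
        return np.interp(times, ts, zs)

    def south_extent(self) -> float:
        """Radius of the lowest headgroup atom of a -z pointing ligand."""
        return self.extended_radius + _SOUTH_EXTENT

    def bound_height(self, clearance: float = 0.35) -> float:
        """Midplane height at which the south headgroup sits ``clearance``
        above the upper-leaflet phosphates."""
        return self.leaflet_separation / 2.0 + self.south_extent() + clearance

    def box(self) -> np.ndarray:
        nx, ny = self.lipid_grid
        if self.include_membrane:
            lx = nx * self.lipid_spacing
            ly = ny * self.lipid_spacing
        else:
            lx = ly = 2.0 * (self.extended_radius + 3.0)
        heights = self.np_heights(self.frame_times()) if self.include_np else [0.0]
        z_top = max(heights) + self.extended_radius + 2.0
        tail_len = 0.5 + self.n_tail_beads * self.tail_bead_spacing
        z_bot = self.leaflet_separation / 2.0 + tail_len + 1.0
        return np.asarray([lx, ly, z_bot + max(z_top, 2.0)])

    def midplane_z(self) -> float:
        tail_len = 0.5 + self.n_tail_beads * self.tail_bead_spacing
        return self.leaflet_separation / 2.0 + tail_len + 1.0

    def np_center_xy(self) -> np.ndarray:
        box = self.box()
        if not self.include_membrane:
            return box[:2] / 2.0
        nx, ny = self.lipid_grid
        s = self.lipid_spacing
        # snap onto the lipid grid node nearest the box centre so that a
        # south-pole ligand sits exactly above a phosphate
        return np.asarray([(nx // 2 + 0.5) * s, (ny // 2 + 0.5) * s])


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    names = (
        "ligand_dirs",
        "ligand_azimuth",
        "lipid_alpha",
        "lipid_beta",
        "tails",
        "waters",
        "ions",
        "plants",
        "tumbling",
    )
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _perp_basis(u: np.ndarray, azimuth: float) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (e1, e2) perpendicular to unit vector u, rotated by azimuth."""
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    c, s = np.cos(azimuth), np.sin(azimuth)
    return c * e1 + s * e2, -s * e1 + c * e2


# ---------------------------------------------------------------------------
# fragment assembly
# ---------------------------------------------------------------------------


class _Builder:
    """Accumulates atom records and coordinates for one configuration."""

    def __init__(self):
        self.names: list[str] = []
        self.resnames: list[str] = []
        self.resids: list[int] = []
        self.coords: list[np.ndarray] = []
        self.next_resid = 1

    def add_residue(self, resname: str, names, coords) -> np.ndarray:
        start = len(self.names)
        rid = self.next_resid
        self.next_resid += 1
        for n, c in zip(names, coords):
            self.names.append(n)
            self.resnames.append(resname)
            self.resids.append(rid)
            self.coords.append(np.asarray(c, dtype=float))
        return np.arange(start, len(self.names))

    def positions(self) -> np.ndarray:
        return np.asarray(self.coords)


_LIG_NAMES = ("S", "C1", "C2", "NE", "HE", "CZ", "NH1", "HH11", "HH12", "NH2", "HH21", "HH22")
_HEAD_NAMES = ("NE", "HE", "CZ", "NH1", "HH11", "HH12", "NH2", "HH21", "HH22")


def _ligand_coords(u: np.ndarray, r_head: float, core_radius: float, azimuth: float):
    """Atom coordinates of one ligand chain along direction u (NP frame).

    The heavy-atom skeleton (NE, CZ, NH1, NH2) is planar; the lone epsilon
    hydrogen points out of the plane so its hydrogen-bond cone is well
    separated from the eta donors.
    """
    e1, e2 = _perp_basis(u, azimuth)

    def plane_dir(gamma_deg: float) -> np.ndarray:
        g = np.radians(gamma_deg)
        return np.cos(g) * u + np.sin(g) * e1

    cz = r_head * u
    ne = (r_head - _CN) * u
    nh1 = cz + _CN * plane_dir(60.0)
    nh2 = cz + _CN * plane_dir(-60.0)
    coords = [
        core_radius * u,  # S
        (core_radius + (r_head - core_radius) / 3.0) * u,  # C1
        (core_radius + 2.0 * (r_head - core_radius) / 3.0) * u,  # C2
        ne,
        ne + _NH * e2,  # HE (out of plane)
        cz,
        nh1,
        nh1 + _NH * plane_dir(120.0),  # HH11
        nh1 + _NH * plane_dir(0.0),  # HH12 -- radially outward
        nh2,
        nh2 + _NH * plane_dir(-120.0),  # HH21
        nh2 + _NH * plane_dir(0.0),  # HH22
    ]
    return coords


def _sample_polar(law: tuple, rng: np.random.Generator, n: int) -> np.ndarray:
    kind = law[0]
    if kind == "delta":
        return np.full(n, float(law[1]))
    if kind == "uniform_cone":
        lo, hi = float(law[1]), float(law[2])
        # uniform in solid angle on the cone band
        clo, chi = np.cos(np.radians(lo)), np.cos(np.radians(hi))
        return np.degrees(np.arccos(rng.uniform(min(clo, chi), max(clo, chi), size=n)))
    if kind == "empirical":
        return rng.choice(np.asarray(law[1], dtype=float), size=n)
    raise SpecError(f"unknown polar law {law!r}")


def _sample_tilt(law: tuple, rng: np.random.Generator, n: int):
    if law[0] == "delta":
        theta = np.full(n, np.radians(float(law[1])))
        psi = rng.uniform(0.0, 2 * np.pi, size=n)
        return theta, psi
    if law[0] == "isotropic":
        return None, None  # handled segment-wise
    raise SpecError(f"unknown tail tilt law {law!r}")


@dataclass
class SyntheticTrajectory:
    """Bundle of a generated system, its trajectory, and its ground truth."""

    spec: SyntheticSpec
    system: AnnotatedSystem
    trajectory: Trajectory
    roles: dict
    np_indices: np.ndarray  # atoms translated rigidly with the nanoparticle
    plant_acceptors: list  # (HBondPlant, atom index) per planted triplet
    midplane_z: float = 0.0

    def planted_ledger(self, t_ps: float) -> dict[tuple[str, str], int]:
        """Planted H-bond count per (donor class, acceptor class) at time t."""
        counts: dict[tuple[str, str], int] = {}
        for plant, _idx in self.plant_acceptors:
            if plant.active(t_ps):
                key = (plant.donor_class, plant.acceptor_class)
                counts[key] = counts.get(key, 0) + 1
        return counts

    def write(self, outdir) -> dict:
        """Write GRO + XYZ + roles.yaml (+ spec.yaml); returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "topology": outdir / "system.gro",
            "trajectory": outdir / "trajectory.xyz",
            "roles": outdir / "roles.yaml",
            "spec": outdir / "spec.yaml",
        }
        write_gro(paths["topology"], self.system, self.trajectory[0])
        write_trajectory(paths["trajectory"], self.system, self.trajectory)
        with open(paths["roles"], "w") as fh:
            yaml.safe_dump(self.roles, fh, sort_keys=False)
        with open(paths["spec"], "w") as fh:
            yaml.safe_dump(spec_to_dict(self.spec), fh, sort_keys=False)
        return {k: str(v) for k, v in paths.items()}


def default_roles(spec: SyntheticSpec) -> dict:
    """The roles config matching the generator's own atom naming."""
    tails = [
        [f"C{j}A" for j in range(1, spec.n_tail_beads + 1)],
        [f"C{j}B" for j in range(1, spec.n_tail_beads + 1)],
    ]
    cfg = {
        "core": {"resname": "AUC"},
        "ligands": {
            "resname": "LIG",
            "headgroup_atoms": list(_HEAD_NAMES),
            "headgroup_center": "CZ",
        },
        "donors": [
            {"resname": "LIG", "atom": "NH1", "hydrogens": ["HH11", "HH12"], "class": "eta"},
            {"resname": "LIG", "atom": "NH2", "hydrogens": ["HH21", "HH22"], "class": "eta"},
            {"resname": "LIG", "atom": "NE", "hydrogens": ["HE"], "class": "epsilon"},
        ],
        "acceptors": {
            "water": [{"resname": "SOL", "atom": "OW"}]
            + (
                [{"resname": "PLW", "atom": "OW"}]
                if any(p.acceptor_class == "water" for p in spec.hbond_plants)
                else []
            ),
            "phosphate": [{"resname": "PC", "atom": "P"}]
            + (
                [{"resname": "PLP", "atom": "OP"}]
                if any(p.acceptor_class == "phosphate" for p in spec.hbond_plants)
                else []
            ),
        },
        "lipids": {"resname": "PC", "p_atom": "P", "n_atom": "N", "tails": tails},
        "waters": {"resname": "SOL"},
        "counterions": {"resname": "CL"},
    }
    if not spec.include_np:
        del cfg["core"], cfg["ligands"], cfg["donors"]
    if not spec.include_membrane:
        del cfg["lipids"]
        cfg["acceptors"]["phosphate"] = [
            p for p in cfg["acceptors"]["phosphate"] if p["resname"] != "PC"
        ]
    if spec.n_waters == 0:
        del cfg["waters"]
        cfg["acceptors"]["water"] = [
            p for p in cfg["acceptors"]["water"] if p["resname"] != "SOL"
        ]
    if spec.n_counterions == 0 and spec.shell_counterions == 0:
        del cfg["counterions"]
    cfg["acceptors"] = {k: v for k, v in cfg["acceptors"].items() if v}
    if not cfg.get("acceptors"):
        del cfg["acceptors"]
    return cfg


def _build_np_fragment(spec: SyntheticSpec, b: _Builder, rng: dict, dirs=None):
    """Nanoparticle in its local frame (centre at origin). Returns index info.

    Surface gold atoms come in antipodal pairs so the core COM is exactly the
    geometric centre — planted headgroup radii are then exact by construction.
    """
    half = spec.core_radius * _fibonacci_sphere(max(1, spec.n_core // 2))
    core_pts = np.vstack([[0.0, 0.0, 0.0], half, -half])
    core_idx = b.add_residue("AUC", ["AU"] * len(core_pts), core_pts)
    if dirs is None:
        dirs = _uniform_sphere(rng["ligand_dirs"], spec.n_ligands)
        if spec.south_pole_ligand and spec.n_ligands > 0:
            dirs[0] = np.array([0.0, 0.0, -1.0])
    azimuths = rng["ligand_azimuth"].uniform(0.0, 2 * np.pi, size=spec.n_ligands)
    # the last n_coiled ligands fold back into the monolayer
    radii = np.full(spec.n_ligands, spec.extended_radius)
    if spec.n_coiled:
        radii[-spec.n_coiled :] = spec.coiled_radius
    lig_idx = []
    for u, r, az in zip(dirs, radii, azimuths):
        lig_idx.append(b.add_residue("LIG", list(_LIG_NAMES), _ligand_coords(u, r, spec.core_radius, az)))
    ion_idx = []
    if spec.shell_counterions:
        ion_dirs = _uniform_sphere(rng["ions"], spec.shell_counterions)
        for u in ion_dirs:
            ion_idx.append(b.add_residue("CL", ["CL"], [spec.shell_ion_radius * u]))
    return core_idx, lig_idx, ion_idx, dirs


def _build_membrane_fragment(spec: SyntheticSpec, b: _Builder, rng: dict, midplane: float):
    nx, ny = spec.lipid_grid
    s = spec.lipid_spacing
    n_lip = nx * ny
    box = spec.box()
    tail_names = [f"C{j}A" for j in range(1, spec.n_tail_beads + 1)] + [
        f"C{j}B" for j in range(1, spec.n_tail_beads + 1)
    ]
    for leaflet, zsign in (("upper", 1.0), ("lower", -1.0)):
        alphas = np.radians(_sample_polar(spec.alpha_law, rng["lipid_alpha"], n_lip))
        n_out = np.array([0.0, 0.0, zsign])
        theta_t, psi_t = _sample_tilt(spec.tail_tilt_law, rng["tails"], 2 * n_lip)
        k = 0
        for ix in range(nx):
            for iy in range(ny):
                p = np.array(
                    [(ix + 0.5) * s, (iy + 0.5) * s, midplane + zsign * spec.leaflet_separation / 2.0]
                )
                if spec.dimple_depth > 0 and zsign > 0:
                    d_xy = p[:2] - spec.np_center_xy()
                    p[2] -= spec.dimple_depth * np.exp(
                        -np.dot(d_xy, d_xy) / (2.0 * spec.dimple_sigma**2)
                    )
                # azimuth of the P->N headgroup vector
                bl = spec.beta_law
                if bl[0] == "random_azimuth":
                    phi = rng["lipid_beta"].uniform(0.0, 2 * np.pi)
                elif bl[0] == "point_outward":
                    tgt = np.asarray(bl[1:3], dtype=float)
                    d = minimum_image(p[:2] - tgt, box[:2])  # same fold as beta
                    phi = np.arctan2(d[1], d[0])
                elif bl[0] == "fixed_offset":
                    tgt = spec.np_center_xy()
                    d = minimum_image(p[:2] - tgt, box[:2])
                    phi = np.arctan2(d[1], d[0]) + np.radians(float(bl[1]))
                else:
                    raise SpecError(f"unknown azimuth law {bl!r}")
                a = alphas[k]
                pn = spec.pn_distance * (
                    np.cos(a) * n_out + np.sin(a) * np.array([np.cos(phi), np.sin(phi), 0.0])
                )
                coords = [p, p + pn]
                for chain in range(2):
                    if theta_t is None:  # isotropic segments
                        pos = p + np.array([0.0, 0.0, -zsign * 0.15])
                        for _j in range(spec.n_tail_beads):
                            step = _uniform_sphere(rng["tails"], 1)[0] * spec.tail_bead_spacing
                            pos = pos + step
                            coords.append(pos.copy())
                    else:
                        th = theta_t[2 * k + chain]
                        ps_ = psi_t[2 * k + chain]
                        t_hat = np.cos(th) * (-n_out) + np.sin(th) * np.array(
                            [np.cos(ps_), np.sin(ps_), 0.0]
                        )
                        for j in range(1, spec.n_tail_beads + 1):
                            coords.append(p + t_hat * (0.15 + j * spec.tail_bead_spacing))
                b.add_residue("PC", ["P", "N"] + tail_names, coords)
                k += 1


def _plant_acceptor_position(
    d_pos: np.ndarray,
    h_pos: np.ndarray,
    plant: HBondPlant,
    donor_heavies: np.ndarray,
    donor_h_by_heavy: list[np.ndarray],
    all_coords,
    d_cut: float,
    angle_cut: float,
) -> np.ndarray:
    """Place an acceptor at the planted (distance, angle) from donor D/H,
    azimuth chosen so no *other* donor sees it inside the cutoffs."""
    a_hat = h_pos - d_pos
    a_hat = a_hat / np.linalg.norm(a_hat)
    theta = np.radians(plant.angle)
    for az_deg in range(0, 360, 10):
        e1, _ = _perp_basis(a_hat, np.radians(az_deg))
        w = np.cos(theta) * a_hat + np.sin(theta) * e1
        a_pos = d_pos + plant.distance * w
        ok = True
        for heavy, hyds in zip(donor_heavies, donor_h_by_heavy):
            dpos2 = all_coords[heavy]
            if np.array_equal(dpos2, d_pos):
                continue
            dist = np.linalg.norm(a_pos - dpos2)
            if dist > d_cut * 1.02:
                continue
            for h in hyds:
                if angle_deg(all_coords[h] - dpos2, a_pos - dpos2) <= angle_cut * 1.05:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return a_pos
    return None


def build_trajectory(spec: SyntheticSpec) -> SyntheticTrajectory:
    """Assemble the full synthetic system and kinematic trajectory."""
    rng = _rng_streams(spec.seed)
    box = spec.box()
    midplane = spec.midplane_z() if spec.include_membrane else box[2] / 2.0
    b = _Builder()
    np_parts: list[np.ndarray] = []
    lig_idx: list[np.ndarray] = []
    dirs = None
    if spec.include_np:
        core_idx, lig_idx, ion_idx, dirs = _build_np_fragment(spec, b, rng)
        np_parts = [core_idx, *lig_idx, *ion_idx]
    if spec.include_membrane:
        _build_membrane_fragment(spec, b, rng, midplane)

    # planted H-bond acceptors (in the NP local frame; they ride with the NP)
    plant_records: list[tuple[HBondPlant, int]] = []
    if spec.include_np and spec.hbond_plants:
        coords_local = b.positions()
        heavies, h_by_heavy, classes = [], [], []
        for li in lig_idx:
            name_of = {b.names[i]: i for i in li}
            for heavy_n, h_ns, cls in (
                ("NH1", ("HH11", "HH12"), "eta"),
                ("NH2", ("HH21", "HH22"), "eta"),
                ("NE", ("HE",), "epsilon"),
            ):
                heavies.append(name_of[heavy_n])
                h_by_heavy.append(np.asarray([name_of[h] for h in h_ns]))
                classes.append(cls)
        heavies = np.asarray(heavies)
        # hand out donor hydrogens of the right class, one plant per hydrogen,
        # spreading plants over ligands (round-robin over donors)
        free: dict[str, list[tuple[int, int]]] = {"eta": [], "epsilon": []}
        for heavy, hyds, cls in zip(heavies, h_by_heavy, classes):
            for h in hyds:
                free[cls].append((int(heavy), int(h)))
        cursor = {"eta": 0, "epsilon": 0}
        for plant in spec.hbond_plants:
            if plant.donor_class not in free:
                raise SpecError(f"unknown donor class {plant.donor_class!r}")
            for _ in range(plant.count):
                pool = free[plant.donor_class]
                # take the next free hydrogen that admits a clash-free placement
                a_pos = None
                while cursor[plant.donor_class] < len(pool):
                    heavy, h = pool[cursor[plant.donor_class]]
                    cursor[plant.donor_class] += 1
                    a_pos = _plant_acceptor_position(
                        coords_local[heavy],
                        coords_local[h],
                        plant,
                        heavies,
                        h_by_heavy,
                        coords_local,
                        spec.plant_d_cut,
                        spec.plant_angle_cut,
                    )
                    if a_pos is not None:
                        break
                if a_pos is None:
                    raise SpecError(
                        f"not enough clash-free {plant.donor_class} donor hydrogens for all plants"
                    )
                resname, aname = (
                    ("PLW", "OW") if plant.acceptor_class == "water" else ("PLP", "OP")
                )
                idx = b.add_residue(resname, [aname], [a_pos])
                np_parts.append(idx)
                plant_records.append((plant, int(idx[0])))
                coords_local = b.positions()

    # bulk waters / counterions: static, kept clear of the NP column so they
    # never perturb planted shell or H-bond counts
    def _place_cloud(n: int, resname: str, aname: str, stream: str):
        if n == 0:
            return
        g = rng[stream]
        placed = 0
        guard = 0
        xy_np = spec.np_center_xy() if spec.include_np and spec.cloud_excludes_np else None
        while placed < n:
            guard += 1
            if guard > 100 * n + 1000:
                raise SpecError("cannot place bulk cloud outside exclusion zones")
            pos = g.uniform(0.0, 1.0, size=3) * box
            if xy_np is not None and np.linalg.norm(pos[:2] - xy_np) < spec.extended_radius + 1.0:
                continue
            if (
                spec.cloud_excludes_np
                and spec.include_membrane
                and abs(pos[2] - midplane) < spec.leaflet_separation / 2.0 + 0.5
            ):
                continue
            b.add_residue(resname, [aname], [pos])
            placed += 1

    _place_cloud(spec.n_waters, "SOL", "OW", "waters")
    _place_cloud(spec.n_counterions, "CL", "CL", "ions")

    names = np.asarray(b.names, dtype=object)
    resnames = np.asarray(b.resnames, dtype=object)
    resids = np.asarray(b.resids, dtype=int)
    roles = default_roles(spec)
    system = annotate(names, resnames, resids, roles)

    coords0 = b.positions()
    np_idx = (
        np.concatenate([np.asarray(g) for g in np_parts]) if np_parts else np.empty(0, dtype=int)
    )

    times = spec.frame_times()
    heights = spec.np_heights(times)
    xy = spec.np_center_xy()
    frames = np.empty((spec.n_frames, len(names), 3))
    park_base = np.asarray([0.25, 0.25, box[2] - 0.3])
    for f, (t, h) in enumerate(zip(times, heights)):
        c = coords0.copy()
        if spec.include_np:
            centre = np.asarray([xy[0], xy[1], midplane + h])
            if spec.ligand_tumbling and lig_idx:
                new_dirs = _uniform_sphere(rng["tumbling"], spec.n_ligands)
                az = rng["tumbling"].uniform(0.0, 2 * np.pi, size=spec.n_ligands)
                radii = np.full(spec.n_ligands, spec.extended_radius)
                if spec.n_coiled:
                    radii[-spec.n_coiled :] = spec.coiled_radius
                for li, u, r, a in zip(lig_idx, new_dirs, radii, az):
                    c[li] = _ligand_coords(u, r, spec.core_radius, a)
            c[np_idx] += centre
            for j, (plant, aidx) in enumerate(plant_records):
                if not plant.active(t):
                    c[aidx] = park_base + np.asarray([0.0, (j * 0.2) % (box[1] - 1.0), 0.0])
        frames[f] = c
    boxes = np.tile(box, (spec.n_frames, 1))
    trajectory = Trajectory(frames, boxes, times)
    return SyntheticTrajectory(
        spec=spec,
        system=system,
        trajectory=trajectory,
        roles=roles,
        np_indices=np_idx,
        plant_acceptors=plant_records,
        midplane_z=midplane if spec.include_membrane else float("nan"),
    )


def build_nanoparticle(spec: SyntheticSpec) -> tuple[AnnotatedSystem, Frame]:
    """Nanoparticle-only system (one configuration) in box coordinates."""
    s = replace(spec, include_membrane=False, n_frames=1, np_path=None)
    built = build_trajectory(s)
    return built.system, built.trajectory[0]


def build_membrane(spec: SyntheticSpec) -> tuple[AnnotatedSystem, Frame]:
    """Membrane-only system (one configuration)."""
    s = replace(spec, include_np=False, n_frames=1, np_path=None, hbond_plants=())
    built = build_trajectory(s)
    return built.system, built.trajectory[0]


# ---------------------------------------------------------------------------
# YAML round-trip for specs
# ---------------------------------------------------------------------------


def spec_to_dict(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["hbond_plants"] = [asdict(p) for p in spec.hbond_plants]
    d["np_path"] = [list(p) for p in spec.np_path] if spec.np_path else None
    d["alpha_law"] = list(spec.alpha_law)
    d["beta_law"] = list(spec.beta_law)
    d["tail_tilt_law"] = list(spec.tail_tilt_law)
    d["lipid_grid"] = list(spec.lipid_grid)
    return d


def spec_from_dict(d: dict) -> SyntheticSpec:
    d = dict(d)
    if d.get("hbond_plants"):
        d["hbond_plants"] = tuple(HBondPlant(**p) for p in d["hbond_plants"])
    else:
        d["hbond_plants"] = ()
    if d.get("np_path"):
        d["np_path"] = tuple(tuple(p) for p in d["np_path"])
    for key in ("alpha_law", "beta_law", "tail_tilt_law"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if "lipid_grid" in d:
        d["lipid_grid"] = tuple(d["lipid_grid"])
    return SyntheticSpec(**d)


def load_spec(path) -> SyntheticSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
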