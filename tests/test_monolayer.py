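"""Ligand-shell statistics: RDF, coiled classification, polar density, occupancy."""

import numpy as np
import pytest
from scipy import stats

from npmem.geometry import minimum_image
from npmem.io import Frame, Trajectory
from npmem.monolayer import (
    classify_coiled,
    core_com,
    headgroup_rdf,
    polar_density,
    shell_occupancy,
)
from npmem.synth import SyntheticSpec, build_nanoparticle, build_trajectory
from npmem.system import AnnotatedSystem


def _traj_of(frame, n=1):
    frames = [Frame(frame.coordinates, frame.box, time=10.0 * i) for i in range(n)]
    return Trajectory.from_frames(frames)


# --- core COM --------------------------------------------------------------


def _toy_core(coords, box):
    n = len(coords)
    sys_ = AnnotatedSystem(
        names=np.array(["AU"] * n, dtype=object),
        resnames=np.array(["AUC"] * n, dtype=object),
        resids=np.ones(n, dtype=int),
        elements=np.array(["Au"] * n, dtype=object),
    )
    sys_.core_atoms = np.arange(n)
    return sys_, Frame(np.asarray(coords, dtype=float), np.asarray(box, dtype=float))


def test_core_com_symmetric_pair_at_origin_offset():
    sys_, frame = _toy_core([[4.0, 5.0, 5.0], [6.0, 5.0, 5.0]], [10.0, 10.0, 10.0])
    np.testing.assert_allclose(core_com(sys_, frame), [5.0, 5.0, 5.0])


def test_core_com_single_atom_identity():
    sys_, frame = _toy_core([[1.0, 2.0, 3.0]], [10.0, 10.0, 10.0])
    np.testing.assert_allclose(core_com(sys_, frame), [1.0, 2.0, 3.0])


def test_core_com_across_periodic_boundary_stays_in_cluster():
    # cluster straddling x = 0: atoms at 9.8 and 0.2 in a 10-box -> COM at 0.0 (mod L)
    sys_, frame = _toy_core([[9.8, 5.0, 5.0], [0.2, 5.0, 5.0]], [10.0, 10.0, 10.0])
    com = core_com(sys_, frame)
    d = np.linalg.norm(minimum_image(com - np.array([10.0, 5.0, 5.0]), frame.box))
    assert d < 1e-9
    # 27-image oracle: COM must be within the cluster radius of both atoms
    for a in frame.coordinates:
        da = np.linalg.norm(minimum_image(com - a, frame.box))
        assert da <= 0.21


def test_core_com_empty_core_errors():
    sys_, frame = _toy_core([[1.0, 1.0, 1.0]], [5.0, 5.0, 5.0])
    sys_.core_atoms = np.empty(0, dtype=int)
    with pytest.raises(ValueError):
        core_com(sys_, frame)


# --- RDF -------------------------------------------------------------------


def test_rdf_delta_shell_concentrates_in_one_bin():
    spec = SyntheticSpec(seed=1, n_coiled=0, n_frames=1)
    sys_, frame = build_nanoparticle(spec)
    # bin width chosen so the planted 1.8 nm radius is a bin interior point
    rdf = headgroup_rdf(sys_, _traj_of(frame), bin_width=0.08, normalization="count")
    occupied = np.nonzero(rdf.values)[0]
    assert len(occupied) == 1
    lo, hi = rdf.bin_edges[occupied[0]], rdf.bin_edges[occupied[0] + 1]
    assert lo <= spec.extended_radius < hi
    assert rdf.values[occupied[0]] == 60


def test_rdf_two_population_secondary_peak():
    spec = SyntheticSpec(seed=1, n_coiled=2, n_frames=1)
    sys_, frame = build_nanoparticle(spec)
    rdf = headgroup_rdf(sys_, _traj_of(frame), bin_width=0.1)
    centers = rdf.bin_centers
    main_r, _ = rdf.peak()
    assert abs(main_r - 1.8) <= 0.1
    inner = centers < 1.55
    secondary_r = centers[inner][np.argmax(rdf.values[inner])]
    assert abs(secondary_r - 1.3) <= 0.1


def test_rdf_mass_conservation_every_frame(bound_system):
    sys_ = bound_system.system
    traj = bound_system.trajectory
    rdf = headgroup_rdf(sys_, traj, bin_width=0.05, normalization="count")
    # mean per-bin counts sum to the ligand count; delta shells make this exact
    assert rdf.values.sum() == pytest.approx(len(sys_.ligands))


def test_rdf_uniform_shell_density_constant(rng):
    # uniform placement inside a spherical shell -> flat number density
    n = 40_000
    r = (rng.uniform(1.0**3, 2.0**3, size=n)) ** (1.0 / 3.0)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    box = np.array([20.0, 20.0, 20.0])
    coords = 10.0 + r[:, None] * u
    names = np.array(["CZ"] * n, dtype=object)
    sys_ = AnnotatedSystem(
        names=names,
        resnames=np.array(["LIG"] * n, dtype=object),
        resids=np.arange(1, n + 1),
        elements=names.copy(),
    )
    from npmem.system import Ligand

    sys_.core_atoms = np.array([0])  # degenerate core at one point
    coords[0] = [10.0, 10.0, 10.0]
    sys_.ligands = [Ligand(atoms=(i,), headgroup=(i,), head_rep=i) for i in range(1, n)]
    frame = Frame(coords, box)
    rdf = headgroup_rdf(sys_, _traj_of(frame), bin_width=0.1, r_max=2.5)
    rho = (n - 1) / (4.0 / 3.0 * np.pi * (2.0**3 - 1.0**3))
    sel = (rdf.bin_centers > 1.1) & (rdf.bin_centers < 1.9)
    for c, v in zip(rdf.bin_centers[sel], rdf.values[sel]):
        shell_n = rho * 4 * np.pi * c**2 * 0.1
        assert abs(v - rho) < 3.0 * np.sqrt(shell_n) / (4 * np.pi * c**2 * 0.1)


def test_rdf_requires_headgroups():
    sys_, frame = _toy_core([[1.0, 1.0, 1.0]], [5.0, 5.0, 5.0])
    with pytest.raises(ValueError, match="headgroup"):
        headgroup_rdf(sys_, _traj_of(frame))


# --- coiled classification -------------------------------------------------


def test_planted_two_of_sixty_coiled_fraction(bound_system):
    res = classify_coiled(bound_system.system, bound_system.trajectory, r_threshold=1.55)
    assert res.fraction == pytest.approx(2.0 / 60.0)
    assert np.all(res.counts == 2)


def test_all_extended_zero_fraction():
    spec = SyntheticSpec(seed=2, n_coiled=0, n_frames=3, lipid_grid=(5, 5))
    built = build_trajectory(spec)
    res = classify_coiled(built.system, built.trajectory)
    assert res.fraction == 0.0


def test_threshold_below_core_radius_warns_and_counts_zero(bound_system):
    with pytest.warns(UserWarning, match="core"):
        res = classify_coiled(bound_system.system, bound_system.trajectory, r_threshold=0.5)
    assert res.fraction == 0.0


def test_coiled_count_monotone_in_threshold(bound_system):
    prev = -1
    for thr in (1.0, 1.4, 1.6, 1.9, 2.5):
        res = classify_coiled(bound_system.system, bound_system.trajectory, r_threshold=thr)
        total = int(res.counts.sum())
        assert total >= prev
        prev = total


# --- polar density ---------------------------------------------------------


def test_uniform_shell_all_ratios_near_one():
    spec = SyntheticSpec(
        seed=21, n_ligands=4000, n_coiled=0, south_pole_ligand=False,
        include_membrane=False, n_frames=1,
    )
    sys_, frame = build_nanoparticle(spec)
    pd = polar_density(sys_, _traj_of(frame), "headgroup", shell=(1.0, 2.2), n_bins=12)
    total = pd.counts.sum()
    edges = np.radians(pd.bin_edges)
    p = (np.cos(edges[:-1]) - np.cos(edges[1:])) / 2.0
    for ratio, pi, c in zip(pd.values, p, pd.counts):
        sigma_ratio = np.sqrt(total * pi * (1 - pi)) / (total * pi)
        assert abs(ratio - 1.0) < 3.5 * sigma_ratio


def test_all_mass_in_south_bin_closed_form():
    # one ligand straight down (south pole convention theta=180), membrane-free
    spec = SyntheticSpec(
        seed=3, n_ligands=1, n_coiled=0, south_pole_ligand=True,
        include_membrane=False, n_frames=1,
    )
    sys_, frame = build_nanoparticle(spec)
    # membrane-free: polar axis is +z, so the planted -z ligand is the south bin
    pd = polar_density(sys_, _traj_of(frame), "headgroup", shell=(1.0, 2.2), n_bins=18)
    domega_south = 2 * np.pi * (np.cos(np.radians(170.0)) - np.cos(np.radians(180.0)))
    assert pd.values[-1] == pytest.approx(4 * np.pi / domega_south)
    assert np.all(pd.values[:-1] == 0)


def test_planted_southern_enrichment_matches_analytic_ratio(rng):
    # 70% of points at theta > 150 deg, 30% uniform elsewhere: per-bin ratio
    # follows from the planted solid-angle split
    n = 30_000
    cos_south = np.cos(np.radians(150.0))
    u_s = rng.uniform(-1.0, cos_south, size=int(0.7 * n))
    u_r = rng.uniform(cos_south, 1.0, size=n - len(u_s))
    cost = np.r_[u_s, u_r]
    phi = rng.uniform(0, 2 * np.pi, size=n)
    sint = np.sqrt(1 - cost**2)
    r = rng.uniform(1.2, 2.0, size=n)
    pts = np.c_[sint * np.cos(phi), sint * np.sin(phi), cost] * r[:, None]
    box = np.array([20.0, 20.0, 20.0])
    coords = np.vstack([[0.0, 0.0, 0.0], pts]) + 10.0
    names = np.array(["CZ"] * (n + 1), dtype=object)
    sys_ = AnnotatedSystem(
        names=names,
        resnames=np.array(["LIG"] * (n + 1), dtype=object),
        resids=np.arange(1, n + 2),
        elements=names.copy(),
    )
    from npmem.system import Ligand

    sys_.core_atoms = np.array([0])
    sys_.ligands = [Ligand(atoms=(i,), headgroup=(i,), head_rep=i) for i in range(1, n + 1)]
    pd = polar_density(sys_, _traj_of(Frame(coords, box)), "headgroup", shell=(1.0, 2.2), n_bins=6)
    # southern band is the last bin (150-180): planted fraction 0.7 over
    # solid-angle fraction (1-cos30)/2
    frac_south = (1.0 - np.cos(np.radians(30.0))) / 2.0
    expected_south = 0.7 / frac_south
    assert pd.values[-1] == pytest.approx(expected_south, rel=0.03)
    expected_north = 0.3 / (1.0 - frac_south)
    np.testing.assert_allclose(pd.values[:-1], expected_north, rtol=0.05)


def test_uniform_cloud_passes_chi2_uniformity_across_seeds():
    # seeded uniform shells must look uniform at alpha=0.01 in >=99/100 seeds
    n_pass = 0
    for seed in range(100):
        spec = SyntheticSpec(
            seed=seed, n_ligands=600, n_coiled=0, south_pole_ligand=False,
            include_membrane=False, n_frames=1,
        )
        sys_, frame = build_nanoparticle(spec)
        pd = polar_density(sys_, _traj_of(frame), "headgroup", shell=(1.0, 2.2), n_bins=12)
        edges = np.radians(pd.bin_edges)
        p = (np.cos(edges[:-1]) - np.cos(edges[1:])) / 2.0
        expected = pd.counts.sum() * p
        chi2 = float(np.sum((pd.counts - expected) ** 2 / expected))
        if stats.chi2.sf(chi2, df=len(p) - 1) > 0.01:
            n_pass += 1
    assert n_pass >= 99


def test_empty_shell_errors(bound_system):
    with pytest.raises(ValueError, match="shell"):
        polar_density(bound_system.system, bound_system.trajectory, "counterion", shell=(0.1, 0.2))


# --- shell occupancy -------------------------------------------------------


def test_planted_shell_counterions_counted_every_frame():
    spec = SyntheticSpec(seed=6, n_frames=5, shell_counterions=5, lipid_grid=(5, 5))
    built = build_trajectory(spec)
    occ = shell_occupancy(built.system, built.trajectory, "counterion", shell=(0.95, 2.2))
    assert np.all(occ.counts == 5)
    assert occ.mean == 5.0


def test_counterions_outside_shell_count_zero():
    spec = SyntheticSpec(seed=6, n_frames=3, n_counterions=10, lipid_grid=(9, 9))
    built = build_trajectory(spec)
    occ = shell_occupancy(built.system, built.trajectory, "counterion", shell=(0.95, 2.2))
    assert np.all(occ.counts == 0)


def test_uniform_gas_occupancy_matches_poisson_expectation():
    spec = SyntheticSpec(
        seed=8, n_frames=1, n_waters=4000, include_membrane=False,
        cloud_excludes_np=False, n_ligands=1, n_coiled=0,
    )
    built = build_trajectory(spec)
    shell = (1.5, 3.0)
    occ = shell_occupancy(built.system, built.trajectory, "water", shell=shell)
    box = built.trajectory[0].box
    v_shell = 4.0 / 3.0 * np.pi * (shell[1] ** 3 - shell[0] ** 3)
    lam = 4000 * v_shell / np.prod(box)
    assert abs(occ.mean - lam) < 3.0 * np.sqrt(lam)
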