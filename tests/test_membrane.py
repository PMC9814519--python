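"""Headgroup angles, deformation maps, thickness and tail order."""

import numpy as np
import pytest

from npmem.io import Frame, Trajectory
from npmem.membrane import (
    alpha_angle,
    angle_map,
    beta_angle,
    leaflet_assignment,
    order_parameter,
    thickness_map,
)
from npmem.synth import SyntheticSpec, build_trajectory
from npmem.system import AnnotatedSystem, Lipid


def _two_lipid_system(p_up, n_up, p_lo, n_lo, box=(10.0, 10.0, 10.0)):
    names = np.array(["P", "N", "P", "N"], dtype=object)
    sys_ = AnnotatedSystem(
        names=names,
        resnames=np.array(["PC"] * 4, dtype=object),
        resids=np.array([1, 1, 2, 2]),
        elements=names.copy(),
    )
    sys_.lipids = [Lipid(resid=1, p_site=0, n_site=1), Lipid(resid=2, p_site=2, n_site=3)]
    frame = Frame(np.array([p_up, n_up, p_lo, n_lo], dtype=float), np.array(box))
    return sys_, frame


@pytest.mark.parametrize(
    "v_pn,expected",
    [
        ((0.0, 0.0, 0.45), 0.0),  # straight up in the upper leaflet
        ((0.45, 0.0, 0.0), 90.0),  # in-plane
        ((0.3, 0.0, 0.3), 45.0),  # closed form
        ((0.0, 0.0, -0.45), 180.0),  # pointing into the bilayer
    ],
)
def test_alpha_closed_forms_upper_leaflet(v_pn, expected):
    p = np.array([5.0, 5.0, 7.0])
    sys_, frame = _two_lipid_system(p, p + v_pn, [5.0, 5.0, 3.0], [5.0, 5.0, 2.55])
    assert alpha_angle(sys_, 0, frame, "upper") == pytest.approx(expected, abs=1e-9)


def test_alpha_lower_leaflet_uses_outward_normal():
    # lower-leaflet P->N pointing down (outward) is alpha = 0
    sys_, frame = _two_lipid_system(
        [5.0, 5.0, 7.0], [5.0, 5.0, 7.45], [5.0, 5.0, 3.0], [5.0, 5.0, 2.55]
    )
    assert alpha_angle(sys_, 1, frame, "lower") == pytest.approx(0.0, abs=1e-9)


def test_alpha_degenerate_lipid_errors():
    p = [5.0, 5.0, 7.0]
    sys_, frame = _two_lipid_system(p, p, [5.0, 5.0, 3.0], [5.0, 5.0, 2.55])
    with pytest.raises(ValueError, match="degenerate"):
        alpha_angle(sys_, 0, frame, "upper")


@pytest.mark.parametrize(
    "n_offset,expected",
    [
        ((0.45, 0.0, 0.0), 0.0),  # N directly away from the NP projection
        ((0.0, 0.45, 0.0), 90.0),  # perpendicular
        ((-0.45, 0.0, 0.0), 180.0),  # pointing back at the NP
    ],
)
def test_beta_closed_forms(n_offset, expected):
    np_com = [5.0, 5.0, 9.0]
    p = np.array([7.0, 5.0, 7.0])  # NP->P projection along +x
    sys_, frame = _two_lipid_system(p, p + n_offset, [5.0, 5.0, 3.0], [5.0, 5.0, 2.55])
    assert beta_angle(sys_, 0, frame, np_com) == pytest.approx(expected, abs=1e-9)


def test_beta_undefined_when_projection_vanishes():
    np_com = [5.0, 5.0, 9.0]
    p = np.array([5.0, 5.0, 7.0])  # lipid directly under the NP: v1 projects to 0
    sys_, frame = _two_lipid_system(p, p + [0.45, 0, 0], [5.0, 5.0, 3.0], [5.0, 5.0, 2.55])
    assert beta_angle(sys_, 0, frame, np_com) is None


def test_leaflet_assignment_and_midplane(bound_system):
    frame = bound_system.trajectory[0]
    labels, mid = leaflet_assignment(bound_system.system, frame)
    assert mid == pytest.approx(bound_system.midplane_z, abs=1e-6)
    n = len(labels)
    assert np.sum(labels == "upper") == n // 2
    assert np.sum(labels == "lower") == n // 2


# --- maps ------------------------------------------------------------------


def test_delta_alpha_map_every_cell_exact(bound_system):
    m = angle_map(bound_system.system, bound_system.trajectory, "alpha", grid_shape=(8, 8))
    filled = m.values[m.counts > 0]
    np.testing.assert_allclose(filled, 67.0, atol=1e-9)
    assert m.global_mean == pytest.approx(67.0)


def test_point_outward_beta_map_is_zero():
    spec = SyntheticSpec(seed=4, n_frames=2, lipid_grid=(8, 8))
    tgt = spec.np_center_xy()
    spec = SyntheticSpec(
        seed=4, n_frames=2, lipid_grid=(8, 8),
        beta_law=("point_outward", float(tgt[0]), float(tgt[1])),
    )
    built = build_trajectory(spec)
    m = angle_map(built.system, built.trajectory, "beta", grid_shape=(8, 8))
    filled = m.values[m.counts > 0]
    np.testing.assert_allclose(filled, 0.0, atol=1e-4)


def test_fixed_offset_beta_map_recovers_offset():
    spec = SyntheticSpec(seed=4, n_frames=1, lipid_grid=(8, 8), beta_law=("fixed_offset", 60.0))
    built = build_trajectory(spec)
    m = angle_map(built.system, built.trajectory, "beta", grid_shape=(8, 8))
    filled = m.values[m.counts > 0]
    np.testing.assert_allclose(filled, 60.0, atol=1e-6)


def test_map_global_mean_equals_unbinned_mean(bound_system):
    from npmem.membrane import _alpha_all

    spec = SyntheticSpec(
        seed=10, n_frames=3, lipid_grid=(8, 8), alpha_law=("uniform_cone", 40.0, 90.0)
    )
    built = build_trajectory(spec)
    m = angle_map(built.system, built.trajectory, "alpha", grid_shape=(5, 5))
    vals = []
    for frame in built.trajectory:
        labels, _ = leaflet_assignment(built.system, frame)
        vals.append(_alpha_all(built.system, frame, labels))
    assert m.global_mean == pytest.approx(float(np.mean(vals)))


def test_empty_window_errors(bound_system):
    with pytest.raises(ValueError, match="window"):
        angle_map(bound_system.system, bound_system.trajectory, "alpha", window=slice(5, 5))


def test_flat_membrane_thickness_everywhere(bound_system):
    m = thickness_map(bound_system.system, bound_system.trajectory, grid_shape=(8, 8))
    filled = m.values[m.counts > 0]
    np.testing.assert_allclose(filled, 4.0, atol=1e-9)
    assert m.global_mean == pytest.approx(4.0)


def test_planted_dimple_depth_recovered():
    spec = SyntheticSpec(seed=5, n_frames=2, dimple_depth=0.4, dimple_sigma=1.2)
    built = build_trajectory(spec)
    m = thickness_map(built.system, built.trajectory, grid_shape=(16, 16))
    filled = m.values[m.counts > 0]
    # minimum at the dimple centre: 4.0 - 0.4, within grid discretisation of
    # the Gaussian (cell centres may miss the exact minimum)
    assert np.nanmin(m.values) == pytest.approx(3.6, abs=0.05)
    far = filled[filled > 3.95]
    assert len(far) > 0  # far field untouched


def test_thickness_translation_invariance():
    spec = SyntheticSpec(seed=6, n_frames=1, lipid_grid=(8, 8))
    built = build_trajectory(spec)
    m1 = thickness_map(built.system, built.trajectory, grid_shape=(8, 8))
    # shift all coordinates by exactly one grid cell in x (cell = box_x / 8)
    box = built.trajectory[0].box
    shift = np.array([box[0] / 8.0, 0.0, 0.0])
    coords = (built.trajectory.coordinates + shift) % box
    shifted = Trajectory(coords, built.trajectory.boxes, built.trajectory.times)
    m2 = thickness_map(built.system, shifted, grid_shape=(8, 8))
    np.testing.assert_allclose(np.roll(m1.values, 1, axis=0), m2.values, atol=1e-9)


def test_one_leaflet_cells_are_empty():
    # remove the lower leaflet: every cell must be flagged empty (NaN)
    spec = SyntheticSpec(seed=6, n_frames=1, lipid_grid=(6, 6))
    built = build_trajectory(spec)
    frame = built.trajectory[0]
    labels, _ = leaflet_assignment(built.system, frame)
    upper = [lp for lp, lab in zip(built.system.lipids, labels) if lab == "upper"]
    built.system.lipids = upper
    m = thickness_map(built.system, built.trajectory, grid_shape=(6, 6))
    assert np.all(m.counts == 0)
    assert np.all(np.isnan(m.values))


# --- order parameter -------------------------------------------------------


def test_straight_tails_give_unit_order(bound_system):
    s = order_parameter(bound_system.system, bound_system.trajectory, window=slice(0, 2))
    np.testing.assert_allclose(s, 1.0, atol=1e-9)


def test_in_plane_tails_give_minus_half():
    spec = SyntheticSpec(seed=2, n_frames=1, lipid_grid=(6, 6), tail_tilt_law=("delta", 90.0))
    built = build_trajectory(spec)
    s = order_parameter(built.system, built.trajectory)
    np.testing.assert_allclose(s, -0.5, atol=1e-9)


def test_isotropic_tails_give_zero():
    spec = SyntheticSpec(seed=3, n_frames=1, lipid_grid=(16, 16), tail_tilt_law=("isotropic",))
    built = build_trajectory(spec)
    s = order_parameter(built.system, built.trajectory)
    # 512 lipids x 2 chains x 6 segments per carbon position; var of
    # (3cos^2-1)/2 under isotropy is 1/5
    n_samples = 2 * 16 * 16 * 2
    assert np.all(np.abs(s) < 3.0 * np.sqrt(0.2 / n_samples))


def test_short_chains_skipped():
    spec = SyntheticSpec(seed=2, n_frames=1, lipid_grid=(4, 4), n_tail_beads=2)
    built = build_trajectory(spec)
    with pytest.raises(ValueError, match="3 beads"):
        order_parameter(built.system, built.trajectory)
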