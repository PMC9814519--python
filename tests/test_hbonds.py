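"""Geometric H-bond detection against an independent all-pairs oracle."""

import numpy as np
import pytest

from npmem.io import Frame, Trajectory
from npmem.hbonds import detect_hbonds, ledger
from npmem.synth import HBondPlant, SyntheticSpec, build_trajectory
from npmem.system import AnnotatedSystem, AnnotationError, DonorTriplet

from conftest import PAPER_CELLS


def _triplet_system(d_pos, h_pos, a_pos, box=(10.0, 10.0, 10.0)):
    """One donor-H plus one water acceptor at given positions."""
    names = np.array(["N", "H", "OW"], dtype=object)
    sys_ = AnnotatedSystem(
        names=names,
        resnames=np.array(["LIG", "LIG", "SOL"], dtype=object),
        resids=np.array([1, 1, 2]),
        elements=names.copy(),
    )
    sys_.donors = [DonorTriplet(heavy=0, hydrogens=(1,), donor_class="eta")]
    sys_.acceptors = {"water": np.array([2])}
    frame = Frame(np.array([d_pos, h_pos, a_pos], dtype=float), np.array(box))
    return sys_, frame


def _acceptor_at(d, angle_deg_):
    """Acceptor at distance d from donor (origin), angle from the D-H axis (+x)."""
    a = np.radians(angle_deg_)
    return [5.0 + d * np.cos(a), 5.0 + d * np.sin(a), 5.0]


@pytest.mark.parametrize(
    "dist,angle,expected",
    [
        (0.30, 10.0, 1),  # inside both cutoffs
        (0.36, 10.0, 0),  # outside distance
        (0.30, 35.0, 0),  # outside angle
    ],
)
def test_single_triplet_cutoff_cases(dist, angle, expected):
    sys_, frame = _triplet_system(
        [5.0, 5.0, 5.0], [5.1, 5.0, 5.0], _acceptor_at(dist, angle)
    )
    recs = detect_hbonds(sys_, frame)
    assert len(recs) == expected


def test_distance_cutoff_is_inclusive():
    # acceptor exactly at the cutoff distance (0.25 is float-exact)
    sys_, frame = _triplet_system([5.0, 5.0, 5.0], [5.1, 5.0, 5.0], [5.25, 5.0, 5.0])
    assert len(detect_hbonds(sys_, frame, d_cut=0.25)) == 1
    assert len(detect_hbonds(sys_, frame, d_cut=0.2499999)) == 0


def test_bond_found_across_periodic_boundary():
    # donor at box edge, acceptor wrapped to the other side
    sys_, frame = _triplet_system(
        [9.9, 5.0, 5.0], [0.0, 5.0, 5.0], [0.2, 5.0, 5.0]
    )
    recs = detect_hbonds(sys_, frame)
    assert len(recs) == 1
    assert recs[0].distance == pytest.approx(0.3)


def test_missing_hydrogen_is_annotation_error():
    sys_, frame = _triplet_system([5, 5, 5], [5.1, 5, 5], [5.3, 5, 5])
    sys_.donors = [DonorTriplet(heavy=0, hydrogens=(), donor_class="eta")]
    with pytest.raises(AnnotationError):
        detect_hbonds(sys_, frame)


def _random_water_system(rng, n_donors=100, n_acceptors=150, box=3.0):
    """Random water-like donors (O with two H) and acceptor oxygens."""
    names, resnames, resids, coords = [], [], [], []
    donors = []
    rid = 1
    def unit(v):
        return v / np.linalg.norm(v)

    for _ in range(n_donors):
        o = rng.uniform(0, box, 3)
        i0 = len(names)
        names += ["OW", "HW1", "HW2"]
        resnames += ["DON"] * 3
        resids += [rid] * 3
        coords += [o, o + 0.1 * unit(rng.normal(size=3)), o + 0.1 * unit(rng.normal(size=3))]
        donors.append(DonorTriplet(heavy=i0, hydrogens=(i0 + 1, i0 + 2), donor_class="other"))
        rid += 1
    acc0 = len(names)
    for _ in range(n_acceptors):
        names.append("OW")
        resnames.append("ACC")
        resids.append(rid)
        coords.append(rng.uniform(0, box, 3))
        rid += 1
    sys_ = AnnotatedSystem(
        names=np.array(names, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids),
        elements=np.array(names, dtype=object),
    )
    sys_.donors = donors
    sys_.acceptors = {"water": np.arange(acc0, len(names))}
    frame = Frame(np.array(coords, dtype=float), np.array([box] * 3))
    return sys_, frame


def _oracle_count(sys_, frame, d_cut=0.35, angle_cut=30.0):
    """Independent all-pairs reference, written from the criterion directly."""
    box = frame.box
    c = frame.coordinates
    n = 0
    for don in sys_.donors:
        for a in sys_.acceptors["water"]:
            da = c[a] - c[don.heavy]
            da = da - box * np.round(da / box)
            if np.linalg.norm(da) > d_cut:
                continue
            for h in don.hydrogens:
                dh = c[h] - c[don.heavy]
                dh = dh - box * np.round(dh / box)
                cosang = np.dot(dh, da) / (np.linalg.norm(dh) * np.linalg.norm(da))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= angle_cut:
                    n += 1
    return n


def test_detector_equals_all_pairs_oracle_on_random_frames():
    rng = np.random.default_rng(1234)
    for _ in range(100):
        sys_, frame = _random_water_system(rng)
        fast = len(detect_hbonds(sys_, frame))
        assert fast == _oracle_count(sys_, frame)
        assert fast > 0  # dense boxes: the comparison must be non-trivial


def test_counts_monotone_in_cutoffs():
    rng = np.random.default_rng(7)
    sys_, frame = _random_water_system(rng)
    base = len(detect_hbonds(sys_, frame, d_cut=0.30, angle_cut=20.0))
    wider_d = len(detect_hbonds(sys_, frame, d_cut=0.40, angle_cut=20.0))
    wider_a = len(detect_hbonds(sys_, frame, d_cut=0.30, angle_cut=40.0))
    assert wider_d >= base and wider_a >= base


# --- ledger ----------------------------------------------------------------


def test_planted_partition_reproduces_paper_cells(partition_system):
    led = ledger(partition_system.system, partition_system.trajectory)
    for (dc, ac), n in PAPER_CELLS.items():
        assert led.mean(dc, ac) == float(n)
    assert led.eta_total == 182.0
    assert led.epsilon_total == 42.0
    assert led.np_bilayer_total == 27.0
    assert led.grand_total == 224.0


def test_additivity_grand_total_every_frame(partition_system):
    df = led_df = ledger(partition_system.system, partition_system.trajectory).per_frame
    per_frame_totals = df.groupby("frame")["count"].sum()
    for f, total in per_frame_totals.items():
        cells = df[df.frame == f].set_index(["donor_class", "acceptor_class"])["count"]
        assert total == cells.sum()
        assert total == 224


def test_no_acceptors_all_cells_zero():
    spec = SyntheticSpec(seed=2, n_frames=2, include_membrane=False)
    built = build_trajectory(spec)
    built.system.acceptors = {}
    led = ledger(built.system, built.trajectory)
    assert led.grand_total == 0.0


def test_mean_invariant_under_frame_shuffle(partition_system):
    traj = partition_system.trajectory
    order = np.array([2, 0, 3, 1])
    shuffled = Trajectory(
        traj.coordinates[order], traj.boxes[order], traj.times
    )  # times stay increasing; frames permuted
    a = ledger(partition_system.system, traj)
    b = ledger(partition_system.system, shuffled)
    for key in a.cells:
        assert a.cells[key]["mean"] == b.cells[key]["mean"]


def test_empty_window_errors(partition_system):
    with pytest.raises(ValueError, match="window"):
        ledger(partition_system.system, partition_system.trajectory, window=slice(3, 3))


def test_plants_inactive_outside_window():
    plants = (HBondPlant(0.30, 10.0, "eta", "water", count=5, active_from_ps=20.0),)
    spec = SyntheticSpec(seed=3, n_frames=4, hbond_plants=plants, include_membrane=False)
    built = build_trajectory(spec)
    led = ledger(built.system, built.trajectory)
    counts = (
        led.per_frame[led.per_frame.donor_class == "eta"]
        .groupby("frame")["count"]
        .sum()
        .to_numpy()
    )
    np.testing.assert_array_equal(counts, [0, 0, 5, 5])
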