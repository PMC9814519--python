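import numpy as np
import pytest

from npmem.synth import HBondPlant, SyntheticSpec, build_trajectory

PAPER_CELLS = {
    ("eta", "water"): 159,
    ("eta", "phosphate"): 23,
    ("epsilon", "water"): 38,
    ("epsilon", "phosphate"): 4,
}


@pytest.fixture()
def rng():
    # fresh deterministic stream per test so draws are order-independent
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_spec():
    """A small bound-state system: NP drops onto the membrane at 100 ps."""
    spec = SyntheticSpec(seed=7, n_frames=30)
    zb = spec.bound_height()
    return SyntheticSpec(
        seed=7,
        n_frames=30,
        np_path=((0.0, 6.0), (90.0, 6.0), (100.0, zb), (290.0, zb)),
    )


@pytest.fixture(scope="session")
def bound_system(small_spec):
    return build_trajectory(small_spec)


@pytest.fixture(scope="session")
def partition_system():
    """Ledger fixture with the four-cell H-bond partition planted per frame."""
    plants = tuple(
        HBondPlant(0.30, 10.0, dc, ac, count=n) for (dc, ac), n in PAPER_CELLS.items()
    )
    spec = SyntheticSpec(seed=11, n_frames=4, hbond_plants=plants)
    return build_trajectory(spec)
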