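import numpy as np
import pytest

from triloci import SimulationSpec, TripletDataset, constraint_regimes, simulate_from_zones


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_dataset(rng):
    """100 nuclei with coordinates uniform in a 2 um box."""
    coords = rng.uniform(0.0, 2.0, size=(100, 3, 3))
    return TripletDataset(coords, [f"n{i:03d}" for i in range(100)])


@pytest.fixture
def moderate_dataset():
    """500 nuclei simulated from the moderately constrained zone model."""
    spec = SimulationSpec(model=constraint_regimes()["moderate"], n=500, seed=77)
    return simulate_from_zones(spec)
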