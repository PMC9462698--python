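import numpy as np
import pytest

from xcevolve.fitting import DataPoint, EnergyDataset
from xcevolve.functionals import GridSystem
from xcevolve.synth import SyntheticSpec, b97_ground_truth, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220909)


@pytest.fixture(scope="session")
def b97_truth():
    return b97_ground_truth()


@pytest.fixture(scope="session")
def small_dataset(b97_truth):
    """Noiseless dataset generated from the B97 exchange ground truth."""
    functional, params = b97_truth
    spec = SyntheticSpec(n_systems=10, points_per_system=16, n_datapoints=60,
                         seed=11)
    return generate_dataset(spec, functional, params)


@pytest.fixture()
def toy_dataset():
    """Hand-sized dataset: two one-point systems, three data points."""
    sys_a = GridSystem("a", rho=[1.0], x2=[0.0], w=[0.0], quad_weights=[2.0])
    sys_b = GridSystem("b", rho=[1.0], x2=[100.0], w=[0.0], quad_weights=[1.0])
    dps = [
        DataPoint("d0", (("a", 1.0),), reference=0.0, data_type="TCE", weight=1.0),
        DataPoint("d1", (("a", 1.0), ("b", -1.0)), reference=0.0,
                  data_type="TCE", weight=4.0),
        DataPoint("d2", (("b", 1.0),), reference=1.0, data_type="RG10", weight=2.0),
    ]
    return EnergyDataset(
        systems={"a": sys_a, "b": sys_b},
        splits={"train": dps[:2], "validation": dps[2:], "test": []},
    )
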