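import numpy as np
import pytest

from fluorstab.synthetic import GeneratorSpec
from fluorstab.twostate import TwoStateParams


@pytest.fixture(scope="session")
def default_spec():
    """The study-design generator spec, seed 1."""
    return GeneratorSpec(seed=1)


@pytest.fixture(scope="session")
def noiseless_spec():
    return GeneratorSpec(seed=1, noise_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_surfaces(noiseless_spec):
    from fluorstab.synthetic import generate_dataset
    return generate_dataset(noiseless_spec)


@pytest.fixture
def sharp_params():
    """A well-behaved reference parameter set: Tm 353.15 K (80 °C)."""
    return TwoStateParams(I_N=20000.0, a=-30.0, I_D=30000.0, b=-40.0,
                          Tm=353.15, dHvh=500e3)


def random_valid_params(rng: np.random.Generator) -> TwoStateParams:
    """Random parameters satisfying the model invariants, for property tests."""
    tm = rng.uniform(330.0, 370.0)
    i_n = rng.uniform(1000.0, 20000.0)
    a = rng.uniform(-0.002, -0.0001) * i_n
    i_d = i_n * rng.uniform(1.5, 3.0)
    b = rng.uniform(-0.0015, -0.0002) * i_d
    p = TwoStateParams(I_N=i_n, a=a, I_D=i_d, b=b, Tm=tm,
                       dHvh=rng.uniform(100e3, 900e3))
    p.validate()
    return p
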