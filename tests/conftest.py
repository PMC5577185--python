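import numpy as np
import pytest

from dfsbind import BondModelParams, ExperimentDesign, NoiseModel


@pytest.fixture
def params_a() -> BondModelParams:
    """Reference bond: f_eq = 50 pN, x_t = 0.30 nm, k_u = 1/s, T = 298 K."""
    return BondModelParams(f_eq=50e-12, x_t=0.30e-9, k_u=1.0, temperature=298.0)


@pytest.fixture
def default_design() -> ExperimentDesign:
    return ExperimentDesign()


@pytest.fixture
def quiet_noise() -> NoiseModel:
    return NoiseModel(force_noise_sd=0.0)


def random_params(rng: np.random.Generator) -> BondModelParams:
    """Random physically plausible bond parameters for property tests."""
    return BondModelParams(
        f_eq=rng.uniform(5e-12, 200e-12),
        x_t=rng.uniform(0.05e-9, 2e-9),
        k_u=10.0 ** rng.uniform(-2, 3),
        temperature=rng.uniform(278.0, 318.0),
    )
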