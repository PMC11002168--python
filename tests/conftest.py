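import numpy as np
import pytest

from ifndyn import FITTED_REGIMES, ModelParameters, NoiseModel


@pytest.fixture(scope="session")
def low_dose() -> ModelParameters:
    return FITTED_REGIMES["CpG-C 0.5 ug/mL"]


@pytest.fixture(scope="session")
def noiseless() -> NoiseModel:
    """Infinite-well, zero-CV measurement model (LOQ censoring still applies)."""
    return NoiseModel(n_cells_per_well=None, elisa_cv=0.0, replicate_count=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
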