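import numpy as np
import pytest

from olfrisk.core import LabConstants, ToxTable, load_tox_table
from olfrisk.distributions import TruncatedGaussianSpec
from olfrisk.risk import CategoryRiskInputs, ExposureModel
from olfrisk.synthetic import default_tox_frame


@pytest.fixture(scope="session")
def tox() -> ToxTable:
    return load_tox_table(default_tox_frame())


@pytest.fixture
def constants() -> LabConstants:
    return LabConstants()


@pytest.fixture
def exposure(constants) -> ExposureModel:
    """Dispersed but benign exposure parameters."""
    return ExposureModel(
        constants=constants,
        spec_n_pr=TruncatedGaussianSpec(9.5, 2.0, 6.0, 14.0),
        spec_f_s=TruncatedGaussianSpec(180.0, 90.0, 40.0, 400.0),
        spec_n_y=TruncatedGaussianSpec(5.0, 3.0, 1.0, 12.0),
    )


@pytest.fixture
def degenerate_exposure(constants) -> ExposureModel:
    """Point-mass exposure parameters (no randomness)."""
    return ExposureModel(
        constants=constants,
        spec_n_pr=TruncatedGaussianSpec(10.0, 0.0, 10.0, 10.0),
        spec_f_s=TruncatedGaussianSpec(100.0, 0.0, 100.0, 100.0),
        spec_n_y=TruncatedGaussianSpec(5.0, 0.0, 5.0, 5.0),
    )


@pytest.fixture
def two_compound_inputs(tox) -> CategoryRiskInputs:
    """Small mixed category: one carcinogen (benzene), one not (toluene)."""
    return CategoryRiskInputs(
        category="testcat",
        cin_specs={
            "benzene": TruncatedGaussianSpec(50.0, 20.0, 5.0, 120.0, n_obs=40),
            "toluene": TruncatedGaussianSpec(200.0, 80.0, 20.0, 500.0, n_obs=40),
        },
        tox=tox,
    )


def make_rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
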