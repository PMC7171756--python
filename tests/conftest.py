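import numpy as np
import pytest

from hcc_cea import basecase, simulate
from hcc_cea.cohort import ModelSettings
from hcc_cea.survival import SurvivalDistribution


@pytest.fixture(scope="session")
def fixture_bundle():
    """CELESTIAL-like input bundle with median-matched Weibull curves."""
    return simulate.celestial_fixture()


@pytest.fixture(scope="session")
def calibrated_models():
    """Table-calibrated country models (shared; expensive to rebuild)."""
    dists = basecase.calibrated_distributions()
    return {
        c: basecase.build_country_model(c, distributions=dists)
        for c in ("germany", "us")
    }


@pytest.fixture(scope="session")
def germany_model(calibrated_models):
    return calibrated_models["germany"]


@pytest.fixture
def settings():
    return ModelSettings()


@pytest.fixture
def weibull_13() -> SurvivalDistribution:
    """The fixture-shaped Weibull with median ~10.2 months."""
    return SurvivalDistribution.weibull(13.52, 1.3)


@pytest.fixture
def rng():
    return np.random.default_rng(20230423)
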