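import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def symmetric_setup():
    """Symmetric two-species community with climate and year effects drawn,
    shared by the simulation-level tests."""
    from quadratdyn import synthetic_data as sd
    rng = np.random.default_rng(3)
    truth = sd.scenario("symmetric-2sp")
    climate = sd.generate_climate(30, truth.climate_means, truth.climate_sds,
                                  rng)
    years = [int(y) for y in climate.years]
    community = sd.draw_year_effects(truth, years, rng)
    return truth, community, climate, years


@pytest.fixture(scope="session")
def small_archive():
    """Small tracked synthetic archive for pipeline-level unit tests."""
    from quadratdyn import synthetic_data as sd
    rng = np.random.default_rng(10)
    truth = sd.scenario("symmetric-2sp")
    return sd.generate_quadrat_series(truth, n_quadrats=2, n_years=15,
                                      rng=rng)
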