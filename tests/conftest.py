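import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import jorospread as j

settings.register_profile(
    "ci", database=None, derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def landscape():
    """Small multi-predictor landscape with known logistic truth."""
    spec = j.simulate.LandscapeSpec()
    layers, truth = j.simulate.make_landscape(spec, seed=11)
    return spec, layers, truth


@pytest.fixture(scope="session")
def sdm_table():
    """Labelled, standardized presence/background table (n=2000).

    Truth is logistic in a single predictor and suitable habitat is rare
    (~10% of cells): presence-background AUC is capped by how much of the
    landscape is suitable, so a strongly separable design needs a
    concentrated niche.
    """
    spec = j.simulate.LandscapeSpec(
        predictors=("x1", "x2"),
        coefficients={"x1": (7.0, 0.0), "x2": (0.0, 0.0)},
        intercept=-10.0,
    )
    layers, truth = j.simulate.make_landscape(spec, seed=7)
    occs = j.simulate.sample_presences(truth, 700, seed=8)
    pres = j.geodata.extract_values([(o.lon, o.lat) for o in occs], layers)
    bg = j.geodata.sample_background(layers[0], 1300, seed=9)
    bgv = j.geodata.extract_values(
        [(p.lon, p.lat) for p in bg], layers, label="background"
    )
    df = j.geodata.samples_to_frame(pres + bgv)
    std, params = j.sdm.standardize(df)
    return std, params, layers


@pytest.fixture(scope="session")
def spread_data():
    """Default radial-spread simulation plus its true edges."""
    occs, truth = j.simulate.simulate_spread(seed=21)
    return occs, truth, j.simulate.SpreadSpec()


@pytest.fixture(scope="session")
def survey_table():
    table, beta = j.simulate.simulate_surveys(seed=31)
    return j.simulate.attach_diversity(table), beta


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
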