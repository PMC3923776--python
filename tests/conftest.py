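import numpy as np
import pandas as pd
import pytest

from spatregime.gridding import mercator_correct
from spatregime.simulate import GeneratorConfig, generate_polygon_series


def make_hauls(lon, lat, year, response):
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    return pd.DataFrame(
        {
            "lon_raw": lon,
            "lat": lat,
            "lon_corr": mercator_correct(lon, lat),
            "year": np.asarray(year, int),
            "response": np.asarray(response, float),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20140213)


@pytest.fixture
def random_hauls(rng):
    """200 hauls over 4 years from a known degree-1 surface plus noise."""
    n = 200
    lon = rng.uniform(-5, 9, n)
    lat = rng.uniform(51, 61, n)
    year = rng.integers(2000, 2004, n)
    lc = mercator_correct(lon, lat)
    resp = 2.0 + 0.3 * lc - 0.1 * (lat - 56.0) + rng.normal(0, 0.5, n)
    return make_hauls(lon, lat, year, resp)


@pytest.fixture
def polygon_series():
    return generate_polygon_series(GeneratorConfig(), seed=11)
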