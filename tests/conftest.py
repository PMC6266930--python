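import numpy as np
import pytest

from geoenrich.geo_core import GeoPoint


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_points(rng):
    """Valid random coordinates away from poles/antimeridian edge cases."""

    def make(n, lat_range=(-80.0, 80.0), lon_range=(-170.0, 170.0)):
        lats = rng.uniform(*lat_range, n)
        lons = rng.uniform(*lon_range, n)
        return [GeoPoint(la, lo) for la, lo in zip(lats, lons)]

    return make
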