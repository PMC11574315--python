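import warnings

import numpy as np
import pytest

from phenomap.encoding import ObservationSeries
from phenomap.synthetic import SceneConfig, simulate_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_series(rng, n_obs=None, year=2018, with_cloudy=False):
    """A random valid observation series for property-style tests."""
    if n_obs is None:
        n_obs = int(rng.integers(0, 60))
    doy = np.sort(rng.choice(np.arange(1, 366), size=min(n_obs, 365), replace=False))
    values = rng.uniform(0, 1, (len(doy), 6))
    clear = (
        rng.random(len(doy)) < 0.8 if with_cloudy else np.ones(len(doy), bool)
    )
    return ObservationSeries(year=year, doy=doy, values=values, clear=clear)


@pytest.fixture(scope="session")
def small_scene():
    """A 15x15, 4-year scene with all 18 classes, shared across tests."""
    cfg = SceneConfig(
        shape=(15, 15), years=[2016, 2017, 2018, 2019], n_patches=20,
        peat_expansion_rate=1, seed=3,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_landscape(cfg)
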