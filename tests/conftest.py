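from datetime import date

import numpy as np
import pytest

import hatchphen as hp


@pytest.fixture(scope="session")
def lab_summary():
    return hp.load_incubation_summary()


@pytest.fixture(scope="session")
def lab_regimes():
    return hp.reconstruct_lab_regimes()


@pytest.fixture
def constant_series():
    def make(temp_c: float, n_days: int = 400, start: date = date(2016, 11, 1)):
        return hp.TemperatureSeries.from_values(start, np.full(n_days, temp_c))

    return make


@pytest.fixture(scope="session")
def river_series():
    spec = hp.RegimeSpec(
        kind="river", site_id="synthetic-river", start=date(2006, 8, 1),
        n_days=365 * 3, seed=20060801,
    )
    return hp.make_regime(spec)
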