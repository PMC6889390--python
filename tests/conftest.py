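import datetime as dt

import numpy as np
import pandas as pd
import pytest

import reeftemp as rt


@pytest.fixture
def meta():
    return rt.SiteMeta(site_id=1, name="test reef", lat=28.0, lon=112.0)


@pytest.fixture
def series_factory(meta):
    """Build a TemperatureSeries from raw values on a regular grid."""

    def build(values, start="2009-07-01", interval_min=20, site_meta=None):
        values = np.asarray(values, dtype=float)
        idx = pd.date_range(start, periods=len(values), freq=f"{interval_min}min")
        return rt.TemperatureSeries(
            meta=site_meta or meta, data=pd.Series(values, index=idx)
        )

    return build


@pytest.fixture
def quiet_config():
    """Deterministic generator config: sinusoids only, no events/noise."""
    return rt.SyntheticConfig(
        start_date=dt.date(2009, 1, 1),
        n_days=365,
        event_rate_summer=0.0,
        event_rate_winter=0.0,
        noise_sd=0.0,
        seed=0,
    )
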