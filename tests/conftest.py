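from datetime import date, time

import pandas as pd
import pytest

from tuskrest import synth
from tuskrest.timebase_io import AnalysisNight, AstroDay


@pytest.fixture(scope="session")
def small_dataset():
    """A 12-night synthetic deployment with default (study-like) structure."""
    return synth.generate(synth.GeneratorConfig(n_nights=12, seed=7))


@pytest.fixture(scope="session")
def quiet_dataset():
    """10 nights guaranteed to sleep every night (no flight bouts)."""
    return synth.generate(synth.GeneratorConfig(n_nights=10, p_no_sleep=0.0, seed=21))


@pytest.fixture()
def night():
    return AnalysisNight(date(2014, 4, 15))


@pytest.fixture()
def astro_lookup():
    """Constant sunset 18:10 / sunrise 06:30 for mid-April test nights."""
    out = {}
    for day in pd.date_range("2014-04-10", "2014-04-25"):
        out[day.date()] = AstroDay(
            date=day.date(), sunset=time(18, 10), sunrise=time(6, 30),
            civil_off_min=22.0, nautical_off_min=47.0, astro_off_min=73.0,
            moonrise=time(17, 0), moonset=time(5, 0), moon_illum_pct=50.0,
        )
    return out


def minute_series(start, values):
    """1-min actigraphy frame starting at ``start``."""
    ts = pd.date_range(start, periods=len(values), freq="1min")
    return pd.DataFrame({"timestamp": ts, "count": values})
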