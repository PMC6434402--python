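import datetime as dt

import numpy as np
import pytest

from patx import MINUTES_PER_DAY, MinuteSeries, default_calendar

DATE = dt.date(2015, 9, 14)


def make_day(values=None, subject="s1", date=DATE, missing=()):
    """Build a MinuteSeries; `values` may be a scalar, an array, or None
    (constant 70); `missing` lists slots to blank."""
    if values is None:
        values = 70.0
    hr = np.full(MINUTES_PER_DAY, np.nan)
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 0:
        hr[:] = float(arr)
    else:
        hr[: arr.size] = arr
    for slot in missing:
        hr[slot] = np.nan
    return MinuteSeries(subject, date, hr)


@pytest.fixture
def calendar():
    return default_calendar()


@pytest.fixture
def complete_day():
    return make_day(70.0)
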