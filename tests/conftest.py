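from datetime import date, datetime, time, timedelta

import numpy as np
import pytest

from inca.adherence import DoseLog
from inca.technique import TechniqueLabel

START = date(2024, 1, 1)


def make_log(
    daily_labels,
    subject_id="S000",
    start=START,
    prescribed_per_day=2,
):
    """Build a DoseLog from a list of per-day label lists.

    ``daily_labels[d]`` holds the labels of the doses taken on day ``d``
    (morning slot first).
    """
    slots = (8, 20, 12, 16, 10, 14)  # extra slots for >2 doses/day cases
    events = []
    for d, labels in enumerate(daily_labels):
        for i, lb in enumerate(labels):
            ts = datetime.combine(start + timedelta(days=d), time(slots[i], 0))
            events.append((ts, TechniqueLabel.of(lb)))
    return DoseLog(
        subject_id=subject_id, events=events, prescribed_per_day=prescribed_per_day
    )


@pytest.fixture
def perfect_week_log():
    return make_log([["correct", "correct"]] * 7)


def ols_slope(y):
    """Independent OLS oracle: slope of cumulative y on day index."""
    c = np.cumsum(np.asarray(y, dtype=float))
    x = np.arange(1, c.size + 1, dtype=float)
    return float(np.polyfit(x, c, 1)[0])
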