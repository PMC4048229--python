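"""Adherence series and the weekly regression slope."""

from datetime import timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inca.adherence import (
    DoseLog,
    adherence_slope,
    overall_adherence,
    read_dose_logs,
    weekly_series,
    write_dose_logs,
)

from conftest import START, make_log, ols_slope


def test_perfect_week_slope_is_exactly_two(perfect_week_log):
    series = weekly_series(perfect_week_log)
    assert series["temporal_slope"].tolist() == [2.0]
    assert series["combined_slope"].tolist() == [2.0]


def test_slope_examples():
    assert adherence_slope([2] * 7) == pytest.approx(2.0)
    assert adherence_slope([0] * 7) == 0.0
    assert adherence_slope([1] * 7) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        adherence_slope([2])


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    st.lists(st.integers(min_value=0, max_value=4), min_size=2, max_size=30)
)
def test_slope_formula_equals_ols_oracle(counts):
    """r*s_y/s_x is algebraically the OLS slope, to 1e-9."""
    if sum(counts) == 0:
        assert adherence_slope(counts) == 0.0
    else:
        assert adherence_slope(counts) == pytest.approx(ols_slope(counts), abs=1e-9)


def test_four_perfect_weeks_all_slopes_two():
    log = make_log([["correct", "correct"]] * 28)
    series = weekly_series(log)
    assert len(series) == 4
    assert np.allclose(series["temporal_slope"], 2.0)


def test_every_second_day_gives_slope_one_per_week():
    days = [["correct", "correct"] if d % 2 == 0 else [] for d in range(15)]
    log = make_log(days)
    series = weekly_series(log)
    expected = [ols_slope([2, 0, 2, 0, 2, 0, 2]), ols_slope([0, 2, 0, 2, 0, 2, 0])]
    assert series["temporal_slope"].tolist() == pytest.approx(expected)
    # cumulative-over-week average is one dose/day
    assert np.mean(series["temporal_slope"]) == pytest.approx(1.0, abs=0.1)


def test_excess_doses_capped_and_reported():
    days = [["correct"] * 3] + [["correct", "correct"]] * 6
    log = make_log(days)
    series = weekly_series(log)
    assert series.loc[0, "temporal_slope"] == pytest.approx(2.0)
    assert series.loc[0, "n_excess"] == 1
    assert series.loc[0, "n_taken"] == 15


def test_sixty_percent_errors_reduce_combined_slope_to_about_0_8():
    """Technique errors cut the weekly rate from 2 to ~0.8 while temporal
    adherence stays perfect."""
    labels = ["exhalation_after_priming"] * 3 + ["correct"] * 2  # 60 % errors
    flat = (labels * 12)[: 2 * 28]
    days = [flat[2 * d : 2 * d + 2] for d in range(28)]
    log = make_log(days)
    series = weekly_series(log)
    assert np.allclose(series["temporal_slope"], 2.0)
    # oracle: per-week OLS on the daily correct-dose counts
    correct_daily = [sum(lb == "correct" for lb in day) for day in days]
    for w in range(4):
        assert series.loc[w, "combined_slope"] == pytest.approx(
            ols_slope(correct_daily[7 * w : 7 * w + 7]), abs=1e-9
        )
    assert series["combined_slope"].mean() == pytest.approx(0.8, abs=0.15)


def test_all_errors_give_zero_combined_slope():
    log = make_log([["weak_inhalation", "weak_inhalation"]] * 7)
    series = weekly_series(log)
    assert series["combined_slope"].tolist() == [0.0]
    assert series["temporal_slope"].tolist() == [2.0]


@pytest.mark.parametrize("seed", range(10))
def test_combined_never_exceeds_temporal_on_random_logs(seed):
    rng = np.random.default_rng(seed)
    days = []
    for _ in range(21):
        n = rng.integers(0, 4)
        days.append(
            [
                "correct" if rng.random() > 0.4 else "exhalation_after_priming"
                for _ in range(n)
            ]
        )
    series = weekly_series(make_log(days)) if any(days) else None
    if series is not None:
        assert (series["combined_slope"] <= series["temporal_slope"] + 1e-12).all()


def test_slopes_invariant_to_uniform_time_shift():
    days = [["correct", "correct"], [], ["correct"], ["correct", "correct"],
            [], [], ["correct"]] * 2
    log = make_log(days)
    shifted = DoseLog(
        subject_id=log.subject_id,
        events=[(ts + timedelta(days=30), lb) for ts, lb in log.events],
        prescribed_per_day=2,
    )
    a = weekly_series(log)
    b = weekly_series(shifted)
    assert a["temporal_slope"].tolist() == b["temporal_slope"].tolist()
    assert a["combined_slope"].tolist() == b["combined_slope"].tolist()


def test_overall_adherence_percentages():
    assert overall_adherence(make_log([["correct", "correct"]] * 14)) == 100.0
    half = make_log([["correct", "correct"] if d % 2 else [] for d in range(14)])
    assert overall_adherence(half, start=START, days=14) == pytest.approx(50.0)
    # 28-day log with 50 of 56 doses credited
    days = [["correct", "correct"]] * 25 + [["correct"]] * 0 + [[]] * 3
    log = make_log(days)
    assert overall_adherence(log, start=START, days=28) == pytest.approx(
        100 * 50 / 56, abs=1e-9
    )


def test_empty_log_needs_explicit_window():
    empty = DoseLog(subject_id="E", events=[])
    with pytest.raises(ValueError):
        weekly_series(empty)
    series = weekly_series(empty, start=START, weeks=2)
    assert series["temporal_slope"].tolist() == [0.0, 0.0]
    with pytest.raises(ValueError):
        overall_adherence(empty)


def test_dose_log_csv_round_trip(tmp_path):
    log = make_log([["correct", "weak_inhalation"]] * 8, subject_id="S042")
    path = write_dose_logs([log], tmp_path / "log.csv")
    (back,) = read_dose_logs(path)
    assert back.subject_id == "S042"
    assert [(ts, str(lb)) for ts, lb in back.events] == [
        (ts, str(lb)) for ts, lb in log.events
    ]
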