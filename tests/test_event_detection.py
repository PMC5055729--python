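"""Detector tests with independent brute-force oracles."""

import statistics
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eventscan.count_series import CountSeries
from eventscan.event_detection import (
    Alarm,
    DayRecord,
    EventStatus,
    c2_flags,
    c3_flags,
    classify_events,
    group_alarms,
    make_alarm_id,
    mu_max,
    mu_statistic,
    threshold_metrics,
    threshold_sweep,
    tweet_user_ratio,
)
from eventscan.models import RunConfig

from conftest import make_tweet


def _series(counts, start=date(2014, 5, 1)):
    counts = np.asarray(counts, dtype=float)
    return CountSeries(
        group_id="flu",
        cluster_id=0,
        days=tuple(start + timedelta(days=i) for i in range(len(counts))),
        raw_counts=counts,
        normalised_counts=counts.copy(),
        distinct_users=counts.copy(),
    )


# ---------------------------------------------------------------- C2 / C3

def brute_c2(counts, window=7, k=3.0, floor=0.5, gap=0):
    out = []
    for t in range(len(counts)):
        if t < window + gap:
            out.append(False)
            continue
        base = counts[t - gap - window : t - gap]
        sd = statistics.stdev(base) if window > 1 else 0.0
        out.append(counts[t] - statistics.mean(base) > k * max(sd, floor))
    return out


def brute_c3(c2, lookback=3, min_alarms=2):
    return [
        sum(c2[max(0, t - lookback + 1) : t + 1]) >= min_alarms
        for t in range(len(c2))
    ]


def brute_runs(flags):
    """Run-length scan: list of (start index, end index) of True runs."""
    runs, start = [], None
    for i, f in enumerate(list(flags) + [False]):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    return runs


def test_c2_flat_series_never_flags():
    assert not c2_flags([5.0] * 8).any()


def test_c2_alternating_baseline_arithmetic():
    # baseline [1,2,1,2,1,2,1]: mean 10/7, sample sd ~0.5345; 3*sd ~1.604
    assert c2_flags([1, 2, 1, 2, 1, 2, 1, 4])[-1]
    assert not c2_flags([1, 2, 1, 2, 1, 2, 1, 3])[-1]


def test_c2_sigma_floor_on_zero_variance():
    assert c2_flags([0] * 7 + [2], sigma_floor=0.5)[-1]  # 2 - 0 > 1.5
    assert not c2_flags([0] * 7 + [1], sigma_floor=0.5)[-1]


def test_c3_counting_rules():
    assert not c3_flags([False] * 10).any()
    c2 = [False] * 10
    c2[4] = c2[6] = True  # days t-2 and t
    assert c3_flags(c2)[6]
    single = [False] * 10
    single[4] = True
    assert not c3_flags(single).any()


def test_group_alarms_merging_and_gaps():
    s = _series([0.0] * 10)
    c2 = np.zeros(10, dtype=bool)
    c2[[3, 4]] = True
    (alarm,) = group_alarms(s, c2, np.zeros(10, dtype=bool))
    assert (alarm.start_date, alarm.end_date) == (s.days[3], s.days[4])

    c2 = np.zeros(10, dtype=bool)
    c2[[3, 5]] = True
    alarms = group_alarms(s, c2, np.zeros(10, dtype=bool))
    assert len(alarms) == 2


@given(st.lists(st.integers(0, 30), min_size=10, max_size=40), st.integers(0, 2**31 - 1))
def test_detector_chain_matches_brute_force(counts, seed):
    counts = [float(c) for c in counts]
    c2 = c2_flags(counts)
    assert c2.tolist() == brute_c2(counts)
    c3 = c3_flags(c2)
    assert c3.tolist() == brute_c3(c2.tolist())
    s = _series(counts)
    alarms = group_alarms(s, c2, c3)
    alarmed = (c2 | c3).tolist()
    expected = brute_runs(alarmed)
    assert [(s.days.index(a.start_date), s.days.index(a.end_date)) for a in alarms] == expected


# ---------------------------------------------------------------- mu

def test_mu_zero_at_median():
    assert mu_statistic([1, 2, 3, 4, 5], 3) == 0.0


def test_mu_hand_computed():
    # median 3, MAD 1
    assert mu_statistic([1, 2, 2, 3, 3, 3, 4, 4, 9], 9) == pytest.approx(6.0)


def test_mu_scale_invariant_above_floor():
    hist = [10, 20, 20, 30, 30, 30, 40, 40, 90]
    assert mu_statistic(hist, 90) == pytest.approx(
        mu_statistic([h * 10 for h in hist], 900)
    )


def test_mu_even_median_rule():
    # median of [1,3] = 2, MAD = median(|1-2|,|3-2|) = 1
    assert mu_statistic([1, 3], 4) == pytest.approx(2.0)


@given(
    st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=30),
    st.floats(0, 100),
    st.floats(0.1, 50),
)
def test_mu_monotone_in_observation(history, obs, delta):
    assert mu_statistic(history, obs + delta) > mu_statistic(history, obs)


def test_mu_empty_history_errors():
    with pytest.raises(ValueError):
        mu_statistic([], 1.0)


def _alarm_over(series, day_indices):
    return Alarm(
        group_id=series.group_id,
        cluster_id=series.cluster_id,
        start_date=series.days[day_indices[0]],
        end_date=series.days[day_indices[-1]],
        day_records=[
            DayRecord(series.days[i], float(series.raw_counts[i]), True, False)
            for i in day_indices
        ],
    )


def test_mu_max_is_max_over_alarm_days():
    s = _series([5.0] * 20 + [12.0, 30.0])
    alarm = _alarm_over(s, [20, 21])
    value = mu_max(alarm, s)
    mus = [r.mu for r in alarm.day_records]
    assert value == max(mus)
    assert alarm.day_records[1].mu > alarm.day_records[0].mu


def test_mu_max_single_day_equals_daily_mu():
    s = _series([5.0] * 20 + [12.0])
    alarm = _alarm_over(s, [20])
    assert mu_max(alarm, s) == pytest.approx(mu_statistic([5.0] * 20, 12.0))


def test_larger_burst_larger_mu_max():
    base = [5.0] * 20
    s3 = _series(base + [15.0])
    s10 = _series(base + [50.0])
    assert mu_max(_alarm_over(s10, [20]), s10) > mu_max(_alarm_over(s3, [20]), s3)


# ---------------------------------------------------------------- filters

def test_tweet_user_ratio():
    five = [make_tweet(f"t{i}", user_id=f"u{i}") for i in range(5)]
    assert tweet_user_ratio(five) == 1.0
    six = [make_tweet(f"t{i}", user_id=f"u{i % 3}") for i in range(6)]
    assert tweet_user_ratio(six) == 2.0
    with pytest.raises(ValueError):
        tweet_user_ratio([])


def _scored_alarm(mu, ratio):
    a = Alarm("flu", 0, date(2014, 5, 1), date(2014, 5, 1), [], alarm_id="x")
    a.mu_max = mu
    a.tweet_user_ratio = ratio
    a.tweet_count, a.distinct_user_count = 10, 10
    return a


@pytest.mark.parametrize(
    "mu,ratio,expected",
    [
        (20.0, 1.0, EventStatus.EVENT),
        (3.9, 1.0, EventStatus.REJECTED_LOW_MU),
        (10.0, 1.6, EventStatus.REJECTED_SPAM),
        (2.0, 2.0, EventStatus.REJECTED_SPAM),  # spam takes precedence
        (4.0, 1.5, EventStatus.EVENT),  # boundary: >= mu, <= ratio
    ],
)
def test_classify_events(mu, ratio, expected):
    (decision,) = classify_events([_scored_alarm(mu, ratio)], RunConfig())
    assert decision.status == expected


def test_raising_mu_threshold_never_adds_events():
    rng = np.random.default_rng(0)
    alarms = [_scored_alarm(float(rng.uniform(0, 10)), 1.0) for _ in range(50)]
    counts = []
    for thr in [0, 2, 4, 6, 8]:
        cfg = RunConfig(mu_max_threshold=thr)
        counts.append(
            sum(d.status == EventStatus.EVENT for d in classify_events(alarms, cfg))
        )
    assert counts == sorted(counts, reverse=True)


def test_threshold_metrics_definitions():
    labelled = [(5.0, True), (3.0, True), (6.0, False), (1.0, False)]
    m = threshold_metrics(labelled, 4.0)
    assert m["precision"] == pytest.approx(1 / 2)
    assert m["recall"] == pytest.approx(1 / 2)
    # recall 1 at or below the minimum score
    assert threshold_metrics(labelled, 1.0)["recall"] == 1.0
    # all-verified: precision 1 wherever TP > 0
    allv = [(2.0, True), (9.0, True)]
    assert threshold_metrics(allv, 2.0)["precision"] == 1.0


def test_alarm_id_scheme():
    used = set()
    assert make_alarm_id("sadness", "London", date(2014, 8, 11), used) == "SAL-11-08"
    # second sadness alarm in a city starting with L on the same date
    assert make_alarm_id("sadness", "Leeds", date(2014, 8, 11), used) == "SALE-11-08"
    assert make_alarm_id("sore throat", "London", date(2014, 8, 26), used) == "SOL-26-08"
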