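"""EARS C2/C3 aberration detection and the MAD-based severity filter.

C2 flags a day whose count exceeds a short trailing moving average by a
multiple of its standard deviation; C3 accumulates recent C2 evidence.
Consecutive flagged days for one (keyword group, cluster) form an *alarm*.
Because sparse count series are zero-skewed and non-normal, alarms are then
scored with a robust severity statistic:

    mu = (observation - median(history)) / max(MAD(history), mad_floor)

where the history is every observed count strictly before the day and MAD is
the median absolute deviation from the median.  The alarm's mu_max (its
highest daily mu) together with the tweet-user ratio (tweets per distinct
author, high values indicating spam) decides whether the alarm is promoted
to an *event*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Sequence

import numpy as np

from .count_series import CountSeries
from .models import RunConfig, Tweet


def c2_flags(
    series_counts: Sequence[float] | CountSeries,
    window: int = 7,
    k_sigma: float = 3.0,
    sigma_floor: float = 0.5,
    gap: int = 0,
    normalised: bool = True,
) -> np.ndarray:
    """Per-day C2 flags over a count series.

    Day t (with a full baseline of ``window`` days ending ``gap`` days before
    t) is flagged when count(t) - mean(baseline) > k_sigma * sd(baseline),
    with the sample standard deviation floored at ``sigma_floor``.  Days
    without a full baseline are never flagged.
    """
    counts = (
        series_counts.counts(normalised)
        if isinstance(series_counts, CountSeries)
        else np.asarray(series_counts, dtype=float)
    )
    n = len(counts)
    flags = np.zeros(n, dtype=bool)
    for t in range(window + gap, n):
        baseline = counts[t - gap - window : t - gap]
        mean = baseline.mean()
        sd = baseline.std(ddof=1) if window > 1 else 0.0
        flags[t] = counts[t] - mean > k_sigma * max(sd, sigma_floor)
    return flags


def c3_flags(
    c2: Sequence[bool],
    lookback: int = 3,
    min_alarms: int = 2,
) -> np.ndarray:
    """C3 fires on day t when at least ``min_alarms`` C2 flags fall in the
    trailing ``lookback``-day window ending at t (t included)."""
    c2 = np.asarray(c2, dtype=bool)
    n = len(c2)
    flags = np.zeros(n, dtype=bool)
    for t in range(n):
        lo = max(0, t - lookback + 1)
        flags[t] = c2[lo : t + 1].sum() >= min_alarms
    return flags


def c3_flags_cdc(
    series_counts: Sequence[float] | CountSeries,
    window: int = 7,
    k_sigma: float = 3.0,
    sigma_floor: float = 0.5,
    gap: int = 0,
    threshold: float = 2.0,
    normalised: bool = True,
) -> np.ndarray:
    """Alternative cumulative C3: sum of positive standardised excesses
    (z - 1) over the trailing 3 days exceeds ``threshold``."""
    counts = (
        series_counts.counts(normalised)
        if isinstance(series_counts, CountSeries)
        else np.asarray(series_counts, dtype=float)
    )
    n = len(counts)
    z = np.full(n, np.nan)
    for t in range(window + gap, n):
        baseline = counts[t - gap - window : t - gap]
        sd = baseline.std(ddof=1) if window > 1 else 0.0
        z[t] = (counts[t] - baseline.mean()) / max(sd, sigma_floor)
    flags = np.zeros(n, dtype=bool)
    for t in range(n):
        zs = z[max(0, t - 2) : t + 1]
        zs = zs[~np.isnan(zs)]
        if len(zs):
            flags[t] = np.sum(np.maximum(0.0, zs - 1.0)) > threshold
    return flags


@dataclass
class DayRecord:
    date: date
    count: float
    c2_triggered: bool
    c3_triggered: bool
    mu: float = float("nan")


@dataclass
class Alarm:
    """A maximal run of consecutive alarmed days for one (group, cluster)."""

    group_id: str
    cluster_id: int
    start_date: date
    end_date: date
    day_records: list[DayRecord]
    alarm_id: str = ""
    mu_max: float = float("nan")
    tweet_count: int = 0
    distinct_user_count: int = 0
    tweet_user_ratio: float = float("nan")

    @property
    def days(self) -> list[date]:
        return [r.date for r in self.day_records]


class EventStatus(str, Enum):
    EVENT = "event"
    REJECTED_LOW_MU = "rejected_low_mu"
    REJECTED_SPAM = "rejected_spam"


@dataclass
class EventDecision:
    alarm_id: str
    status: EventStatus
    mu_threshold_used: float
    ratio_threshold_used: float


def group_alarms(
    series: CountSeries,
    c2: Sequence[bool],
    c3: Sequence[bool],
    normalised: bool = True,
) -> list[Alarm]:
    """Merge consecutive alarmed days (C2 or C3 true) into Alarm objects."""
    c2 = np.asarray(c2, dtype=bool)
    c3 = np.asarray(c3, dtype=bool)
    if len(c2) != len(series.days) or len(c3) != len(series.days):
        raise ValueError("flags must align with series days")
    alarmed = c2 | c3
    counts = series.counts(normalised)
    alarms: list[Alarm] = []
    run: list[int] = []
    for t in range(len(alarmed) + 1):
        if t < len(alarmed) and alarmed[t]:
            run.append(t)
            continue
        if run:
            records = [
                DayRecord(
                    date=series.days[i],
                    count=float(counts[i]),
                    c2_triggered=bool(c2[i]),
                    c3_triggered=bool(c3[i]),
                )
                for i in run
            ]
            alarms.append(
                Alarm(
                    group_id=series.group_id,
                    cluster_id=series.cluster_id,
                    start_date=series.days[run[0]],
                    end_date=series.days[run[-1]],
                    day_records=records,
                )
            )
            run = []
    return alarms


def mu_statistic(
    history: Sequence[float], observation: float, mad_floor: float = 1.0
) -> float:
    """MADs above the historical median: (obs - median) / max(MAD, floor)."""
    history = np.asarray(history, dtype=float)
    if len(history) == 0:
        raise ValueError("history must be non-empty")
    med = float(np.median(history))
    mad = float(np.median(np.abs(history - med)))
    return (observation - med) / max(mad, mad_floor)


def mu_max(
    alarm: Alarm,
    full_series: CountSeries,
    mad_floor: float = 1.0,
    normalised: bool = True,
) -> float:
    """Highest daily mu over the alarm; per-day mu is stored on the records.

    The history for each alarm day is every series count strictly before
    that day, from the start of the series.
    """
    counts = full_series.counts(normalised)
    best = -np.inf
    for record in alarm.day_records:
        t = full_series.index_of(record.date)
        if t == 0:
            continue  # no history yet
        record.mu = mu_statistic(counts[:t], counts[t], mad_floor)
        best = max(best, record.mu)
    alarm.mu_max = float(best)
    return alarm.mu_max


def tweet_user_ratio(alarm_tweets: Sequence[Tweet]) -> float:
    """Tweets per distinct author; the spam signature is a ratio well above 1."""
    if not alarm_tweets:
        raise ValueError("alarm_tweets must be non-empty")
    users = {t.user_id for t in alarm_tweets}
    return len(alarm_tweets) / len(users)


def classify_events(
    alarms: Sequence[Alarm], config: RunConfig
) -> list[EventDecision]:
    """Promote alarms to events via the mu_max and tweet-user-ratio filters.

    An alarm is an event iff mu_max >= mu_max_threshold and the ratio is at
    most tweet_user_ratio_threshold; a failing ratio labels the alarm as spam
    even when mu_max also falls short.
    """
    decisions = []
    for alarm in alarms:
        if np.isnan(alarm.mu_max):
            raise ValueError(f"alarm {alarm.alarm_id!r} has no mu_max")
        if alarm.tweet_user_ratio > config.tweet_user_ratio_threshold:
            status = EventStatus.REJECTED_SPAM
        elif alarm.mu_max < config.mu_max_threshold:
            status = EventStatus.REJECTED_LOW_MU
        else:
            status = EventStatus.EVENT
        decisions.append(
            EventDecision(
                alarm_id=alarm.alarm_id,
                status=status,
                mu_threshold_used=config.mu_max_threshold,
                ratio_threshold_used=config.tweet_user_ratio_threshold,
            )
        )
    return decisions


def threshold_metrics(
    labelled: Sequence[tuple[float, bool]], threshold: float
) -> dict[str, float]:
    """Precision/recall/F1 of the rule "mu_max at or above threshold => event"
    against external verification labels."""
    if not labelled:
        raise ValueError("labelled must be non-empty")
    tp = sum(1 for mu, v in labelled if mu >= threshold and v)
    fp = sum(1 for mu, v in labelled if mu >= threshold and not v)
    fn = sum(1 for mu, v in labelled if mu < threshold and v)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1}


def threshold_sweep(
    labelled: Sequence[tuple[float, bool]], thresholds: Sequence[float]
) -> list[dict[str, float]]:
    """threshold_metrics at each threshold, for parameter-selection curves."""
    rows = []
    for thr in thresholds:
        row = {"threshold": float(thr)}
        row.update(threshold_metrics(labelled, thr))
        rows.append(row)
    return rows


def make_alarm_id(
    group_id: str, area_label: str, start: date, used: set[str]
) -> str:
    """Event id: two letters of the keyword + 1-2 letter area code + day-month.

    Keyword pairs sharing a prefix (or repeated ids) are disambiguated with a
    numeric suffix.
    """
    kw = "".join(ch for ch in group_id if ch.isalpha())[:2].upper()
    area_letters = "".join(ch for ch in area_label if ch.isalpha()).upper()
    for area in (area_letters[:1], area_letters[:2]):
        candidate = f"{kw}{area}-{start.day:02d}-{start.month:02d}"
        if candidate not in used:
            used.add(candidate)
            return candidate
    i = 2
    while f"{candidate}-{i}" in used:
        i += 1
    candidate = f"{candidate}-{i}"
    used.add(candidate)
    return candidate
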