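"""Daily count series per (keyword group, cluster) and weekday normalisation.

Twitter volume has a strong weekly rhythm (more tweeting at weekends), so a
raw Monday count and a raw Saturday count are not comparable.  Each series
carries raw counts, weekday-normalised counts, and distinct-user counts per
day; downstream detection runs on the normalised counts by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geo_clustering import ClusterModel
from .keyword_matching import KeywordMatcher
from .models import KeywordGroup, Tweet


@dataclass
class CountSeries:
    """Contiguous daily counts for one (keyword group, cluster) pair."""

    group_id: str
    cluster_id: int
    days: tuple[date, ...]
    raw_counts: np.ndarray
    normalised_counts: np.ndarray
    distinct_users: np.ndarray

    def __post_init__(self) -> None:
        self.raw_counts = np.asarray(self.raw_counts, dtype=float)
        self.normalised_counts = np.asarray(self.normalised_counts, dtype=float)
        self.distinct_users = np.asarray(self.distinct_users, dtype=float)
        n = len(self.days)
        if not (
            len(self.raw_counts) == len(self.normalised_counts) == len(self.distinct_users) == n
        ):
            raise ValueError("all per-day arrays must have the same length")
        for a, b in zip(self.days, self.days[1:]):
            if b - a != timedelta(days=1):
                raise ValueError("days must increase by exactly one day")
        if np.any(self.distinct_users > self.raw_counts):
            raise ValueError("distinct users cannot exceed raw counts")

    def counts(self, normalised: bool = True) -> np.ndarray:
        return self.normalised_counts if normalised else self.raw_counts

    def index_of(self, day: date) -> int:
        i = (day - self.days[0]).days
        if not 0 <= i < len(self.days):
            raise KeyError(day)
        return i

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": list(self.days),
                "raw": self.raw_counts,
                "normalised": self.normalised_counts,
                "users": self.distinct_users,
            }
        )


def _date_span(start: date, end: date) -> tuple[date, ...]:
    if end < start:
        raise ValueError("empty date range")
    return tuple(start + timedelta(days=i) for i in range((end - start).days + 1))


def aggregate(
    tweets: Sequence[Tweet],
    model: ClusterModel,
    groups: Iterable[KeywordGroup],
    date_range: tuple[date, date],
    cluster_ids: Sequence[int] | None = None,
    group_matches: Sequence[set[str]] | None = None,
) -> list[CountSeries]:
    """One zero-filled series per (group, non-noise cluster) pair with any match.

    A tweet matching g groups contributes one count to each of the g series;
    noise-cluster tweets are excluded from the analysis.  Pre-computed
    ``cluster_ids``/``group_matches`` (aligned to ``tweets``) may be passed to
    avoid re-assigning when the caller has already processed the stream.
    """
    start, end = date_range
    days = _date_span(start, end)
    if cluster_ids is None:
        lats = np.array([t.lat for t in tweets])
        lons = np.array([t.lon for t in tweets])
        cluster_ids = model.assign_many(lats, lons) if len(tweets) else []
    if group_matches is None:
        matcher = KeywordMatcher(groups)
        group_matches = [matcher.match_text(t.text) for t in tweets]

    # (group, cluster) -> day index -> tweet count / user set
    counts: dict[tuple[str, int], np.ndarray] = {}
    users: dict[tuple[str, int], list[set[str]]] = {}
    n_days = len(days)
    for tweet, cid, matched in zip(tweets, cluster_ids, group_matches):
        if cid == model.noise_id or not matched:
            continue
        d = tweet.day
        if not start <= d <= end:
            continue
        di = (d - start).days
        for gid in matched:
            key = (gid, int(cid))
            if key not in counts:
                counts[key] = np.zeros(n_days)
                users[key] = [set() for _ in range(n_days)]
            counts[key][di] += 1
            users[key][di].add(tweet.user_id)

    out = []
    for (gid, cid) in sorted(counts):
        raw = counts[(gid, cid)]
        out.append(
            CountSeries(
                group_id=gid,
                cluster_id=cid,
                days=days,
                raw_counts=raw,
                normalised_counts=raw.copy(),
                distinct_users=np.array([len(s) for s in users[(gid, cid)]], dtype=float),
            )
        )
    return out


def weekday_normalise(series: CountSeries, history_window_days: int = 56) -> CountSeries:
    """Divide each day's count by its trailing weekday activity factor.

    For day t, the factor f(w) is the mean raw count on weekday w over the
    trailing window divided by the overall mean over the window, floored at
    0.1.  Days with fewer than 14 days of trailing history keep f = 1: below
    two full weeks there are not two samples of every weekday and the factor
    would be dominated by single days.
    """
    if history_window_days < 14:
        raise ValueError("history_window_days must be >= 14")
    raw = series.raw_counts
    n = len(raw)
    weekdays = np.array([d.weekday() for d in series.days])
    normalised = raw.astype(float).copy()
    for t in range(n):
        if t < 14:
            continue
        lo = max(0, t - history_window_days)
        window = raw[lo:t]
        wd = weekdays[lo:t]
        overall = window.mean()
        if overall <= 0:
            continue
        same = window[wd == weekdays[t]]
        if len(same) == 0:
            continue
        f = max(same.mean() / overall, 0.1)
        normalised[t] = raw[t] / f
    return replace(series, normalised_counts=normalised)
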