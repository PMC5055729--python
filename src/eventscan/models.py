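"""Shared domain records for the detection and summarisation pipeline.

A *tweet* is a geo-tagged microblog message; a *keyword group* is a primary
keyword (e.g. ``vomit``) plus aliases (``throwing up``, ``being sick``) that
are consolidated into one counted class; a *news article* is one document of
the local news corpus used for event linkage.  :class:`RunConfig` collects
every tunable threshold of the pipeline in one place.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from enum import Enum
from typing import Iterable, Mapping, Sequence


class EventClass(str, Enum):
    SYMPTOM = "symptom"
    EMOTION = "emotion"


@dataclass(frozen=True, slots=True)
class Tweet:
    """One geo-tagged message.

    ``lat``/``lon`` are WGS84 decimal degrees; ``timestamp`` is timezone-aware
    UTC.  The calendar day of a tweet is its UTC date.
    """

    id: str
    timestamp: datetime
    user_id: str
    lat: float
    lon: float
    text: str
    is_retweet: bool = False

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")
        if not self.text:
            raise ValueError("tweet text must be non-empty")
        if self.timestamp.tzinfo is None:
            object.__setattr__(
                self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc)
            )
        else:
            object.__setattr__(
                self, "timestamp", self.timestamp.astimezone(timezone.utc)
            )

    @property
    def day(self) -> date:
        return self.timestamp.date()


@dataclass(frozen=True, slots=True)
class KeywordGroup:
    """A primary keyword plus its aliases, all lowercase."""

    primary_keyword: str
    aliases: tuple[str, ...] = ()
    event_class: EventClass = EventClass.SYMPTOM

    def __post_init__(self) -> None:
        if not self.primary_keyword:
            raise ValueError("primary_keyword must be non-empty")
        norm = tuple(" ".join(a.lower().split()) for a in self.aliases)
        primary = " ".join(self.primary_keyword.lower().split())
        norm = tuple(a for a in norm if a != primary)
        if len(set(norm)) != len(norm):
            raise ValueError(f"duplicate aliases in group {primary!r}")
        object.__setattr__(self, "primary_keyword", primary)
        object.__setattr__(self, "aliases", norm)
        object.__setattr__(self, "event_class", EventClass(self.event_class))

    @property
    def terms(self) -> tuple[str, ...]:
        """Primary keyword first, then aliases."""
        return (self.primary_keyword,) + self.aliases


@dataclass(frozen=True, slots=True)
class NewsArticle:
    """One document of the local news corpus (stands in for a web search hit)."""

    article_id: str
    title: str
    body: str
    date: date
    source: str = ""
    url: str = ""

    def __post_init__(self) -> None:
        if not self.title:
            raise ValueError("article title must be non-empty")
        if self.date is None:
            raise ValueError("article date must be present")


@dataclass(slots=True)
class RunConfig:
    """Pipeline parameters.

    Detection: the C2 detector flags day ``t`` when the count exceeds the
    trailing ``c2_window_days`` mean by ``c2_sigma_multiplier`` standard
    deviations (sd floored at ``c2_sigma_floor``); C3 fires on at least
    ``c3_min_alarms`` C2 flags within the trailing ``c3_lookback_days``.  An
    alarm is promoted to an event when its severity ``mu_max`` (MADs above the
    series median, MAD floored at ``mad_floor``) reaches
    ``mu_max_threshold`` and its tweet-user ratio stays at or below
    ``tweet_user_ratio_threshold``.

    Summarisation: terms must occur in at least ``ngram_doc_fraction`` of the
    gist tweets and beat Fisher's exact test at ``fisher_alpha``; news sets
    must score at least ``pcss_threshold`` pairwise cosine coherence and be
    related to another term's set at ``relatedness_threshold``.
    """

    c2_window_days: int = 7
    c2_sigma_multiplier: float = 3.0
    c2_sigma_floor: float = 0.5
    # guard band between baseline and test day (CDC C2 uses 2): without it a
    # multi-day burst masks itself — its first day inflates the baseline mean
    # and variance for its second day, truncating alarms to a single day
    c2_gap_days: int = 2
    c3_lookback_days: int = 3
    c3_min_alarms: int = 2
    c3_mode: str = "window"  # "window" (C2-count rule) or "cdc" (cumulative excess)
    mu_max_threshold: float = 4.0
    tweet_user_ratio_threshold: float = 1.5
    mad_floor: float = 1.0
    baseline_days: int = 28
    min_event_tweets: int = 30
    ngram_doc_fraction: float = 0.05
    fisher_alpha: float = 0.05
    top_k_unigrams: int = 2
    top_k_bigrams: int = 2
    news_per_term: int = 10
    pcss_threshold: float = -0.08
    relatedness_threshold: float = -0.08
    top_k_articles: int = 5
    top_k_tweets: int = 5
    dbscan_eps_km: float = 10.0
    dbscan_min_points: int = 10
    stopword_top_n: int = 200
    weekday_window_days: int = 56
    use_normalised: bool = True

    def __post_init__(self) -> None:
        for name in (
            "c2_window_days",
            "c3_lookback_days",
            "c3_min_alarms",
            "baseline_days",
            "min_event_tweets",
            "news_per_term",
            "top_k_articles",
            "top_k_tweets",
            "dbscan_min_points",
            "weekday_window_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.c2_gap_days < 0 or self.stopword_top_n < 0:
            raise ValueError("c2_gap_days and stopword_top_n must be >= 0")
        if not 0.0 < self.ngram_doc_fraction < 1.0:
            raise ValueError("ngram_doc_fraction must lie in (0, 1)")
        if not 0.0 < self.fisher_alpha < 1.0:
            raise ValueError("fisher_alpha must lie in (0, 1)")
        if self.dbscan_eps_km <= 0:
            raise ValueError("dbscan_eps_km must be positive")
        if self.c3_mode not in ("window", "cdc"):
            raise ValueError("c3_mode must be 'window' or 'cdc'")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_keyword_groups(groups: Iterable[KeywordGroup]) -> list[KeywordGroup]:
    """Validate a collection of groups: primary keywords unique per event class."""
    out = list(groups)
    seen: set[tuple[str, str]] = set()
    for g in out:
        key = (g.event_class.value, g.primary_keyword)
        if key in seen:
            raise ValueError(
                f"duplicate primary keyword {g.primary_keyword!r} "
                f"in event class {g.event_class.value!r}"
            )
        seen.add(key)
    return out


def check_unique_tweet_ids(tweets: Sequence[Tweet]) -> None:
    ids = {t.id for t in tweets}
    if len(ids) != len(tweets):
        raise ValueError("tweet ids must be unique within a stream")
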