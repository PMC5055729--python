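"""End-to-end orchestration: stream -> clusters -> alarms -> events -> summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

import numpy as np

from .count_series import CountSeries, aggregate, weekday_normalise
from .event_detection import (
    Alarm,
    EventDecision,
    EventStatus,
    c2_flags,
    c3_flags,
    c3_flags_cdc,
    classify_events,
    group_alarms,
    make_alarm_id,
    mu_max,
    tweet_user_ratio,
)
from .geo_clustering import ClusterModel, build_cluster_model, dbscan
from .keyword_matching import KeywordMatcher, NoiseFilterModel, apply_noise_filter
from .models import KeywordGroup, NewsArticle, RunConfig, Tweet
from .news_linkage import (
    TermSearchResult,
    filter_terms,
    rank_articles,
    search_news,
)
from .term_extraction import (
    build_stopwords,
    candidate_table,
    extract_candidates,
    fetch_sets,
    fisher_p,
    select_terms,
)
from .tweet_ranking import EventSummary, SttSource, rank_tweets, select_tweet_set


@dataclass
class ProcessedStream:
    """A tweet stream with per-tweet cluster assignment and group matches."""

    tweets: list[Tweet]
    cluster_ids: np.ndarray
    group_matches: list[set[str]]

    @classmethod
    def process(
        cls,
        tweets: Sequence[Tweet],
        model: ClusterModel,
        groups: Iterable[KeywordGroup],
        noise_filter: NoiseFilterModel | None = None,
    ) -> "ProcessedStream":
        tweets = apply_noise_filter(tweets, noise_filter)
        matcher = KeywordMatcher(groups)
        lats = np.array([t.lat for t in tweets], dtype=float)
        lons = np.array([t.lon for t in tweets], dtype=float)
        cluster_ids = (
            model.assign_many(lats, lons) if len(tweets) else np.empty(0, dtype=int)
        )
        return cls(
            tweets=list(tweets),
            cluster_ids=cluster_ids,
            group_matches=[matcher.match_text(t.text) for t in tweets],
        )


def build_clusters(
    tweets: Sequence[Tweet],
    config: RunConfig,
    names: dict[int, str] | None = None,
) -> ClusterModel:
    """DBSCAN the tweet coordinates and wrap each cluster in a convex hull."""
    points = [(t.lat, t.lon) for t in tweets]
    labels = dbscan(points, config.dbscan_eps_km, config.dbscan_min_points)
    return build_cluster_model(points, labels, names)


@dataclass
class DetectionResult:
    series: list[CountSeries]
    alarms: list[Alarm]
    decisions: list[EventDecision]

    def events(self) -> list[Alarm]:
        by_id = {a.alarm_id: a for a in self.alarms}
        return [
            by_id[d.alarm_id]
            for d in self.decisions
            if d.status == EventStatus.EVENT
        ]

    def decision_for(self, alarm_id: str) -> EventDecision:
        for d in self.decisions:
            if d.alarm_id == alarm_id:
                return d
        raise KeyError(alarm_id)


def detect(
    stream: ProcessedStream,
    model: ClusterModel,
    groups: Iterable[KeywordGroup],
    config: RunConfig,
    date_range: tuple[date, date] | None = None,
) -> DetectionResult:
    """Count, normalise, run C2/C3, group alarms, score and classify them."""
    tweets = stream.tweets
    if date_range is None:
        if not tweets:
            raise ValueError("empty stream and no date range")
        date_range = (tweets[0].day, tweets[-1].day)
    series = aggregate(
        tweets,
        model,
        groups,
        date_range,
        cluster_ids=stream.cluster_ids,
        group_matches=stream.group_matches,
    )
    series = [weekday_normalise(s, config.weekday_window_days) for s in series]

    alarms: list[Alarm] = []
    used_ids: set[str] = set()
    for s in series:
        c2 = c2_flags(
            s,
            window=config.c2_window_days,
            k_sigma=config.c2_sigma_multiplier,
            sigma_floor=config.c2_sigma_floor,
            gap=config.c2_gap_days,
            normalised=config.use_normalised,
        )
        if config.c3_mode == "cdc":
            c3 = c3_flags_cdc(
                s,
                window=config.c2_window_days,
                k_sigma=config.c2_sigma_multiplier,
                sigma_floor=config.c2_sigma_floor,
                gap=config.c2_gap_days,
                normalised=config.use_normalised,
            )
        else:
            c3 = c3_flags(c2, config.c3_lookback_days, config.c3_min_alarms)
        for alarm in group_alarms(s, c2, c3, normalised=config.use_normalised):
            mu_max(alarm, s, config.mad_floor, normalised=config.use_normalised)
            alarm_tweets = [
                t
                for t, cid, matched in zip(
                    tweets, stream.cluster_ids, stream.group_matches
                )
                if cid == alarm.cluster_id
                and alarm.group_id in matched
                and alarm.start_date <= t.day <= alarm.end_date
            ]
            alarm.tweet_count = len(alarm_tweets)
            alarm.distinct_user_count = len({t.user_id for t in alarm_tweets})
            alarm.tweet_user_ratio = (
                tweet_user_ratio(alarm_tweets) if alarm_tweets else float("nan")
            )
            alarm.alarm_id = make_alarm_id(
                alarm.group_id, model.label_of(alarm.cluster_id), alarm.start_date, used_ids
            )
            alarms.append(alarm)
    scoreable = [a for a in alarms if a.tweet_count > 0]
    decisions = classify_events(scoreable, config)
    return DetectionResult(series=series, alarms=alarms, decisions=decisions)


def summarise(
    alarm: Alarm,
    stream: ProcessedStream,
    model: ClusterModel,
    groups: Iterable[KeywordGroup],
    news_corpus: Sequence[NewsArticle],
    config: RunConfig,
    stopwords: set[str] | None = None,
) -> EventSummary:
    """Terms -> news -> tweets summary for one event.

    ``stopwords`` (the standard list plus the corpus's most frequent tokens)
    may be passed in when summarising several events over one stream.
    """
    gist, baseline, summarisable = fetch_sets(
        alarm,
        stream.tweets,
        model,
        groups,
        baseline_days=config.baseline_days,
        min_event_tweets=config.min_event_tweets,
        cluster_ids=stream.cluster_ids,
        group_matches=stream.group_matches,
    )
    gtt = rank_tweets(gist.tweets, config.top_k_tweets)
    if not summarisable:
        return EventSummary(
            event_id=alarm.alarm_id,
            terms=[],
            good_terms=[],
            top_articles=[],
            gtt=gtt,
            stt=None,
            stt_source=SttSource.UNAVAILABLE,
            summarisable=False,
        )
    if stopwords is None:
        stopwords = build_stopwords(stream.tweets, top_n=config.stopword_top_n)

    ngrams = extract_candidates(gist, stopwords, config.ngram_doc_fraction)
    candidates = candidate_table(ngrams, gist, baseline, stopwords)
    for c in candidates:
        fisher_p(c)
    terms = select_terms(
        candidates,
        alarm.group_id,
        alpha=config.fisher_alpha,
        k_uni=config.top_k_unigrams,
        k_bi=config.top_k_bigrams,
    )
    extracted_terms = [t for t in terms if t != alarm.group_id]

    results = [
        TermSearchResult(
            term=term,
            articles=search_news(
                news_corpus,
                term,
                (alarm.start_date, alarm.end_date),
                limit=config.news_per_term,
            ),
        )
        for term in terms
    ]
    filter_terms(
        results,
        pcss_threshold=config.pcss_threshold,
        relatedness_threshold=config.relatedness_threshold,
    )
    good_terms = [r.term for r in results if r.good]
    top_articles = rank_articles(
        [r for r in results if r.good], top_k=config.top_k_articles
    )

    stt_tweets, stt_source = select_tweet_set(gist, extracted_terms, good_terms)
    stt = (
        rank_tweets(stt_tweets, config.top_k_tweets)
        if stt_source != SttSource.UNAVAILABLE
        else None
    )
    diagnostics = [
        {
            "term": r.term,
            "n_articles": len(r.articles),
            "body_pcss": r.body_pcss,
            "coherent": r.coherent,
            "related_terms": sorted(r.related_terms),
            "good": r.good,
        }
        for r in results
    ]
    return EventSummary(
        event_id=alarm.alarm_id,
        terms=terms,
        good_terms=good_terms,
        top_articles=top_articles,
        gtt=gtt,
        stt=stt,
        stt_source=stt_source,
        summarisable=True,
        term_diagnostics=diagnostics,
    )
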