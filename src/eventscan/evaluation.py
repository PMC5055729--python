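"""Threshold-sweep analysis and seeded synthetic recovery studies.

Two evaluations ship with the package.  The first sweeps the mu_max event
threshold over the packaged 33-event evaluation table and reports precision,
recall and F1 per threshold.  The second is a Monte-Carlo recovery study on
the canonical synthetic scenario: across many seeded worlds, how often does
the pipeline detect the injected burst, reject the spam burst, recover the
planted vocabulary, reject the cross-topic decoy news term, and surface a
planted term in the top summary tweet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .event_detection import EventStatus, threshold_sweep
from .models import RunConfig
from .news_linkage import TermSearchResult, filter_terms, search_news
from .pipeline import ProcessedStream, build_clusters, detect, summarise
from .synthetic_data import default_scenario, generate_news, generate_stream, table4_fixture
from .term_extraction import build_stopwords
from .tweet_ranking import SttSource


def table4_threshold_analysis(
    thresholds: Sequence[float] = tuple(range(21)),
) -> list[dict[str, float]]:
    """Precision/recall/F1 of the mu_max event filter over the packaged table."""
    labelled = [(mu, verified) for _, verified, mu in table4_fixture()]
    return threshold_sweep(labelled, thresholds)


@dataclass
class RecoveryOutcome:
    """Per-seed booleans of the synthetic recovery study."""

    seed: int
    burst_detected: bool
    spam_rejected: bool
    terms_recovered: bool
    decoy_rejected: bool
    stt_top1_planted: bool
    assigned_fraction: float


@dataclass
class RecoveryStudy:
    outcomes: list[RecoveryOutcome] = field(default_factory=list)

    def rate(self, name: str) -> float:
        return float(np.mean([getattr(o, name) for o in self.outcomes]))

    def rates(self) -> dict[str, float]:
        return {
            "burst_detection_rate": self.rate("burst_detected"),
            "spam_rejection_rate": self.rate("spam_rejected"),
            "planted_term_recovery_rate": self.rate("terms_recovered"),
            "decoy_rejection_rate": self.rate("decoy_rejected"),
            "stt_top1_planted_rate": self.rate("stt_top1_planted"),
            "mean_assigned_fraction": self.rate("assigned_fraction"),
        }


def _planted_token_sets(vocabulary: Sequence[str]) -> tuple[set[str], set[str]]:
    """(full planted terms, individual planted tokens)."""
    full = set(vocabulary)
    tokens = {tok for term in vocabulary for tok in term.split()}
    return full, tokens


def run_recovery_seed(seed: int, config: RunConfig | None = None) -> RecoveryOutcome:
    """Run the full pipeline on one seeded synthetic world and score it."""
    config = config or RunConfig()
    scenario = default_scenario(seed)
    tweets, truth = generate_stream(scenario)
    news = generate_news(scenario, truth)
    event_spec = truth.events[0]
    spam_spec = scenario.spam[0]

    model = build_clusters(tweets, config, names={})
    stream = ProcessedStream.process(tweets, model, scenario.groups)
    assigned_fraction = float(np.mean(stream.cluster_ids != model.noise_id))
    result = detect(stream, model, scenario.groups, config)

    city_cluster: dict[str, int] = {}
    for city in scenario.cities:
        city_cluster[city.name] = model.assign(*city.centre)

    def overlapping(alarm, spec_city, spec_group, dates) -> bool:
        return (
            alarm.cluster_id == city_cluster.get(spec_city, -99)
            and alarm.group_id == spec_group
            and alarm.start_date <= dates[1]
            and alarm.end_date >= dates[0]
        )

    burst_alarms = [
        a
        for a in result.alarms
        if overlapping(a, event_spec.city, event_spec.group_id, event_spec.dates)
    ]
    burst_detected = any(
        a.mu_max >= config.mu_max_threshold
        and result.decision_for(a.alarm_id).status == EventStatus.EVENT
        for a in burst_alarms
        if a.tweet_count > 0
    )

    spam_alarms = [
        a
        for a in result.alarms
        if overlapping(a, spam_spec.city, spam_spec.group_id, spam_spec.dates)
        and a.tweet_count > 0
    ]
    spam_rejected = bool(spam_alarms) and all(
        result.decision_for(a.alarm_id).status == EventStatus.REJECTED_SPAM
        for a in spam_alarms
    )

    terms_recovered = False
    decoy_rejected = False
    stt_top1_planted = False
    if burst_detected:
        alarm = max(
            (a for a in burst_alarms if a.tweet_count > 0),
            key=lambda a: a.mu_max,
        )
        stopwords = build_stopwords(stream.tweets, top_n=config.stopword_top_n)
        summary = summarise(
            alarm, stream, model, scenario.groups, news, config, stopwords=stopwords
        )
        full_terms, planted_tokens = _planted_token_sets(event_spec.planted_vocabulary)
        extracted = [t for t in summary.terms if t != alarm.group_id]
        planted_hits = [
            t for t in extracted if t in full_terms or set(t.split()) <= planted_tokens
        ]
        terms_recovered = len(planted_hits) >= 2

        if summary.stt:
            top_tokens = set(summary.stt[0].text.lower().split())
            stt_top1_planted = bool(top_tokens & planted_tokens)

        # decoy check: add the cross-topic decoy term to the event's searches
        decoy_results = [
            TermSearchResult(
                term=term,
                articles=search_news(
                    news, term, (alarm.start_date, alarm.end_date), config.news_per_term
                ),
            )
            for term in summary.terms + list(scenario.news.decoy_terms)
        ]
        filter_terms(
            decoy_results,
            pcss_threshold=config.pcss_threshold,
            relatedness_threshold=config.relatedness_threshold,
        )
        decoy_rejected = all(
            not r.good for r in decoy_results if r.term in scenario.news.decoy_terms
        )

    return RecoveryOutcome(
        seed=seed,
        burst_detected=burst_detected,
        spam_rejected=spam_rejected,
        terms_recovered=terms_recovered,
        decoy_rejected=decoy_rejected,
        stt_top1_planted=stt_top1_planted,
        assigned_fraction=assigned_fraction,
    )


def run_recovery_study(
    n_seeds: int = 100, base_seed: int = 1, config: RunConfig | None = None
) -> RecoveryStudy:
    """Recovery study over ``n_seeds`` independent synthetic worlds."""
    study = RecoveryStudy()
    for i in range(n_seeds):
        seed = (base_seed * 100_003 + i) % (2**31 - 1)
        study.outcomes.append(run_recovery_seed(seed, config))
    return study
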