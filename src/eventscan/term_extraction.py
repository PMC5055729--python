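"""Differential term extraction for event summarisation.

The *gist* (tweets matching the event's keyword group and cluster during the
event period) is contrasted with a *baseline* (same filter, the 28 days
before the event start).  Frequent unigrams and bigrams of the gist are
tested with a one-sided Fisher's exact test for enrichment over the
baseline; the most significant ones, plus the primary keyword that
triggered the alarm, become the event's search terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import Enum
from functools import lru_cache
from typing import Iterable, Sequence

from scipy.stats import fisher_exact

from .event_detection import Alarm
from .geo_clustering import ClusterModel
from .keyword_matching import KeywordMatcher, tokenize
from .models import KeywordGroup, Tweet


@lru_cache(maxsize=1)
def standard_stopwords() -> frozenset[str]:
    """The standard English stopword list (scikit-learn's built-in set)."""
    from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

    return frozenset(ENGLISH_STOP_WORDS)


class SetRole(str, Enum):
    GIST = "gist"
    BASELINE = "baseline"


@dataclass
class TweetSet:
    role: SetRole
    tweets: list[Tweet]
    group_id: str
    cluster_id: int
    date_range: tuple[date, date]

    def __len__(self) -> int:
        return len(self.tweets)


def fetch_sets(
    event: Alarm,
    tweets: Sequence[Tweet],
    model: ClusterModel,
    groups: Iterable[KeywordGroup],
    baseline_days: int = 28,
    min_event_tweets: int = 30,
    cluster_ids: Sequence[int] | None = None,
    group_matches: Sequence[set[str]] | None = None,
) -> tuple[TweetSet, TweetSet, bool]:
    """Gist and baseline tweet sets for an event.

    Returns (gist, baseline, summarisable); events whose gist holds fewer
    than ``min_event_tweets`` tweets do not contain enough text to summarise.
    """
    baseline_range = (
        event.start_date - timedelta(days=baseline_days),
        event.start_date - timedelta(days=1),
    )
    if cluster_ids is None or group_matches is None:
        matcher = KeywordMatcher(groups)
        cluster_ids = [model.assign(t.lat, t.lon) for t in tweets]
        group_matches = [matcher.match_text(t.text) for t in tweets]

    gist_tweets: list[Tweet] = []
    baseline_tweets: list[Tweet] = []
    for tweet, cid, matched in zip(tweets, cluster_ids, group_matches):
        if cid != event.cluster_id or event.group_id not in matched:
            continue
        if event.start_date <= tweet.day <= event.end_date:
            gist_tweets.append(tweet)
        elif baseline_range[0] <= tweet.day <= baseline_range[1]:
            baseline_tweets.append(tweet)
    gist = TweetSet(
        SetRole.GIST, gist_tweets, event.group_id, event.cluster_id,
        (event.start_date, event.end_date),
    )
    baseline = TweetSet(
        SetRole.BASELINE, baseline_tweets, event.group_id, event.cluster_id,
        baseline_range,
    )
    return gist, baseline, len(gist_tweets) >= min_event_tweets


def build_stopwords(
    corpus: Sequence[Tweet | str],
    standard_list: Iterable[str] | None = None,
    top_n: int = 200,
) -> set[str]:
    """Standard stopwords plus the ``top_n`` most frequent corpus tokens.

    The whole tie group at the rank-``top_n`` count is included, so the
    result is independent of any ordering among equally frequent tokens.
    """
    stop = set(standard_stopwords() if standard_list is None else standard_list)
    if top_n <= 0:
        return stop
    freq: dict[str, int] = {}
    for item in corpus:
        text = item.text if isinstance(item, Tweet) else item
        for tok in tokenize(text):
            freq[tok] = freq.get(tok, 0) + 1
    if not freq:
        return stop
    by_count = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(by_count) <= top_n:
        stop.update(tok for tok, _ in by_count)
        return stop
    cutoff = by_count[top_n - 1][1]
    stop.update(tok for tok, count in freq.items() if count >= cutoff)
    return stop


def _tweet_ngrams(text: str, stopwords: set[str] | frozenset[str]) -> set[str]:
    """Unigrams and bigrams of the stopword-free token sequence of one tweet.

    Bigrams are formed from tokens adjacent *after* stopword removal, so
    "air pollution" survives an intervening "the".  Presence is binary per
    tweet.
    """
    toks = [t for t in tokenize(text) if t not in stopwords]
    grams = set(toks)
    grams.update(f"{a} {b}" for a, b in zip(toks, toks[1:]))
    return grams


def extract_candidates(
    gist: TweetSet | Sequence[Tweet],
    stopwords: set[str] | frozenset[str],
    doc_fraction: float = 0.05,
) -> list[str]:
    """N-grams occurring in at least ceil(doc_fraction * |gist|) distinct tweets."""
    tweets = gist.tweets if isinstance(gist, TweetSet) else list(gist)
    if not tweets:
        raise ValueError("gist must be non-empty")
    threshold = math.ceil(doc_fraction * len(tweets))
    doc_freq: dict[str, int] = {}
    for t in tweets:
        for gram in _tweet_ngrams(t.text if isinstance(t, Tweet) else t, stopwords):
            doc_freq[gram] = doc_freq.get(gram, 0) + 1
    return sorted(g for g, c in doc_freq.items() if c >= max(threshold, 1))


@dataclass
class TermCandidate:
    """2x2 tweet-presence table for one n-gram, with its Fisher p-value."""

    ngram: str
    gist_tweets_with: int
    gist_tweets_without: int
    baseline_tweets_with: int
    baseline_tweets_without: int
    p_value: float = float("nan")

    @property
    def n_tokens(self) -> int:
        return len(self.ngram.split())


def count_candidate(
    ngram: str,
    gist: TweetSet | Sequence[Tweet],
    baseline: TweetSet | Sequence[Tweet],
    stopwords: set[str] | frozenset[str],
) -> TermCandidate:
    gist_tweets = gist.tweets if isinstance(gist, TweetSet) else list(gist)
    base_tweets = baseline.tweets if isinstance(baseline, TweetSet) else list(baseline)
    gw = sum(1 for t in gist_tweets if ngram in _tweet_ngrams(t.text, stopwords))
    bw = sum(1 for t in base_tweets if ngram in _tweet_ngrams(t.text, stopwords))
    return TermCandidate(
        ngram=ngram,
        gist_tweets_with=gw,
        gist_tweets_without=len(gist_tweets) - gw,
        baseline_tweets_with=bw,
        baseline_tweets_without=len(base_tweets) - bw,
    )


def candidate_table(
    ngrams: Sequence[str],
    gist: TweetSet | Sequence[Tweet],
    baseline: TweetSet | Sequence[Tweet],
    stopwords: set[str] | frozenset[str],
) -> list[TermCandidate]:
    """Presence tables for many n-grams at once (one pass over each tweet)."""
    gist_tweets = gist.tweets if isinstance(gist, TweetSet) else list(gist)
    base_tweets = baseline.tweets if isinstance(baseline, TweetSet) else list(baseline)
    wanted = set(ngrams)
    gw: dict[str, int] = {g: 0 for g in wanted}
    bw: dict[str, int] = {g: 0 for g in wanted}
    for t in gist_tweets:
        for g in _tweet_ngrams(t.text, stopwords) & wanted:
            gw[g] += 1
    for t in base_tweets:
        for g in _tweet_ngrams(t.text, stopwords) & wanted:
            bw[g] += 1
    return [
        TermCandidate(
            ngram=g,
            gist_tweets_with=gw[g],
            gist_tweets_without=len(gist_tweets) - gw[g],
            baseline_tweets_with=bw[g],
            baseline_tweets_without=len(base_tweets) - bw[g],
        )
        for g in ngrams
    ]


def fisher_p(candidate: TermCandidate) -> float:
    """One-sided (gist-enriched) Fisher's exact p-value for the 2x2 table."""
    table = [
        [candidate.gist_tweets_with, candidate.gist_tweets_without],
        [candidate.baseline_tweets_with, candidate.baseline_tweets_without],
    ]
    if sum(table[0]) + sum(table[1]) == 0:
        return 1.0
    _, p = fisher_exact(table, alternative="greater")
    candidate.p_value = float(p)
    return candidate.p_value


def select_terms(
    candidates: Sequence[TermCandidate],
    primary_keyword: str,
    alpha: float = 0.05,
    k_uni: int = 2,
    k_bi: int = 2,
) -> list[str]:
    """The most significant unigrams and bigrams, plus the primary keyword.

    Among candidates with p < alpha, the ``k_uni`` smallest-p unigrams and
    ``k_bi`` smallest-p bigrams are taken (ties by higher gist count, then
    lexicographic).  The primary keyword is appended (deduplicated); if no
    candidate is significant the result is just the primary keyword, which
    signals callers to fall back to gist-only summarisation.
    """
    significant = [c for c in candidates if c.p_value < alpha]
    key = lambda c: (c.p_value, -c.gist_tweets_with, c.ngram)
    unigrams = sorted((c for c in significant if c.n_tokens == 1), key=key)[:k_uni]
    bigrams = sorted((c for c in significant if c.n_tokens == 2), key=key)[:k_bi]
    terms = [c.ngram for c in unigrams] + [c.ngram for c in bigrams]
    if primary_keyword not in terms:
        terms.append(primary_keyword)
    return terms
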