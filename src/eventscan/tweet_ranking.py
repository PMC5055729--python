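"""Representative-tweet selection for event summaries.

Two ranked lists are produced per event: the *Gist Top Tweets* (GTT), ranked
over every gist tweet, and the *Summary Top Tweets* (STT), ranked over the
gist tweets containing a good search term — falling back to the extracted
terms when no term survived the news-coherence checks, and absent when no
term was significant at all.  Ranking is centroid-based: each tweet is
scored by cosine similarity to the mean TF-IDF vector of its set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .keyword_matching import tokenize
from .models import NewsArticle, Tweet
from .term_extraction import TweetSet, standard_stopwords
from .vectors import cosine, count_terms, mean_vector, tfidf_vectors


class SttSource(str, Enum):
    GOOD_TERMS = "good_terms"
    EXTRACTED_TERMS = "extracted_terms"
    UNAVAILABLE = "unavailable"


def _contains_term(tokens: Sequence[str], term_tokens: tuple[str, ...]) -> bool:
    k = len(term_tokens)
    return any(tuple(tokens[i : i + k]) == term_tokens for i in range(len(tokens) - k + 1))


def select_tweet_set(
    gist: TweetSet | Sequence[Tweet],
    extracted_terms: Sequence[str],
    good_terms: Sequence[str],
) -> tuple[list[Tweet], SttSource]:
    """The tweet set the STT is ranked over, with its provenance.

    Preference order: gist tweets containing a good search term; else gist
    tweets containing an extracted term beyond the primary keyword; else no
    STT (GTT only).  Term containment uses stopword-free token phrases, the
    same matcher the extraction step used.  A preferred set that matches no
    tweet falls through to the next option.
    """
    tweets = list(gist.tweets if isinstance(gist, TweetSet) else gist)
    stop = standard_stopwords()
    token_cache = [
        [tok for tok in tokenize(t.text) if tok not in stop] for t in tweets
    ]

    def matching(terms: Sequence[str]) -> list[Tweet]:
        phrases = [tuple(tok for tok in tokenize(term) if tok not in stop) for term in terms]
        phrases = [p for p in phrases if p]
        return [
            t
            for t, toks in zip(tweets, token_cache)
            if any(_contains_term(toks, p) for p in phrases)
        ]

    if good_terms:
        selected = matching(good_terms)
        if selected:
            return selected, SttSource.GOOD_TERMS
    if extracted_terms:
        selected = matching(extracted_terms)
        if selected:
            return selected, SttSource.EXTRACTED_TERMS
    return [], SttSource.UNAVAILABLE


def rank_tweets(tweets: Sequence[Tweet], top_k: int = 5) -> list[Tweet]:
    """Tweets ranked by cosine similarity to the set's mean TF-IDF vector.

    Tweet vectors are unstemmed stopword-free unigrams with tf*ln(N/df)
    weights over the set; ties break by earlier timestamp then id.
    """
    tweets = list(tweets)
    if not tweets:
        return []
    stop = standard_stopwords()
    counts = [
        count_terms([tok for tok in tokenize(t.text) if tok not in stop])
        for t in tweets
    ]
    vectors = tfidf_vectors(counts)
    centre = mean_vector(vectors)
    scored = sorted(
        zip(vectors, tweets),
        key=lambda vt: (-cosine(vt[0], centre), vt[1].timestamp, vt[1].id),
    )
    return [t for _, t in scored[:top_k]]


@dataclass
class EventSummary:
    """Everything the pipeline reports for one event."""

    event_id: str
    terms: list[str]
    good_terms: list[str]
    top_articles: list[NewsArticle]
    gtt: list[Tweet]
    stt: list[Tweet] | None
    stt_source: SttSource
    summarisable: bool = True
    term_diagnostics: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.stt is None) != (self.stt_source == SttSource.UNAVAILABLE):
            raise ValueError("stt must be present iff stt_source is not unavailable")

    def to_dict(self) -> dict:
        def tweet_ref(t: Tweet) -> dict:
            return {"id": t.id, "text": t.text, "timestamp": t.timestamp.isoformat()}

        return {
            "event_id": self.event_id,
            "terms": self.terms,
            "good_terms": self.good_terms,
            "top_articles": [
                {"article_id": a.article_id, "title": a.title, "url": a.url}
                for a in self.top_articles
            ],
            "gtt": [tweet_ref(t) for t in self.gtt],
            "stt": None if self.stt is None else [tweet_ref(t) for t in self.stt],
            "stt_source": self.stt_source.value,
            "summarisable": self.summarisable,
            "term_diagnostics": self.term_diagnostics,
        }
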