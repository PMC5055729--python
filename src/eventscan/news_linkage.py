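"""Linking detected events to news: search, coherence filtering, ranking.

Each selected search term retrieves up to ten articles from a local news
corpus (the production stand-in for a web news search).  A term is only
trusted when (a) its retrieved set is topically *coherent* — the PCSS of the
articles' TF-IDF body vectors is above a threshold — and (b) the set is
*related* to at least one other term's set, judged by a cross-set PCSS over
title vectors.  A lone term retrieving a coherent but unrelated story (the
classic off-topic hit) is thereby dropped.  Articles of the surviving
"good" terms are ranked by cosine similarity to their set's mean vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable, Iterable, Sequence

from .keyword_matching import tokenize
from .models import NewsArticle
from .stemming import porter_stem
from .term_extraction import standard_stopwords
from .vectors import (
    TermVector,
    cosine,
    count_terms,
    cross_pcss,
    mean_vector,
    pcss,
    tfidf_vectors,
)

Stemmer = Callable[[str], str]


def _content_tokens(
    text: str, stopwords: frozenset[str] | set[str], stemmer: Stemmer | None
) -> list[str]:
    toks = [t for t in tokenize(text) if t not in stopwords]
    if stemmer is not None:
        toks = [stemmer(t) for t in toks]
    return toks


def search_news(
    corpus: Sequence[NewsArticle],
    term: str,
    date_range: tuple[date, date],
    limit: int = 10,
) -> list[NewsArticle]:
    """Top articles for a term, ranked by TF-IDF cosine relevance.

    Articles dated in [start, end + 1 day] (events are reported up to a day
    later) are scored by the cosine between the term's token vector and the
    article's title+body vector, title tokens counted twice.  Only articles
    with positive relevance are hits; ties break by date then article id.
    """
    start, end = date_range
    stop = standard_stopwords()
    in_range = [a for a in corpus if start <= a.date <= end + timedelta(days=1)]
    if not in_range:
        return []
    doc_counts = []
    for a in in_range:
        title_toks = _content_tokens(a.title, stop, None)
        body_toks = _content_tokens(a.body, stop, None)
        doc_counts.append(count_terms(title_toks + title_toks + body_toks))
    vectors = tfidf_vectors(doc_counts)
    query_toks = _content_tokens(term, stop, None)
    query = {t: 1.0 for t in query_toks}
    scored = [
        (cosine(query, vec), a) for a, vec in zip(in_range, vectors)
    ]
    hits = [(s, a) for s, a in scored if s > 0.0]
    hits.sort(key=lambda sa: (-sa[0], sa[1].date, sa[1].article_id))
    return [a for _, a in hits[:limit]]


def body_vectors(
    articles: Sequence[NewsArticle], stemmer: Stemmer | None = porter_stem
) -> list[TermVector]:
    """Stemmed unigram TF-IDF vectors of title+body over the retrieved set."""
    stop = standard_stopwords()
    counts = [
        count_terms(_content_tokens(a.title + " " + a.body, stop, stemmer))
        for a in articles
    ]
    return tfidf_vectors(counts)


def body_vector(
    article: NewsArticle,
    corpus_for_idf: Sequence[NewsArticle],
    stemmer: Stemmer | None = porter_stem,
) -> TermVector:
    """TF-IDF vector of one article, with IDF from the retrieved set it sits in."""
    docs = list(corpus_for_idf)
    if article not in docs:
        docs = docs + [article]
    return body_vectors(docs, stemmer)[docs.index(article)]


def title_vectors(
    set_a: Sequence[NewsArticle], set_b: Sequence[NewsArticle]
) -> tuple[list[TermVector], list[TermVector]]:
    """Unstemmed uni/bi/trigram TF-IDF title vectors, IDF over both sets.

    Titles are short, so all n-grams up to trigrams are kept as features;
    the IDF corpus is the union of the two title sets being compared.
    """
    stop = standard_stopwords()
    counts = [
        count_terms(_content_tokens(a.title, stop, None), ngram_range=(1, 3))
        for a in list(set_a) + list(set_b)
    ]
    vectors = tfidf_vectors(counts)
    return vectors[: len(set_a)], vectors[len(set_a) :]


def title_vector(article: NewsArticle, title_set: Sequence[NewsArticle]) -> TermVector:
    docs = list(title_set)
    if article not in docs:
        docs = docs + [article]
    stop = standard_stopwords()
    counts = [
        count_terms(_content_tokens(a.title, stop, None), ngram_range=(1, 3))
        for a in docs
    ]
    return tfidf_vectors(counts)[docs.index(article)]


@dataclass
class TermSearchResult:
    """One search term with its retrieved articles and coherence verdicts."""

    term: str
    articles: list[NewsArticle]
    body_pcss: float = float("nan")
    coherent: bool = False
    related_terms: set[str] = field(default_factory=set)
    good: bool = False


def filter_terms(
    results: Sequence[TermSearchResult],
    pcss_threshold: float = -0.08,
    relatedness_threshold: float = -0.08,
    stemmer: Stemmer | None = porter_stem,
) -> list[TermSearchResult]:
    """Mark each term coherent/related/good in place and return the list.

    coherent: the body-vector PCSS of the term's retrieved set reaches
    ``pcss_threshold`` (a term with fewer than two hits cannot be scored and
    is not coherent).  good: coherent and related (by title cross-PCSS at
    ``relatedness_threshold``) to at least one other coherent term.
    """
    for r in results:
        r.related_terms = set()
        r.good = False
        if len(r.articles) >= 2:
            r.body_pcss = pcss(body_vectors(r.articles, stemmer))
            r.coherent = r.body_pcss >= pcss_threshold
        else:
            r.body_pcss = float("nan")
            r.coherent = False
    coherent = [r for r in results if r.coherent]
    for i, a in enumerate(coherent):
        for b in coherent[i + 1 :]:
            va, vb = title_vectors(a.articles, b.articles)
            if cross_pcss(va, vb) >= relatedness_threshold:
                a.related_terms.add(b.term)
                b.related_terms.add(a.term)
    for r in coherent:
        r.good = bool(r.related_terms)
    return list(results)


def rank_articles(
    good_results: Sequence[TermSearchResult],
    top_k: int = 5,
    stemmer: Stemmer | None = porter_stem,
) -> list[NewsArticle]:
    """Top articles across the good terms, by cosine to each set's mean vector.

    Within a term's set each article is scored against the set's arithmetic
    mean TF-IDF vector; sets are merged with per-article deduplication
    keeping the higher score.  Returns an empty list when no term is good
    (the caller reports "no newsworthy match").
    """
    best: dict[str, tuple[float, int, NewsArticle]] = {}
    order = 0
    for result in good_results:
        if not result.good or not result.articles:
            continue
        vectors = body_vectors(result.articles, stemmer)
        centre = mean_vector(vectors)
        for article, vec in zip(result.articles, vectors):
            score = cosine(vec, centre)
            prev = best.get(article.article_id)
            if prev is None:
                best[article.article_id] = (score, order, article)
                order += 1
            elif score > prev[0]:
                best[article.article_id] = (score, prev[1], article)
    ranked = sorted(best.values(), key=lambda t: (-t[0], t[1]))
    return [a for _, _, a in ranked[:top_k]]
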