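"""Sparse weighted-term vectors and cosine-similarity coherence scores.

Documents are represented as sparse term -> weight maps with tf*ln(N/df)
weighting computed over the document set at hand (no global corpus exists
for a retrieved article group, so the set itself supplies the IDF).  The
Pairwise Cosine Similarity Score (PCSS) of a set of vectors is the mean of
all pairwise cosines minus their (population) standard deviation: it
rewards uniformly similar sets and penalises sets where only a few pairs
are related.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Iterable, Mapping, Sequence

TermVector = dict[str, float]


def count_terms(tokens: Sequence[str], ngram_range: tuple[int, int] = (1, 1)) -> TermVector:
    """Raw term frequencies of the n-grams (space-joined) of a token list."""
    lo, hi = ngram_range
    tf: TermVector = {}
    for n in range(lo, hi + 1):
        for i in range(len(tokens) - n + 1):
            term = " ".join(tokens[i : i + n])
            tf[term] = tf.get(term, 0.0) + 1.0
    return tf


def tfidf_vectors(term_counts: Sequence[TermVector]) -> list[TermVector]:
    """tf * ln(N/df) over the given set; terms present in every document vanish."""
    n = len(term_counts)
    df: dict[str, int] = {}
    for tc in term_counts:
        for term in tc:
            df[term] = df.get(term, 0) + 1
    out = []
    for tc in term_counts:
        vec = {}
        for term, tf in tc.items():
            idf = math.log(n / df[term])
            if idf > 0.0 and tf > 0.0:
                vec[term] = tf * idf
        out.append(vec)
    return out


def cosine(a: Mapping[str, float], b: Mapping[str, float]) -> float:
    """Cosine similarity; defined as 0 when either vector is empty."""
    if not a or not b:
        return 0.0
    if len(b) < len(a):
        a, b = b, a
    dot = sum(w * b[t] for t, w in a.items() if t in b)
    na = math.sqrt(sum(w * w for w in a.values()))
    nb = math.sqrt(sum(w * w for w in b.values()))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return dot / (na * nb)


def mean_vector(vectors: Sequence[Mapping[str, float]]) -> TermVector:
    """Arithmetic mean of sparse vectors."""
    out: TermVector = {}
    if not vectors:
        return out
    for vec in vectors:
        for term, w in vec.items():
            out[term] = out.get(term, 0.0) + w
    n = len(vectors)
    return {t: w / n for t, w in out.items() if w != 0.0}


def _mean_minus_std(values: Sequence[float]) -> float:
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n  # population form
    return mean - math.sqrt(var)


def pcss(vectors: Sequence[Mapping[str, float]]) -> float:
    """Pairwise Cosine Similarity Score over all unordered distinct pairs."""
    if len(vectors) < 2:
        raise ValueError("pcss needs at least two vectors")
    cosines = [cosine(a, b) for a, b in combinations(vectors, 2)]
    return _mean_minus_std(cosines)


def cross_pcss(
    set_a: Sequence[Mapping[str, float]], set_b: Sequence[Mapping[str, float]]
) -> float:
    """PCSS over all cross-set pairs (a, b); within-set pairs are excluded."""
    if not set_a or not set_b:
        raise ValueError("both vector sets must be non-empty")
    cosines = [cosine(a, b) for a in set_a for b in set_b]
    return _mean_minus_std(cosines)
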