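"""PCSS, TF-IDF vectors, news search and coherence filtering."""

import math
from datetime import date

import pytest
from hypothesis import given, strategies as st

from eventscan.models import NewsArticle
from eventscan.news_linkage import (
    TermSearchResult,
    body_vector,
    body_vectors,
    filter_terms,
    rank_articles,
    search_news,
    title_vector,
    title_vectors,
)
from eventscan.stemming import porter_stem
from eventscan.vectors import cosine, cross_pcss, mean_vector, pcss


def _art(aid, title, body="", day=date(2014, 4, 2)):
    return NewsArticle(aid, title, body, day)


# ---------------------------------------------------------------- pcss

V1 = {"x": 1.0}
V2 = {"x": 1.0, "y": 1.0}
V3 = {"y": 1.0}


def test_pcss_identical_vectors_is_one():
    assert pcss([V1, V1, V1]) == pytest.approx(1.0)


def test_pcss_orthogonal_vectors_is_zero():
    a, b, c = {"x": 1.0}, {"y": 1.0}, {"z": 1.0}
    assert pcss([a, b, c]) == pytest.approx(0.0)


def test_pcss_worked_example():
    # cosines {0.7071, 0, 0.7071}: mean 0.4714, population std 0.3333
    assert pcss([V1, V2, V3]) == pytest.approx(0.1381, abs=1e-4)


def test_pcss_requires_two_vectors():
    with pytest.raises(ValueError):
        pcss([V1])


def test_pcss_permutation_invariant():
    assert pcss([V1, V2, V3]) == pytest.approx(pcss([V3, V1, V2]))


def test_pcss_scale_invariant():
    scaled = [{t: 7.5 * w for t, w in v.items()} for v in (V1, V2, V3)]
    assert pcss(scaled) == pytest.approx(pcss([V1, V2, V3]))


@given(st.lists(st.dictionaries(st.sampled_from("abcde"), st.floats(0.1, 5)), min_size=2, max_size=6))
def test_pcss_at_most_one(vectors):
    assert pcss(vectors) <= 1.0 + 1e-12


def test_cross_pcss_single_identical_pair():
    assert cross_pcss([V1], [V1]) == pytest.approx(1.0)


def test_cross_pcss_disjoint_vocabularies():
    assert cross_pcss([{"a": 1.0}, {"b": 2.0}], [{"z": 1.0}]) == pytest.approx(0.0)


def test_cross_pcss_hand_computed():
    a = [{"x": 1.0}, {"y": 1.0}]
    b = [{"x": 1.0}, {"x": 1.0, "y": 1.0}, {"z": 1.0}]
    r2 = 1 / math.sqrt(2)
    cosines = [1.0, r2, 0.0, 0.0, r2, 0.0]
    mean = sum(cosines) / 6
    std = math.sqrt(sum((c - mean) ** 2 for c in cosines) / 6)
    assert cross_pcss(a, b) == pytest.approx(mean - std)


def test_cross_pcss_symmetric():
    a = [{"x": 1.0}, {"y": 1.0, "z": 0.5}]
    b = [{"x": 1.0, "y": 1.0}]
    assert cross_pcss(a, b) == pytest.approx(cross_pcss(b, a))


def test_cross_pcss_empty_set_errors():
    with pytest.raises(ValueError):
        cross_pcss([], [V1])


# ---------------------------------------------------------------- vectors

def test_identical_documents_identical_vectors():
    a = _art("a", "smog alert", "heavy smog tonight")
    b = _art("b", "smog alert", "heavy smog tonight")
    va, vb = body_vectors([a, b])
    assert va == vb  # shared terms vanish identically (df = N)


def test_term_in_every_document_vanishes():
    docs = [_art(str(i), f"smog word{i}") for i in range(3)]
    vecs = body_vectors(docs)
    assert all("smog" not in v for v in vecs)


def test_body_vector_hand_computed():
    # stems chosen to be stemming-stable; counts listed by hand
    docs = [
        _art("a", "dust", "dust dust wind"),
        _art("b", "wind", "storm"),
        _art("c", "storm", "dust storm"),
    ]
    vecs = body_vectors(docs, stemmer=None)
    n = 3
    # dust: docs a (tf 3), c (tf 1) -> df 2; wind: a, b -> df 2; storm: b, c -> df 2
    ln = math.log
    assert vecs[0] == pytest.approx({"dust": 3 * ln(n / 2), "wind": 1 * ln(n / 2)})
    assert vecs[1] == pytest.approx({"wind": 1 * ln(n / 2), "storm": 1 * ln(n / 2)})
    assert vecs[2] == pytest.approx({"storm": 2 * ln(n / 2), "dust": 1 * ln(n / 2)})


def test_body_vector_applies_stemming():
    docs = [_art("a", "polluted city", "pollution rising"), _art("b", "clean air", "no pollution")]
    vec = body_vector(docs[0], docs)
    assert porter_stem("polluted") == porter_stem("pollution")
    # both variants collapse onto one stem, so no distinct "polluted" feature
    assert "polluted" not in vec


def test_title_vector_ngram_features():
    other = _art("b", "completely different words here")
    vec = title_vector(_art("a", "air pollution reaches high levels"), [other])
    assert "air pollution" in vec
    assert "air pollution reaches" in vec


def test_disjoint_titles_cosine_zero():
    va, vb = title_vectors([_art("a", "alpha beta")], [_art("b", "gamma delta")])
    assert cosine(va[0], vb[0]) == 0.0


def test_stopword_only_document_gives_empty_vector():
    docs = [_art("a", "something", ""), _art("b", "other words", "more words")]
    assert body_vector(_art("c", "the", ""), docs) == {}


# ---------------------------------------------------------------- search

CORPUS = [
    _art("n1", "smog blankets city", "smog levels rise across the city", date(2014, 4, 2)),
    _art("n2", "heavy smog warning", "warning issued for smog", date(2014, 4, 3)),
    _art("n3", "smog mention", "a single smog note plus football", date(2014, 4, 3)),
    _art("n4", "football roundup", "match report football", date(2014, 4, 2)),
    _art("n5", "smog out of range", "smog article dated too late", date(2014, 4, 20)),
]


def test_search_returns_matching_in_range_articles():
    hits = search_news(CORPUS, "smog", (date(2014, 4, 1), date(2014, 4, 4)))
    assert {a.article_id for a in hits} == {"n1", "n2", "n3"}


def test_search_excludes_out_of_window_dates():
    hits = search_news(CORPUS, "smog", (date(2014, 4, 1), date(2014, 4, 4)))
    assert "n5" not in {a.article_id for a in hits}


def test_search_respects_limit_and_determinism():
    hits1 = search_news(CORPUS, "smog", (date(2014, 4, 1), date(2014, 4, 4)), limit=2)
    hits2 = search_news(CORPUS, "smog", (date(2014, 4, 1), date(2014, 4, 4)), limit=2)
    assert len(hits1) == 2 and hits1 == hits2


# ---------------------------------------------------------------- filtering

def _coherent_set(prefix, vocab=("smog", "dust", "haze"), n=4, day=date(2014, 4, 2)):
    """Articles that each use 2 of 3 shared vocabulary words: every pair
    overlaps, but no word is universal, so TF-IDF keeps the shared signal."""
    pairs = [(0, 1), (1, 2), (0, 2)]
    arts = []
    for i in range(n):
        a, b = pairs[i % 3]
        picks = f"{vocab[a]} {vocab[b]}"
        arts.append(
            _art(f"{prefix}{i}", f"{picks} alert", f"{picks} {picks} note{i}", day)
        )
    return arts


def test_incoherent_term_fails_pcss_threshold():
    mixed = [
        _art("a1", "aaa bbb", "aaa aaa bbb bbb xx"),
        _art("a2", "aaa bbb", "aaa aaa bbb bbb yy"),
        _art("b1", "ccc ddd", "ccc ccc ddd ddd zz"),
        _art("c1", "eee fff", "eee eee fff fff ww"),
        _art("d1", "ggg hhh", "ggg ggg hhh hhh vv"),
    ]
    r = TermSearchResult("mixed", mixed)
    filter_terms([r])
    assert r.body_pcss < -0.08 and not r.coherent


def test_lone_coherent_term_is_not_good():
    r = TermSearchResult("solo", _coherent_set("s"))
    filter_terms([r])
    assert r.coherent and not r.good


def test_related_terms_are_good():
    shared = _coherent_set("s")
    a = TermSearchResult("smog", shared)
    b = TermSearchResult("dust", shared)
    filter_terms([a, b])
    assert a.good and b.good
    assert "dust" in a.related_terms


def test_few_articles_not_coherent():
    r = TermSearchResult("thin", CORPUS[:1])
    filter_terms([r])
    assert not r.coherent


# ---------------------------------------------------------------- ranking

def test_rank_articles_identical_set_keeps_order():
    arts = [_art(f"a{i}", "same title", "same body words") for i in range(4)]
    r = TermSearchResult("t", arts)
    r.good = True
    ranked = rank_articles([r], top_k=3)
    assert [a.article_id for a in ranked] == ["a0", "a1", "a2"]


def test_union_article_ranks_first():
    arts = [
        _art("a", "dust storm", "dust dust alpha"),
        _art("b", "wind storm", "wind wind beta"),
        _art("u", "dust wind", "dust wind alpha beta"),
    ]
    r = TermSearchResult("t", arts)
    r.good = True
    ranked = rank_articles([r], top_k=3, stemmer=None)
    assert ranked[0].article_id == "u"


def test_no_good_terms_empty_ranking():
    r = TermSearchResult("t", _coherent_set("x"))
    r.good = False
    assert rank_articles([r]) == []


def test_rank_articles_dedups_by_id():
    arts = _coherent_set("s")
    r1 = TermSearchResult("t1", arts)
    r2 = TermSearchResult("t2", arts)
    r1.good = r2.good = True
    ranked = rank_articles([r1, r2], top_k=10)
    assert len(ranked) == len(arts)
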