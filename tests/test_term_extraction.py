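"""Term extraction tests, with an explicit hypergeometric Fisher oracle."""

from datetime import date, timedelta
from math import comb

import pytest

from eventscan.event_detection import Alarm
from eventscan.geo_clustering import build_cluster_model
from eventscan.models import KeywordGroup
from eventscan.term_extraction import (
    TermCandidate,
    build_stopwords,
    candidate_table,
    count_candidate,
    extract_candidates,
    fetch_sets,
    fisher_p,
    select_terms,
)

from conftest import make_tweet


def hypergeom_fisher_greater(a, b, c, d):
    """One-sided Fisher p by explicit enumeration over all feasible tables."""
    row1, col1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    total = comb(n, col1)
    return sum(
        comb(row1, x) * comb(n - row1, col1 - x) for x in range(a, hi + 1)
    ) / total


# ---------------------------------------------------------------- fetch_sets

LONDON = [(51.3, -0.3), (51.3, 0.1), (51.7, 0.1), (51.7, -0.3)]


def _event(start, end):
    return Alarm("asthma", 0, start, end, [])


def test_fetch_sets_filters_and_baseline_window():
    model = build_cluster_model(LONDON, [0] * 4)
    groups = [KeywordGroup("asthma", ()), KeywordGroup("flu", ())]
    start, end = date(2014, 4, 2), date(2014, 4, 3)
    tweets = [
        make_tweet("in1", "asthma is bad", day=start, lat=51.5, lon=-0.1),
        make_tweet("in2", "asthma again", day=end, lat=51.5, lon=-0.1),
        make_tweet("wrong_group", "the flu", day=start, lat=51.5, lon=-0.1),
        make_tweet("wrong_place", "asthma", day=start, lat=55.0, lon=-3.0),
        make_tweet("before", "asthma", day=start - timedelta(days=10), lat=51.5, lon=-0.1),
        make_tweet("long_before", "asthma", day=start - timedelta(days=29), lat=51.5, lon=-0.1),
    ]
    gist, baseline, ok = fetch_sets(_event(start, end), tweets, model, groups)
    assert [t.id for t in gist.tweets] == ["in1", "in2"]
    assert [t.id for t in baseline.tweets] == ["before"]
    assert baseline.date_range == (start - timedelta(days=28), start - timedelta(days=1))
    assert not ok  # 2 < 30


def test_min_event_tweets_boundary():
    model = build_cluster_model(LONDON, [0] * 4)
    groups = [KeywordGroup("asthma", ())]
    start = date(2014, 4, 2)
    tweets = [
        make_tweet(f"t{i}", "asthma", day=start, lat=51.5, lon=-0.1) for i in range(29)
    ]
    *_, ok = fetch_sets(_event(start, start), tweets, model, groups)
    assert not ok
    tweets.append(make_tweet("t29", "asthma", day=start, lat=51.5, lon=-0.1))
    *_, ok = fetch_sets(_event(start, start), tweets, model, groups)
    assert ok


# ---------------------------------------------------------------- stopwords

def test_top_frequency_token_becomes_stopword():
    corpus = ["lol what a day", "lol again", "lol lol"]
    assert "lol" in build_stopwords(corpus, standard_list=[], top_n=1)


def test_empty_standard_list_and_zero_top_n():
    assert build_stopwords(["a b c"], standard_list=[], top_n=0) == set()


def test_top_n_matches_independent_counter():
    words = [f"w{i}" for i in range(50)]
    corpus = []
    for i, w in enumerate(words):
        corpus.extend([w] * (i + 1))  # w49 most frequent
    stop = build_stopwords(corpus, standard_list=[], top_n=10)
    # independent counter: the ten highest-count tokens
    expected = set(words[-10:])
    assert stop == expected


def test_tie_group_fully_included():
    corpus = ["aa aa", "bb bb", "cc"]
    stop = build_stopwords(corpus, standard_list=[], top_n=1)
    assert stop == {"aa", "bb"}  # both tied at the cutoff count


# ---------------------------------------------------------------- candidates

def test_doc_fraction_threshold_both_directions():
    gist = [make_tweet(f"s{i}", "smog here", user_id=f"u{i}") for i in range(3)]
    gist += [make_tweet(f"o{i}", "other text", user_id=f"v{i}") for i in range(37)]
    # ceil(0.05 * 40) = 2 <= 3 occurrences -> included
    assert "smog" in extract_candidates(gist, set(), 0.05)
    one = gist[:1] + gist[3:]
    # 1 < 2 -> excluded
    assert "smog" not in extract_candidates(one, set(), 0.05)


def test_bigrams_bridge_removed_stopwords():
    gist = [make_tweet("a", "bad smog in the air")]
    grams = extract_candidates(gist, {"in", "the"}, 0.05)
    assert "bad smog" in grams and "smog air" in grams
    assert "the air" not in grams


def test_candidates_match_brute_force_recount():
    texts = [
        "alpha beta gamma",
        "alpha beta",
        "beta gamma delta",
        "alpha alpha beta",
        "epsilon zeta",
    ]
    gist = [make_tweet(f"t{i}", text) for i, text in enumerate(texts)]
    got = set(extract_candidates(gist, {"delta"}, 0.4))  # ceil(0.4*5)=2 tweets
    counts = {}
    for text in texts:
        toks = [w for w in text.split() if w != "delta"]
        seen = set(toks) | {f"{a} {b}" for a, b in zip(toks, toks[1:])}
        for g in seen:
            counts[g] = counts.get(g, 0) + 1
    assert got == {g for g, c in counts.items() if c >= 2}


# ---------------------------------------------------------------- fisher

def _cand(a, b, c, d):
    return TermCandidate("x", a, b, c, d)


def test_fisher_no_gist_occurrences_p_one():
    assert fisher_p(_cand(0, 10, 5, 5)) == pytest.approx(1.0)


def test_fisher_hand_enumeration():
    # gist 8/10 vs baseline 2/10: sum over tables with gist-with in {8,9,10}
    expected = (comb(10, 8) * comb(10, 2) + comb(10, 9) * comb(10, 1) + 1) / comb(20, 10)
    assert fisher_p(_cand(8, 2, 2, 8)) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(2126 / 184756)


def test_fisher_equal_proportions_not_significant():
    assert fisher_p(_cand(20, 80, 20, 80)) > 0.05


def test_fisher_all_zero_table():
    assert fisher_p(_cand(0, 0, 0, 0)) == 1.0


def test_fisher_matches_oracle_small_margins():
    for n1 in range(0, 13, 3):
        for a in range(n1 + 1):
            for n2 in range(0, 13, 4):
                for c in range(n2 + 1):
                    cand = _cand(a, n1 - a, c, n2 - c)
                    assert fisher_p(cand) == pytest.approx(
                        hypergeom_fisher_greater(a, n1 - a, c, n2 - c), abs=1e-10
                    )


# ---------------------------------------------------------------- selection

def _scored(ngram, p, gist_with=10):
    c = TermCandidate(ngram, gist_with, 10, 0, 10)
    c.p_value = p
    return c


def test_select_terms_top_unigrams_and_bigrams():
    cands = [
        _scored("smog", 1e-9),
        _scored("pollution", 1e-7),
        _scored("cloud", 1e-3),
        _scored("air pollution", 1e-8),
        _scored("saharan dust", 1e-4),
        _scored("dust cloud", 0.2),
    ]
    terms = select_terms(cands, "asthma", alpha=0.05)
    assert terms == ["smog", "pollution", "air pollution", "saharan dust", "asthma"]
    assert len(terms) <= 2 + 2 + 1


def test_select_terms_fallback_to_primary():
    assert select_terms([_scored("x", 0.5)], "vomit") == ["vomit"]


def test_select_terms_dedups_primary():
    assert select_terms([_scored("vomit", 1e-6)], "vomit") == ["vomit"]


def test_count_candidate_and_batch_agree():
    gist = [make_tweet(f"g{i}", t) for i, t in enumerate(["a b", "b c", "a c"])]
    base = [make_tweet(f"b{i}", t) for i, t in enumerate(["a", "c c d"])]
    single = count_candidate("a", gist, base, set())
    (batch,) = candidate_table(["a"], gist, base, set())
    assert (single.gist_tweets_with, single.baseline_tweets_with) == (2, 1)
    assert batch == single
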