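# Methods

`eventscan` detects localised events — illness-symptom outbreaks and
emotion spikes — in a stream of geo-tagged microblog messages, and
summarises each event with characteristic terms, linked news articles and
representative tweets.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic test bed does and
does not establish.

## Detection model

**Geography.** Tweet coordinates are clustered once with DBSCAN over
great-circle (haversine) distance; each cluster becomes a convex-hull
polygon and every later tweet is assigned to the hull containing it, or to
a reserved noise cluster that is excluded from analysis.  DBSCAN border
points are order-dependent by nature, so the implementation pins the scan
to input order and documents it; tests hold it to an independent quadratic
reference.  When hulls overlap, the smallest-area hull wins (the more
specific area).  Hull area is computed in a local equirectangular
projection about the hull centroid — adequate at city scale, increasingly
biased for hulls spanning many degrees of latitude.

**Counting and normalisation.** Tweets are matched to keyword groups (a
primary keyword plus aliases, matched as token phrases, never substrings)
and counted daily per (group, cluster).  Weekly rhythm is removed by
dividing each day's count by a trailing weekday factor

    f(w) = mean count on weekday w over the trailing 56 days
           / overall mean over the window,        floored at 0.1.

Days with fewer than 14 prior days keep f = 1 (below two full weeks there
are not two samples of every weekday).  The scheme is causal (no
look-ahead) and removes a stationary weekend uplift exactly once the
window covers whole weeks.  Detection and severity both run on the
normalised series by default (`use_normalised`).

**Aberration detection.** The C2 detector flags day *t* when

    count(t) − mean(baseline) > 3 · max(sd(baseline), 0.5)

with a 7-day baseline and the sample standard deviation; C3 flags a day
when at least 2 C2 flags fall in the trailing 3-day window.  Runs of
consecutive flagged days for one (group, cluster) form an **alarm**.

The pipeline default places a 2-day guard band between baseline and test
day (`c2_gap_days = 2`, as in the CDC formulation).  Without the gap a
multi-day burst masks itself: its first day enters the next day's baseline,
inflating both mean and standard deviation so the alarm truncates to a
single day — which also starves the summariser of gist tweets.  The
`c2_flags` primitive itself defaults to a gapless baseline; callers choose.
A cumulative C3 variant (`c3_mode="cdc"`, summing positive standardised
excesses over 3 days) is available but lightly exercised.

**Severity and spam filters.** Sparse count series are zero-skewed, so
alarm strength uses a robust statistic rather than z-scores:

    mu = (observation − median(history)) / max(MAD(history), 1)

where the history is every count strictly before the day (from the start
of the series) and MAD is the median absolute deviation.  An alarm's
`mu_max` is the largest daily mu.  The MAD floor of 1 keeps mu defined on
the many all-zero baselines; it also means mu is scale-invariant only
while the MAD sits above the floor.  An alarm is promoted to an **event**
when `mu_max >= 4` (at-or-above) and its tweet-user ratio (tweets per
distinct author) is at most 1.5; a failing ratio labels the alarm spam
regardless of mu.  Threshold-sweep analysis over the packaged 33-event
evaluation table reproduces the operating points behind those defaults:
F1 peaks at threshold 4 (0.939 on the packaged table) and precision
reaches 1 at threshold 6.

## Summarisation model

**Terms.** The *gist* (tweets matching the event's group and cluster
during the event period, at least 30 of them) is contrasted with a
*baseline* (same filter, the 28 days before the start).  Stopwords are the
standard English list plus the 200 most frequent tokens of the full
stream; candidate unigrams/bigrams must appear in at least 5 % of gist
tweets (presence counted once per tweet; bigrams join tokens adjacent
after stopword removal, so "air pollution" survives an intervening
"the").  A one-sided Fisher's exact test (α = 0.05, no multiple-testing
correction — the procedure wants candidate terms, not confirmatory
p-values) keeps gist-enriched n-grams; the two most significant unigrams
and two bigrams, plus the triggering primary keyword, become the search
terms.

**News.** Each term queries a local news corpus (ranked TF-IDF cosine
against title+body, title tokens counted double, positive scores only,
dates in [start, end + 1 day], top 10).  A term's set is *coherent* when
the PCSS of its body vectors — mean pairwise cosine minus the population
standard deviation of those cosines — is at least −0.08; body vectors are
stopword-free, Porter-stemmed unigrams weighted tf·ln(N/df) with the
retrieved set itself as the IDF corpus (terms in every document vanish).
Coherent terms must additionally be *related* to at least one other
coherent term: the cross-set PCSS of unstemmed uni/bi/trigram title
vectors (IDF over the union of the two title sets) must reach −0.08.  A
lone coherent term is not good — that is what drops the off-topic
"coherent but unrelated" story.  Articles of good terms are ranked by
cosine to their set's mean vector, merged with per-id deduplication.  The
relatedness threshold reuses the coherence value; both are configurable.

**Tweets.** The *Gist Top Tweets* rank every gist tweet by cosine to the
set's mean TF-IDF vector (unstemmed unigrams, ties by timestamp then id).
The *Summary Top Tweets* rank the gist tweets containing a good term,
falling back to the extracted terms when no term survived the news checks,
and absent when nothing was significant; a preferred set that matches no
tweet falls through to the next option.  Term containment uses
stopword-free token phrases, the same matcher as extraction.

**Stemming.** The body vectors use a Porter stemmer implemented in the
package (`eventscan.stemming`); any `str -> str` callable can be
substituted via the `stemmer` arguments.

**Noise filter.** An optional pre-processing hook removes tweets that
mention a symptom without reporting illness.  The shipped trainer is a
supervised logistic-regression bag of words over the package tokeniser;
the model is a transparent (vocabulary, weights, bias, threshold) record
serialisable to JSON, so any externally trained linear model or predicate
can be dropped in.  No claim is made about accuracy on real data — that
depends entirely on the labelled corpus supplied.

## Synthetic test bed

`synthetic_data` generates seeded worlds for every stage: per (city,
group, day) counts are Poisson with rate λ · weekday multiplier, scaled by
a burst multiplier when an injected event covers the cell; coordinates are
city-centred Gaussians with a scattered remainder; burst-cell tweets carry
one planted vocabulary term with probability 0.8; spam users repeat from a
fixed id set; a matched news corpus holds planted event articles among
daily topical distractors.  The canonical scenario (used by the recovery
suites and the acceptance script) is: two cities 250 km apart (spread
5 km, 85 % of tweets in-cluster), three keyword groups, λ = 5, weekday
multipliers 0.9–1.3, 70 days, one 2-day 6× burst with token-disjoint
planted vocabulary and 8 matched articles, one single-user 40-tweet/day
spam burst, five distractor topics and one cross-topic decoy term.

Deliberate design points, chosen to reproduce full-scale statistical
conditions at small n:

- **Two-tier filler vocabulary.** Tweet filler mixes a head of 210
  near-uniformly frequent pseudo-words with a long rare tail.  A single
  Zipf curve at desk scale would push planted event terms into the top-200
  most frequent tokens — impossible at realistic corpus scale — and the
  stopword builder would eat them.
- **Token-disjoint planted terms.** A token shared by two planted terms
  becomes near-universal in the event's articles and vanishes under
  ln(N/df) weighting, hollowing out the coherence signal.
- **Decoy structure.** Each day one rotating topic publishes a same-day
  pair of decoy-bearing articles, so a decoy search over an alarm window
  retrieves same-topic pairs from several topics: pockets of high
  similarity in an otherwise unrelated set, exactly the structure PCSS
  penalises.  Decoy rejection therefore happens at the coherence step, the
  robust lever; the relatedness step catches coherent-but-unrelated
  stories.

What the generator does **not** emulate: real language (texts are
vocabulary scaffolding), retweets, user-level activity patterns, spatial
drift, seasonal trends, or news bodies longer than a few dozen tokens.
Passing recovery suites therefore demonstrate the pipeline's mechanics —
counting, detection, filtering, term statistics, vector geometry — not
performance on real social-media data.

## Problem sizes and determinism

The recovery study runs 100 seeded worlds of ~2,300 tweets and ~220
articles each (about a minute in total); the threshold sweep over the
packaged 33-event table is instantaneous.  All randomness flows from
explicit seeds through `numpy.random.default_rng`; per-world seeds are
derived from the study's base seed.  Ties everywhere break
deterministically (lexicographic, timestamp-then-id, or input order, as
documented per operation).

## Known limitations

- DBSCAN is exact but quadratic-ish in dense neighbourhoods; for
  multi-million-point streams, cluster on a sample (the cluster model then
  assigns the rest in vectorised batches).
- The weekday factors assume a stable weekly rhythm; regime changes decay
  only as the 56-day window rolls past.
- mu compares a day against the whole prior series; long series with
  slow drift will understate severity relative to a windowed median.
- The event-id scheme (two keyword letters + 1–2 area letters + day-month)
  disambiguates collisions with longer area codes and numeric suffixes,
  so ids are stable only within one detection run.
- PCSS with the mean-minus-std form rewards uniformly similar sets; two
  sets with all-zero cross cosines score 0, i.e. *pass* a −0.08
  relatedness threshold.  Rejection of unrelated sets in practice relies
  on occasional strong similarity spikes (shared rare words) raising the
  standard deviation — true of real titles and of the synthetic corpus by
  construction.
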