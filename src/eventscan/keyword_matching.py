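"""Tokenisation, keyword-group matching, and the health-report noise filter.

Matching is phrase matching on token sequences (a multi-word alias such as
``sore throat`` must appear as consecutive tokens), never raw substring
matching — this avoids false hits like "flute" matching "flu".

The noise filter removes tweets that mention a symptom without being a
self-report of illness (song lyrics, news discussion, metaphor).  It is a
plain supervised linear bag-of-words classifier behind a small serialisable
model type; any predicate with the same surface can be dropped in.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .models import KeywordGroup, Tweet

logger = logging.getLogger(__name__)

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
# word runs, optionally joined by intra-word apostrophes (ASCII or curly)
_TOKEN_RE = re.compile(r"[^\W_]+(?:['’][^\W_]+)*", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase tokens with URLs and @mentions removed.

    The ``#`` of a hashtag is stripped but the tag word itself is kept (event
    vocabulary often arrives as hashtags).  Punctuation is stripped except
    intra-word apostrophes, so "can't" survives as one token.
    """
    text = text.lower()
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    text = text.replace("#", " ")
    return _TOKEN_RE.findall(text)


class KeywordMatcher:
    """Pre-compiled phrase matcher over a collection of keyword groups."""

    def __init__(self, groups: Iterable[KeywordGroup]):
        self.groups = list(groups)
        # first token -> list of (full phrase tuple, group primary keyword)
        self._index: dict[str, list[tuple[tuple[str, ...], str]]] = {}
        self._max_len = 1
        for g in self.groups:
            for term in g.terms:
                phrase = tuple(tokenize(term))
                if not phrase:
                    continue
                self._max_len = max(self._max_len, len(phrase))
                self._index.setdefault(phrase[0], []).append((phrase, g.primary_keyword))

    def match_tokens(self, tokens: Sequence[str]) -> set[str]:
        matched: set[str] = set()
        for i, tok in enumerate(tokens):
            for phrase, gid in self._index.get(tok, ()):
                if gid in matched:
                    continue
                if tuple(tokens[i : i + len(phrase)]) == phrase:
                    matched.add(gid)
        return matched

    def match_text(self, text: str) -> set[str]:
        return self.match_tokens(tokenize(text))


def match_groups(tweet: Tweet | str, groups: Iterable[KeywordGroup]) -> set[str]:
    """Identifiers of groups whose primary keyword or any alias occurs in the text.

    A tweet matching several aliases of one group yields that group once; it
    may match several distinct groups.
    """
    text = tweet.text if isinstance(tweet, Tweet) else tweet
    return KeywordMatcher(groups).match_text(text)


@dataclass
class NoiseFilterModel:
    """Linear bag-of-words scorer: keep a tweet when score(text) >= threshold."""

    vocabulary: dict[str, int]
    weights: np.ndarray
    bias: float
    threshold: float = 0.0
    holdout_accuracy: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != len(self.vocabulary):
            raise ValueError("weights must align with vocabulary")

    def score(self, text: str) -> float:
        s = self.bias
        for tok in tokenize(text):
            idx = self.vocabulary.get(tok)
            if idx is not None:
                s += self.weights[idx]
        return s

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "vocabulary": self.vocabulary,
                    "weights": self.weights.tolist(),
                    "bias": self.bias,
                    "threshold": self.threshold,
                    "holdout_accuracy": self.holdout_accuracy,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "NoiseFilterModel":
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            vocabulary=obj["vocabulary"],
            weights=np.asarray(obj["weights"], dtype=float),
            bias=obj["bias"],
            threshold=obj.get("threshold", 0.0),
            holdout_accuracy=obj.get("holdout_accuracy"),
        )


def train_noise_filter(
    labelled: Sequence[tuple[str, str]],
    seed: int = 0,
    holdout_fraction: float = 0.25,
) -> NoiseFilterModel:
    """Fit a regularised linear classifier on (text, label) pairs.

    Labels are ``report`` (a self-report of illness, positive class) and
    ``not_report``.  Training is deterministic given the seed; held-out
    accuracy is logged and stored on the model.
    """
    from sklearn.feature_extraction.text import CountVectorizer
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    labels = {lab for _, lab in labelled}
    bad = labels - {"report", "not_report"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    if labels != {"report", "not_report"}:
        raise ValueError("need at least one example of each label")
    texts = [t for t, _ in labelled]
    y = np.array([1 if lab == "report" else 0 for _, lab in labelled])
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("need at least two examples of each label")

    x_train, x_test, y_train, y_test = train_test_split(
        texts, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    vectoriser = CountVectorizer(analyzer=tokenize)
    clf = LogisticRegression(max_iter=1000, random_state=seed)
    xt = vectoriser.fit_transform(x_train)
    clf.fit(xt, y_train)
    accuracy = float(clf.score(vectoriser.transform(x_test), y_test))
    logger.info("noise filter held-out accuracy: %.3f", accuracy)

    vocab = {tok: int(i) for tok, i in vectoriser.vocabulary_.items()}
    return NoiseFilterModel(
        vocabulary=vocab,
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        threshold=0.0,
        holdout_accuracy=accuracy,
    )


def apply_noise_filter(
    tweets: Sequence[Tweet], model: NoiseFilterModel | None
) -> list[Tweet]:
    """Keep tweets scoring at or above the model threshold; identity when model is None."""
    if model is None:
        return list(tweets)
    return [t for t in tweets if model.score(t.text) >= model.threshold]
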