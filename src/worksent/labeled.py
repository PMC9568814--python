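"""Labeled-subset analysis: per-class top-word frequency tables and conjugate
(adjacent) word extraction for reading frequent words in context.

Adjacency is computed on the cleaned token stream by default, so "previous or
next word" means the nearest surviving content token; a raw-adjacency mode is
available for auditing against unprocessed text.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from ._rounding import round_half_up
from .corpus_io import LabeledTweet
from .keywords import tweet_tokens
from .preprocessing import CleaningConfig, preprocess_tweet


@dataclass
class WordFrequencyTable:
    """Top-n words of one class: rows of (word, count, percent), counts descending.

    Percent is taken against the sum of the table's own counts, one decimal.
    """

    label: str
    rows: list[tuple[str, int, float]]

    @property
    def n(self) -> int:
        return len(self.rows)


@dataclass
class ConjugateIndex:
    """target word -> Counter of adjacent words across all occurrences."""

    neighbors: dict[str, Counter]

    def __getitem__(self, target: str) -> Counter:
        return self.neighbors[target]


def _class_token_streams(
    labeled: Sequence[LabeledTweet],
    label: str | None,
    config: CleaningConfig,
    cleaned: bool = True,
) -> list[list[str]]:
    streams = []
    for lt in labeled:
        if label is not None and lt.label != label:
            continue
        if cleaned:
            streams.append(list(preprocess_tweet(lt.tweet, config).tokens))
        else:
            streams.append(tweet_tokens(lt.tweet.text))
    return streams


def top_frequent_words(
    labeled: Sequence[LabeledTweet],
    label: str,
    n: int = 10,
    config: CleaningConfig | None = None,
) -> WordFrequencyTable:
    """The n most frequent cleaned tokens of a class; ties break lexicographically."""
    config = config or CleaningConfig()
    counter: Counter[str] = Counter()
    for stream in _class_token_streams(labeled, label, config):
        counter.update(stream)
    ranked = sorted(counter, key=lambda w: (-counter[w], w))[: max(n, 0)]
    total = sum(counter[w] for w in ranked)
    rows = [
        (w, counter[w], round_half_up(100.0 * counter[w] / total, 1) if total else 0.0)
        for w in ranked
    ]
    return WordFrequencyTable(label, rows)


def conjugate_words(
    labeled: Sequence[LabeledTweet],
    targets: Sequence[str],
    window: int = 1,
    label: str | None = None,
    config: CleaningConfig | None = None,
    cleaned: bool = True,
) -> ConjugateIndex:
    """For each target, the multiset of tokens within ``window`` positions of any
    occurrence, across all (optionally class-filtered) tweets. Tokens equal to
    the target itself are excluded; an absent target yields an empty entry."""
    if not targets:
        raise ValueError("targets must be non-empty")
    config = config or CleaningConfig()
    index: dict[str, Counter] = {t: Counter() for t in targets}
    streams = _class_token_streams(labeled, label, config, cleaned=cleaned)
    for stream in streams:
        for i, tok in enumerate(stream):
            if tok not in index:
                continue
            lo, hi = max(0, i - window), min(len(stream), i + window + 1)
            for j in range(lo, hi):
                if j != i and stream[j] != tok:
                    index[tok][stream[j]] += 1
    return ConjugateIndex(index)


def class_proportions(labeled: Sequence[LabeledTweet]) -> dict[str, int]:
    """Integer percentage of tweets per polarity class (half-up rounding)."""
    if not labeled:
        raise ValueError("labeled subset is empty")
    tally = Counter(lt.label for lt in labeled)
    total = len(labeled)
    return {
        label: round_half_up(100.0 * tally.get(label, 0) / total)
        for label in ("positive", "negative", "neutral")
    }
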