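"""Topic polarity by opinion-lexicon voting.

Each topic's word list is scored word by word: a word found in the positive
opinion lexicon or among the top words of positively labeled tweets increments
the positive count; likewise for negative; a word in none of the four sets
counts as neutral. The topic's label is the strict-majority class, with ties
falling back to Neutral. A word sitting in both a positive and a negative
vocabulary (possible across the lexicon / labeled-word sets) increments both
counters; membership within one polarity is a union, never a double count.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._rounding import round_half_up
from .corpus_io import LabeledTweet
from .lexicon import OpinionLexicon, opinion_lexicon
from .preprocessing import CleaningConfig, preprocess_tweet

logger = logging.getLogger(__name__)

LABELS = ("Positive", "Negative", "Neutral")


@dataclass(frozen=True)
class TopicPolarityCounts:
    positive: int
    negative: int
    neutral: int


@dataclass
class TopicPolarityResult:
    """Per-topic polarity labels and the word-vote counts behind them."""

    labels: dict[int, str]
    counts: dict[int, TopicPolarityCounts]

    @property
    def n_topics(self) -> int:
        return len(self.labels)


def class_top_words(
    labeled: Sequence[LabeledTweet],
    label: str,
    n: int = 50,
    config: CleaningConfig | None = None,
) -> frozenset[str]:
    """The n most frequent cleaned tokens of the given class; ties lexicographic."""
    config = config or CleaningConfig()
    counter: Counter[str] = Counter()
    for lt in labeled:
        if lt.label == label:
            counter.update(preprocess_tweet(lt.tweet, config).tokens)
    if not counter:
        logger.warning("class_top_words: no tokens for class %r", label)
        return frozenset()
    ranked = sorted(counter, key=lambda w: (-counter[w], w))
    return frozenset(ranked[:n])


def assign_topic_polarity(
    topic_words: Sequence[str],
    lexicon: OpinionLexicon | None = None,
    pos_words: Iterable[str] = (),
    neg_words: Iterable[str] = (),
) -> tuple[str, TopicPolarityCounts]:
    """Label one topic by counting its words against the opinion vocabularies."""
    lexicon = lexicon or opinion_lexicon()
    positive_vocab = set(lexicon.positive) | set(pos_words)
    negative_vocab = set(lexicon.negative) | set(neg_words)
    if not topic_words:
        logger.warning("assign_topic_polarity: empty topic word list")
        return "Neutral", TopicPolarityCounts(0, 0, 0)
    pos = neg = neu = 0
    for word in topic_words:
        in_pos = word in positive_vocab
        in_neg = word in negative_vocab
        if in_pos:
            pos += 1
        if in_neg:
            neg += 1
        if not in_pos and not in_neg:
            neu += 1
    if pos > neg and pos > neu:
        label = "Positive"
    elif neg > pos and neg > neu:
        label = "Negative"
    elif neu > pos and neu > neg:
        label = "Neutral"
    else:
        label = "Neutral"  # no strict majority
    return label, TopicPolarityCounts(pos, neg, neu)


def assign_all_topics(
    topic_word_lists: Mapping[int, Sequence[str]],
    lexicon: OpinionLexicon | None = None,
    pos_words: Iterable[str] = (),
    neg_words: Iterable[str] = (),
) -> TopicPolarityResult:
    labels: dict[int, str] = {}
    counts: dict[int, TopicPolarityCounts] = {}
    for topic_id, words in topic_word_lists.items():
        labels[topic_id], counts[topic_id] = assign_topic_polarity(
            words, lexicon, pos_words, neg_words
        )
    return TopicPolarityResult(labels, counts)


def polarity_proportions(result: TopicPolarityResult) -> dict[str, int]:
    """Percentage of topics per label, rounded to the nearest integer."""
    if result.n_topics == 0:
        raise ValueError("no topics")
    tally = Counter(result.labels.values())
    return {
        label: round_half_up(100.0 * tally.get(label, 0) / result.n_topics)
        for label in LABELS
    }
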