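"""Lexicon-and-rule compound sentiment scoring with threshold binning.

The scorer aggregates word valences from the packaged lexicon and applies
surface-form rules that only the raw (uncleaned) text carries: negation within
a three-token window flips and damps a valence, degree adverbs boost or damp
it with distance decay, all-caps emphasis strengthens it (unless the whole
text shouts), and trailing exclamation marks amplify the total. The sum is
squashed to a compound in [-1, +1] with the alpha-normalization
s / sqrt(s^2 + 15). Polarity uses the +-0.05 band (inclusive: |c| <= 0.05 is
neutral) and intensity uses nine fixed bins whose interior edges belong to the
right (higher) bin.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rounding import round_half_up
from .corpus_io import RawTweet
from .lexicon import valence_lexicon

_ALPHA = 15.0
_CAPS_BOOST = 0.733
_EXCL_UNIT = 0.292
_MAX_EXCL = 4
_NEGATION_DAMP = -0.74
_BOOST = 0.293
_DECAY = (1.0, 0.95, 0.9)  # booster strength at distance 1, 2, 3

_WORD_RE = re.compile(r"[A-Za-z][A-Za-z'’-]*")

NEGATORS = frozenset(
    """not no never none neither nor nothing nowhere without cannot can't don't won't
    isn't aren't wasn't weren't doesn't didn't couldn't shouldn't wouldn't mustn't
    hasn't haven't hadn't ain't""".split()
)

BOOSTERS: dict[str, float] = {
    **{w: _BOOST for w in (
        "absolutely amazingly completely considerably deeply especially exceptionally "
        "extremely highly hugely incredibly really remarkably so totally tremendously "
        "utterly very"
    ).split()},
    **{w: -_BOOST for w in (
        "almost barely hardly less little marginally occasionally partly scarcely "
        "slightly somewhat"
    ).split()},
}

INTENSITY_EDGES = (-1.0, -0.75, -0.50, -0.25, -0.05, 0.05, 0.25, 0.50, 0.75, 1.0)
INTENSITY_LABELS = (
    "-1.0 to -0.75",
    "-0.75 to -0.50",
    "-0.50 to -0.25",
    "-0.25 to -0.05",
    "-0.05 to 0.05",
    "0.05 to 0.25",
    "0.25 to 0.50",
    "0.50 to 0.75",
    "0.75 to 1.0",
)


@dataclass(frozen=True)
class SentimentScore:
    """Per-tweet result: compound value, derived polarity, and intensity bin."""

    tweet_id: str
    compound: float
    polarity: str
    intensity_bin: str


def score_tweet(text: str) -> float:
    """Compound sentiment of a raw text; deterministic, in [-1, +1], 0 when empty."""
    tokens = _WORD_RE.findall(text)
    if not tokens:
        return 0.0
    lexicon = valence_lexicon()
    lowered = [t.lower() for t in tokens]
    has_case_mix = any(t.isupper() and len(t) > 1 for t in tokens) and not all(
        t.isupper() for t in tokens if len(t) > 1
    )

    total = 0.0
    for i, word in enumerate(lowered):
        valence = lexicon.get(word)
        if valence is None:
            continue
        sign = 1.0 if valence > 0 else -1.0
        if has_case_mix and tokens[i].isupper() and len(tokens[i]) > 1:
            valence += sign * _CAPS_BOOST
        negated = False
        for dist in (1, 2, 3):
            j = i - dist
            if j < 0:
                break
            prev = lowered[j]
            if prev in BOOSTERS:
                boost = BOOSTERS[prev] * _DECAY[dist - 1]
                if has_case_mix and tokens[j].isupper() and len(tokens[j]) > 1:
                    boost += math.copysign(_CAPS_BOOST / 3, boost)
                valence += sign * boost
            if prev in NEGATORS:
                negated = True
        if negated:
            valence *= _NEGATION_DAMP
        total += valence

    if total != 0.0:
        excl = min(text.count("!"), _MAX_EXCL)
        total += math.copysign(excl * _EXCL_UNIT, total)

    compound = total / math.sqrt(total * total + _ALPHA)
    return float(np.clip(round(compound, 4), -1.0, 1.0))


def classify_polarity(compound: float) -> str:
    """Three-way polarity from the compound via the +-0.05 neutral band."""
    if not -1.0 <= compound <= 1.0:
        raise ValueError(f"compound {compound} outside [-1, 1]")
    if compound > 0.05:
        return "positive"
    if compound < -0.05:
        return "negative"
    return "neutral"


def bin_intensity(compound: float) -> str:
    """Assign the compound to one of the nine intensity bins.

    Interior edges belong to the right (higher) bin; +1.0 stays in the last bin.
    """
    if not -1.0 <= compound <= 1.0:
        raise ValueError(f"compound {compound} outside [-1, 1]")
    idx = int(np.searchsorted(INTENSITY_EDGES, compound, side="right")) - 1
    idx = min(max(idx, 0), len(INTENSITY_LABELS) - 1)
    return INTENSITY_LABELS[idx]


def score_corpus(tweets: Sequence[RawTweet]) -> list[SentimentScore]:
    """Score raw tweets (the rule model needs the original surface form)."""
    out = []
    for tw in tweets:
        c = score_tweet(tw.text)
        out.append(SentimentScore(tw.tweet_id, c, classify_polarity(c), bin_intensity(c)))
    return out


@dataclass
class IntensityHistogram:
    """Counts and percentages of tweets per intensity bin."""

    counts: dict[str, int]
    percents: dict[str, float]
    total: int


def intensity_histogram(scores: Sequence[SentimentScore]) -> IntensityHistogram:
    if not scores:
        raise ValueError("no scores")
    counts = Counter(s.intensity_bin for s in scores)
    total = len(scores)
    return IntensityHistogram(
        counts={b: counts.get(b, 0) for b in INTENSITY_LABELS},
        percents={
            b: round_half_up(100.0 * counts.get(b, 0) / total, 2) for b in INTENSITY_LABELS
        },
        total=total,
    )


@dataclass(frozen=True)
class TermCounts:
    """Per-polarity counts of tweets mentioning a term, plus the overall share."""

    term: str
    positive: int
    negative: int
    neutral: int
    total_matched: int
    percent_of_corpus: float


def term_stratified_counts(
    tweets: Sequence[RawTweet], scores: Sequence[SentimentScore], term: str
) -> TermCounts:
    """Case-insensitive whole-word term match on raw text, stratified by polarity."""
    if not term:
        raise ValueError("term must be non-empty")
    pattern = re.compile(rf"\b{re.escape(term)}\b", re.IGNORECASE)
    by_id = {s.tweet_id: s.polarity for s in scores}
    tally = Counter()
    for tw in tweets:
        if pattern.search(tw.text):
            tally[by_id[tw.tweet_id]] += 1
    matched = sum(tally.values())
    return TermCounts(
        term=term,
        positive=tally.get("positive", 0),
        negative=tally.get("negative", 0),
        neutral=tally.get("neutral", 0),
        total_matched=matched,
        percent_of_corpus=round_half_up(100.0 * matched / len(tweets), 2) if tweets else 0.0,
    )
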