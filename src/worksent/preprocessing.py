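"""Staged cleaning chain turning raw tweet text into normalized token sequences.

The stage order is fixed and auditable: lowercase, contraction expansion, URL
removal, markup removal, mention removal, hashtag removal (the entire #token),
digit-bearing word removal, punctuation stripping, repeated-character collapse
(runs of 3+ to exactly 2), tokenization, stopword removal, search-keyword
elimination, meaningless/advertising word removal, single-character removal,
lemmatization, stemming. Advertisement tweets (whole-word "click"/"coupon"
hits) are dropped wholesale before token cleaning.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .corpus_io import RawTweet
from .lexicon import contraction_map, stopwords
from .stemming import lemmatize, porter_stem

MEANINGLESS_WORDS = frozenset({"thi", "wa", "rt", "ann"})
ADVERTISING_WORDS = frozenset({"click", "coupon"})

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)")
_MARKUP_RE = re.compile(r"<[^>]*>|&[a-z]+;|&#\d+;")
_MENTION_RE = re.compile(r"@\w+")
_HASHTAG_RE = re.compile(r"#\w+")
_DIGIT_WORD_RE = re.compile(r"(?<!\S)\S*\d\S*(?!\S)")
_PUNCT_RE = re.compile(r"[^\w\s]|_")
_REPEAT_RE = re.compile(r"(\w)\1{2,}")
_WORD_RE = re.compile(r"[a-z']+")


@dataclass(frozen=True)
class ProcessedTweet:
    """A cleaned tweet: id plus the ordered surviving token sequence."""

    tweet_id: str
    tokens: tuple[str, ...]


@dataclass(frozen=True)
class CleaningConfig:
    """Everything the cleaning chain needs: word lists, maps, and stage toggles.

    ``eliminated_keywords`` holds the individual tokens of the final search
    KeywordSet; they are removed at the surface stage and (when
    ``eliminate_stemmed`` is on) again after normalization via their stems, since
    a keyword may reach the normalization stage in an inflected form.
    """

    stopword_list: frozenset[str] = field(default_factory=stopwords)
    contractions: dict[str, str] = field(default_factory=contraction_map)
    eliminated_keywords: frozenset[str] = frozenset()
    meaningless_words: frozenset[str] = MEANINGLESS_WORDS
    advertising_words: frozenset[str] = ADVERTISING_WORDS
    eliminate_stemmed: bool = True
    expand_contractions_flag: bool = True
    remove_urls: bool = True
    remove_markup: bool = True
    remove_mentions: bool = True
    remove_hashtags: bool = True
    remove_digit_words: bool = True
    collapse_repeats: bool = True

    def with_keywords(self, keyword_tokens: Iterable[str]) -> "CleaningConfig":
        return replace(self, eliminated_keywords=frozenset(t.lower() for t in keyword_tokens))


@dataclass
class CleaningReport:
    """Per-stage removal accounting for a corpus cleaning run."""

    n_input: int = 0
    n_advertisements: int = 0
    n_output: int = 0
    n_empty: int = 0
    stage_removals: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_advertisements": self.n_advertisements,
            "n_output": self.n_output,
            "n_empty": self.n_empty,
            "stage_removals": dict(self.stage_removals),
        }


def is_advertisement(tweet: RawTweet, config: CleaningConfig | None = None) -> bool:
    """True iff any advertising word occurs as a whole word, case-insensitive."""
    config = config or CleaningConfig()
    tokens = _WORD_RE.findall(tweet.text.lower())
    return any(t in config.advertising_words for t in tokens)


def expand_contractions(text: str, mapping: dict[str, str] | None = None) -> str:
    """Replace every mapped contraction (whole-word) by its expansion."""
    mapping = mapping if mapping is not None else contraction_map()
    if not mapping:
        return text
    pattern = re.compile(
        r"\b(" + "|".join(re.escape(k) for k in sorted(mapping, key=len, reverse=True)) + r")\b"
    )
    return pattern.sub(lambda m: mapping[m.group(0)], text)


def _remove_counted(pattern: re.Pattern, text: str, stage: str, counts: Counter) -> str:
    text, n = pattern.subn(" ", text)
    counts[stage] += n
    return text


def preprocess_tweet(
    tweet: RawTweet, config: CleaningConfig | None = None, _counts: Counter | None = None
) -> ProcessedTweet:
    """Run the full cleaning chain on one tweet; may legitimately yield no tokens."""
    config = config or CleaningConfig()
    counts = _counts if _counts is not None else Counter()

    text = tweet.text.lower()
    if config.expand_contractions_flag:
        text = expand_contractions(text, config.contractions)
    if config.remove_urls:
        text = _remove_counted(_URL_RE, text, "url", counts)
    if config.remove_markup:
        text = _remove_counted(_MARKUP_RE, text, "markup", counts)
    if config.remove_mentions:
        text = _remove_counted(_MENTION_RE, text, "mention", counts)
    if config.remove_hashtags:
        text = _remove_counted(_HASHTAG_RE, text, "hashtag", counts)
    if config.remove_digit_words:
        text = _remove_counted(_DIGIT_WORD_RE, text, "digit_word", counts)
    text = _PUNCT_RE.sub(" ", text)
    if config.collapse_repeats:
        text = _REPEAT_RE.sub(r"\1\1", text)

    tokens = text.split()

    def _filter(pred, stage: str) -> None:
        nonlocal tokens
        kept = [t for t in tokens if not pred(t)]
        counts[stage] += len(tokens) - len(kept)
        tokens = kept

    _filter(lambda t: t in config.stopword_list, "stopword")
    _filter(lambda t: t in config.eliminated_keywords, "keyword")
    _filter(lambda t: t in config.meaningless_words or t in config.advertising_words,
            "meaningless_or_ad")
    _filter(lambda t: len(t) <= 1, "single_char")

    tokens = [porter_stem(lemmatize(t)) for t in tokens]

    if config.eliminate_stemmed and config.eliminated_keywords:
        stemmed_keywords = {porter_stem(lemmatize(k)) for k in config.eliminated_keywords}
        _filter(lambda t: t in stemmed_keywords, "keyword_stem")
    # normalization can shorten a token into a stopword/meaningless word; the
    # output contract forbids those, so re-apply the surface filters
    _filter(
        lambda t: t in config.stopword_list
        or t in config.meaningless_words
        or t in config.advertising_words
        or len(t) <= 1,
        "post_normalization",
    )

    return ProcessedTweet(tweet.tweet_id, tuple(tokens))


def preprocess_corpus(
    tweets: Sequence[RawTweet], config: CleaningConfig | None = None
) -> tuple[list[ProcessedTweet], CleaningReport]:
    """Clean a corpus: drop advertisement tweets, then token-clean the rest."""
    config = config or CleaningConfig()
    report = CleaningReport(n_input=len(tweets))
    out: list[ProcessedTweet] = []
    for tweet in tweets:
        if is_advertisement(tweet, config):
            report.n_advertisements += 1
            continue
        processed = preprocess_tweet(tweet, config, _counts=report.stage_removals)
        if not processed.tokens:
            report.n_empty += 1
        out.append(processed)
    report.n_output = len(out)
    return out, report
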