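"""Synthetic tweet-corpus generator with planted topics, planted polarity, and
platform noise, giving every pipeline stage a recoverable ground truth.

Each tweet draws a polarity class from the mixture, a topic (biased toward the
topic affiliated with its class by ``class_topic_coupling``), a Poisson length,
and tokens from a blend of the topic's word distribution and the class's
opinion-lexicon signature words. Noise transforms then add what the cleaner is
contracted to strip — URLs, mentions, hashtags, contractions, meaningless and
advertising words — plus character-level corruption (letter stretching,
misspelling) applied only to non-lexicon content tokens so the planted
polarity class is never altered.

Content vocabularies are pseudo-words sampled from syllables and screened
against the valence lexicon, stopword list, and meaningless/advertising lists;
their stems are unique, so planted topics stay disjoint after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .corpus_io import LabeledTweet, RawTweet
from .lexicon import opinion_lexicon, stopwords, valence_lexicon
from .preprocessing import ADVERTISING_WORDS, MEANINGLESS_WORDS
from .stemming import lemmatize, porter_stem

CLASSES = ("positive", "negative", "neutral")

_SAFE_CONTRACTIONS = (
    "i'm", "it's", "we're", "they're", "you're", "i've", "we've", "i'll", "we'll", "that's"
)

_CONSONANTS = list("bcdfgjklmnpqrstvz")
_VOWELS = list("aeiou")


@dataclass(frozen=True)
class NoiseRates:
    """Per-tweet probabilities of each noise transform."""

    url: float = 0.15
    mention: float = 0.15
    hashtag: float = 0.15
    contraction: float = 0.15
    advertisement: float = 0.03
    meaningless: float = 0.10
    repeated_char: float = 0.08
    misspelling: float = 0.08


@dataclass
class SyntheticCorpusSpec:
    """Generative parameters; the defaults define the study conditions.

    ``topics`` maps each planted topic to a word distribution; topic i is
    affiliated with class i mod 3 (positive, negative, neutral) and a tweet's
    topic is its class's affiliate with probability ``class_topic_coupling``,
    otherwise uniform.
    """

    topics: tuple[dict[str, float], ...]
    signature_words: dict[str, tuple[str, ...]]
    n_tweets: int = 2000
    class_mixture: tuple[float, float, float] = (0.4, 0.4, 0.2)
    injection_rates: dict[str, float] = field(
        default_factory=lambda: {"positive": 0.4, "negative": 0.4, "neutral": 0.0}
    )
    class_topic_coupling: float = 0.9
    noise: NoiseRates = field(default_factory=NoiseRates)
    length_mean: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_mean <= 0:
            raise ValueError("length_mean must be positive")
        if not self.topics:
            raise ValueError("at least one topic required")
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class mixture must sum to 1")
        for rate in self.injection_rates.values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError("injection rates must lie in [0, 1]")


@dataclass(frozen=True)
class TweetTruth:
    tweet_id: str
    topic_id: int
    polarity: str
    is_advertisement: bool
    noise: tuple[str, ...]


@dataclass
class GroundTruth:
    records: list[TweetTruth]

    def by_id(self) -> dict[str, TweetTruth]:
        return {r.tweet_id: r for r in self.records}


def _forbidden_words() -> set[str]:
    lex = set(valence_lexicon())
    return lex | set(stopwords()) | set(MEANINGLESS_WORDS) | set(ADVERTISING_WORDS)


def make_content_vocabulary(rng: np.random.Generator, n_words: int) -> list[str]:
    """Pseudo-words with unique stems, disjoint from every packaged word list."""
    forbidden = _forbidden_words()
    seen_stems: set[str] = set()
    words: list[str] = []
    while len(words) < n_words:
        n_syll = int(rng.integers(2, 4))
        word = "".join(
            rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syll)
        )
        if word in forbidden or len(word) < 4:
            continue
        stem = porter_stem(lemmatize(word))
        if stem in seen_stems or stem in forbidden or len(stem) < 2:
            continue
        seen_stems.add(stem)
        words.append(word)
    return words


def disjoint_topics(
    k: int, words_per_topic: int = 30, seed: int = 0
) -> tuple[dict[str, float], ...]:
    """K topics with disjoint pseudo-word supports and Zipf-shaped weights."""
    rng = np.random.default_rng(seed)
    vocab = make_content_vocabulary(rng, k * words_per_topic)
    weights = 1.0 / np.arange(1, words_per_topic + 1)
    weights /= weights.sum()
    return tuple(
        dict(zip(vocab[i * words_per_topic : (i + 1) * words_per_topic], weights))
        for i in range(k)
    )


def default_spec(
    seed: int = 0,
    n_tweets: int = 2000,
    k_true: int = 3,
    injection: float = 0.4,
    signature_size: int = 20,
    **overrides,
) -> SyntheticCorpusSpec:
    """The standard study conditions: disjoint planted topics, strong polarity
    injection for the non-neutral classes, mild platform noise."""
    rng = np.random.default_rng(seed)
    lexicon = opinion_lexicon()
    signature = {
        "positive": tuple(rng.choice(sorted(lexicon.positive), signature_size, replace=False)),
        "negative": tuple(rng.choice(sorted(lexicon.negative), signature_size, replace=False)),
        "neutral": (),
    }
    return SyntheticCorpusSpec(
        topics=disjoint_topics(k_true, seed=seed),
        signature_words=signature,
        n_tweets=n_tweets,
        injection_rates={"positive": injection, "negative": injection, "neutral": 0.0},
        seed=seed,
        **overrides,
    )


def _topic_of_class(spec: SyntheticCorpusSpec, cls_idx: int, rng: np.random.Generator) -> int:
    affiliated = [i for i in range(len(spec.topics)) if i % 3 == cls_idx]
    if affiliated and rng.random() < spec.class_topic_coupling:
        return int(rng.choice(affiliated))
    return int(rng.integers(len(spec.topics)))


def _misspell(word: str, rng: np.random.Generator) -> str:
    i = int(rng.integers(len(word)))
    letters = "abcdefghijklmnopqrstuvwxyz"
    repl = letters[int(rng.integers(26))]
    return word[:i] + repl + word[i + 1 :]


def _stretch(word: str, rng: np.random.Generator) -> str:
    i = int(rng.integers(len(word)))
    return word[:i] + word[i] * 4 + word[i + 1 :]


def generate_corpus(spec: SyntheticCorpusSpec) -> tuple[list[RawTweet], GroundTruth]:
    """Generate the corpus and its ground truth; byte-identical under one seed."""
    rng = np.random.default_rng(spec.seed)
    topic_words = [sorted(t) for t in spec.topics]
    topic_probs = [np.array([t[w] for w in ws]) for t, ws in zip(spec.topics, topic_words)]
    base_date = date(2018, 1, 1)
    date_span = (date(2021, 12, 31) - base_date).days

    tweets: list[RawTweet] = []
    records: list[TweetTruth] = []
    for n in range(spec.n_tweets):
        cls_idx = int(rng.choice(3, p=spec.class_mixture))
        cls = CLASSES[cls_idx]
        topic_id = _topic_of_class(spec, cls_idx, rng)
        length = max(3, int(rng.poisson(spec.length_mean)))
        inject = spec.injection_rates.get(cls, 0.0)
        signature = spec.signature_words.get(cls, ())

        tokens: list[str] = []
        content_positions: list[int] = []
        for _ in range(length):
            if signature and inject > 0 and rng.random() < inject:
                tokens.append(str(rng.choice(signature)))
            else:
                tw = topic_words[topic_id]
                tokens.append(tw[int(rng.choice(len(tw), p=topic_probs[topic_id]))])
                content_positions.append(len(tokens) - 1)

        noise_applied: list[str] = []
        nz = spec.noise

        if content_positions and rng.random() < nz.misspelling:
            pos = int(rng.choice(content_positions))
            tokens[pos] = _misspell(tokens[pos], rng)
            noise_applied.append("misspelling")
        if content_positions and rng.random() < nz.repeated_char:
            pos = int(rng.choice(content_positions))
            tokens[pos] = _stretch(tokens[pos], rng)
            noise_applied.append("repeated_char")
        if rng.random() < nz.contraction:
            ins = str(rng.choice(_SAFE_CONTRACTIONS))
            tokens.insert(int(rng.integers(len(tokens) + 1)), ins)
            noise_applied.append("contraction")
        if rng.random() < nz.meaningless:
            ins = str(rng.choice(sorted(MEANINGLESS_WORDS)))
            tokens.insert(int(rng.integers(len(tokens) + 1)), ins)
            noise_applied.append("meaningless")
        if rng.random() < nz.mention:
            tokens.insert(int(rng.integers(len(tokens) + 1)), f"@user{int(rng.integers(10000)):04d}")
            noise_applied.append("mention")
        if rng.random() < nz.hashtag:
            tag = topic_words[topic_id][int(rng.integers(len(topic_words[topic_id])))]
            tokens.insert(int(rng.integers(len(tokens) + 1)), f"#{tag}")
            noise_applied.append("hashtag")
        if rng.random() < nz.url:
            suffix = "".join(str(rng.choice(list("abcdefghij0123456789"))) for _ in range(6))
            tokens.append(f"https://t.co/{suffix}")
            noise_applied.append("url")
        is_ad = bool(rng.random() < nz.advertisement)
        if is_ad:
            ad_word = str(rng.choice(sorted(ADVERTISING_WORDS)))
            tokens.insert(int(rng.integers(len(tokens) + 1)), ad_word)
            noise_applied.append("advertisement")

        tweet_id = f"synth{n:06d}"
        created = base_date + timedelta(days=int(rng.integers(date_span + 1)))
        tweets.append(RawTweet(tweet_id, created, " ".join(tokens)))
        records.append(TweetTruth(tweet_id, topic_id, cls, is_ad, tuple(noise_applied)))
    return tweets, GroundTruth(records)


def generate_labeled_subset(
    corpus: list[RawTweet], truth: GroundTruth, m: int, seed: int = 0
) -> list[LabeledTweet]:
    """Uniform sample without replacement with labels copied from ground truth."""
    if m > len(corpus):
        raise ValueError(f"m={m} exceeds corpus size {len(corpus)}")
    rng = np.random.default_rng(seed)
    by_id = truth.by_id()
    idx = rng.choice(len(corpus), size=m, replace=False)
    return [LabeledTweet(corpus[i], by_id[corpus[i].tweet_id].polarity) for i in sorted(idx)]


def stemmed_topic_distributions(spec: SyntheticCorpusSpec) -> tuple[dict[str, float], ...]:
    """Planted topics mapped through the normalization the cleaner applies."""
    out = []
    for topic in spec.topics:
        merged: dict[str, float] = {}
        for word, p in topic.items():
            stem = porter_stem(lemmatize(word))
            merged[stem] = merged.get(stem, 0.0) + p
        out.append(merged)
    return tuple(out)
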