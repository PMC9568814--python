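"""Search-keyword formulation: category cross-product, embedding-neighbor synonym
expansion, seed-tweet matching, and binary particle-swarm refinement.

A seed keyword is an ordered token sequence with order-insensitive match
semantics: a tweet matches when every keyword token occurs in it as a whole
word (hashtags count with '#' stripped), in any order and multiplicity. The
swarm refines a candidate pool against a fitness that rewards retrieving
tweets whose embedding centroid lies close to the seed-tweet centroid while
penalizing pool bloat.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .corpus_io import RawTweet, WordVectorTable

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[\w']+")

PROVENANCES = ("panel", "synonym", "seed", "optimized")


@dataclass(frozen=True)
class SeedKeyword:
    """An ordered sequence of lowercase tokens; equality is on the token multiset."""

    words: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.words or any(not w for w in self.words):
            raise ValueError("keyword tokens must be non-empty")

    @classmethod
    def from_phrase(cls, phrase: str) -> "SeedKeyword":
        return cls(tuple(phrase.lower().split()))

    @property
    def multiset_key(self) -> tuple[str, ...]:
        return tuple(sorted(self.words))

    def __str__(self) -> str:
        return " ".join(self.words)


class KeywordSet:
    """A deduplicated set of seed keywords with per-keyword provenance.

    Deduplication is on the token multiset; the first-inserted surface form and
    provenance win.
    """

    def __init__(self) -> None:
        self._by_key: dict[tuple[str, ...], SeedKeyword] = {}
        self._provenance: dict[tuple[str, ...], str] = {}

    def add(self, keyword: SeedKeyword | str, provenance: str = "panel") -> None:
        if provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        if isinstance(keyword, str):
            keyword = SeedKeyword.from_phrase(keyword)
        key = keyword.multiset_key
        if key not in self._by_key:
            self._by_key[key] = keyword
            self._provenance[key] = provenance

    def provenance_of(self, keyword: SeedKeyword) -> str:
        return self._provenance[keyword.multiset_key]

    def __iter__(self) -> Iterator[SeedKeyword]:
        return iter(self._by_key.values())

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, keyword: SeedKeyword) -> bool:
        return keyword.multiset_key in self._by_key

    def sorted_keywords(self) -> list[SeedKeyword]:
        return sorted(self._by_key.values(), key=lambda k: k.words)

    def all_tokens(self) -> frozenset[str]:
        return frozenset(t for kw in self for t in kw.words)

    def write(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for kw in self.sorted_keywords():
                fh.write(f"{kw}  # {self.provenance_of(kw)}\n")

    @classmethod
    def read(cls, path: str | Path) -> "KeywordSet":
        ks = cls()
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                phrase, _, prov = line.partition("#")
                ks.add(phrase.strip(), prov.strip() or "panel")
        return ks


def combine_categories(
    prefixes: Sequence[str], postfixes: Sequence[str], provenance: str = "seed"
) -> KeywordSet:
    """Cross-product composition: every "prefix postfix" pair, deduplicated."""
    ks = KeywordSet()
    if not prefixes or not postfixes:
        logger.warning("combine_categories: empty input category, returning empty set")
        return ks
    for pre in prefixes:
        for post in postfixes:
            ks.add(f"{pre.lower()} {post.lower()}", provenance)
    return ks


def expand_synonyms(
    words: Sequence[str], vectors: WordVectorTable, k: int = 5
) -> list[str]:
    """Each word plus its k nearest in-vocabulary neighbors by cosine similarity.

    Out-of-vocabulary words pass through unexpanded; cosine ties break
    lexicographically; the result is deduplicated preserving first occurrence.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    vocab = vectors.words
    index = {w: i for i, w in enumerate(vocab)}
    matrix = np.stack([vectors[w] for w in vocab])
    norms = np.linalg.norm(matrix, axis=1)
    out: list[str] = []
    seen: set[str] = set()

    def _emit(word: str) -> None:
        if word not in seen:
            seen.add(word)
            out.append(word)

    for word in words:
        word = word.lower()
        _emit(word)
        if k == 0 or word not in vectors:
            continue
        v = vectors[word]
        with np.errstate(invalid="ignore", divide="ignore"):
            sims = matrix @ v / (norms * np.linalg.norm(v))
        sims = np.nan_to_num(sims, nan=-np.inf)
        ranked = sorted(
            (w for i, w in enumerate(vocab) if w != word),
            key=lambda w: (-sims[index[w]], w),
        )
        for neighbor in ranked[:k]:
            _emit(neighbor)
    return out


def tweet_tokens(text: str) -> list[str]:
    """Lowercase whole-word tokens; '#' is not a word character, so hashtag
    bodies are matched with the '#' stripped."""
    return _TOKEN_RE.findall(text.lower())


def match_tweet(keyword: SeedKeyword, tweet: RawTweet) -> bool:
    """True iff every keyword token occurs in the tweet, any order, any count."""
    tokens = set(tweet_tokens(tweet.text))
    return all(w in tokens for w in keyword.words)


def tweet_embedding(text: str, vectors: WordVectorTable) -> np.ndarray | None:
    """Mean vector of the tweet's in-vocabulary tokens; None when none are."""
    vecs = [vectors[t] for t in tweet_tokens(text) if t in vectors]
    if not vecs:
        return None
    return np.mean(vecs, axis=0)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


@dataclass(frozen=True)
class SwarmParams:
    """Binary PSO settings: logistic velocity squashing gives per-bit one-probabilities."""

    n_particles: int = 20
    n_iterations: int = 50
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    velocity_clip: float = 6.0
    size_penalty: float = 0.1


class KeywordFitness:
    """Fitness of a candidate subset against seed tweets.

    fitness(S) = cos(centroid of tweets retrieved by S, centroid of seed tweets)
                 - size_penalty * |S| / |pool|.
    An empty subset, or one retrieving no embeddable tweet, scores -1.
    """

    def __init__(
        self,
        candidates: Sequence[SeedKeyword],
        seed_tweets: Sequence[RawTweet],
        vectors: WordVectorTable,
        size_penalty: float = 0.1,
    ):
        if not candidates:
            raise ValueError("candidate pool is empty")
        if not seed_tweets:
            raise ValueError("seed tweet set is empty")
        self.candidates = list(candidates)
        self.size_penalty = size_penalty
        embeddings = [tweet_embedding(t.text, vectors) for t in seed_tweets]
        self._embeddable = [i for i, e in enumerate(embeddings) if e is not None]
        if not self._embeddable:
            raise ValueError("no seed tweet has an in-vocabulary token")
        self._emb = np.stack([embeddings[i] for i in self._embeddable])
        self.seed_centroid = self._emb.mean(axis=0)
        # match matrix restricted to embeddable tweets: candidates x tweets
        self._match = np.array(
            [[match_tweet(kw, seed_tweets[i]) for i in self._embeddable] for kw in candidates],
            dtype=bool,
        )

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return -1.0
        retrieved = self._match[mask].any(axis=0)
        if not retrieved.any():
            return -1.0
        centroid = self._emb[retrieved].mean(axis=0)
        penalty = self.size_penalty * mask.sum() / len(self.candidates)
        return _cosine(centroid, self.seed_centroid) - penalty


def optimize_keywords(
    candidates: KeywordSet,
    seed_tweets: Sequence[RawTweet],
    vectors: WordVectorTable,
    swarm_params: SwarmParams | None = None,
    seed: int = 0,
) -> KeywordSet:
    """Refine the candidate pool with binary PSO; reproducible under ``seed``.

    One particle starts at the all-candidates subset, so the returned subset's
    fitness is never below the unrefined pool's. A single-candidate pool is
    returned unchanged.
    """
    params = swarm_params or SwarmParams()
    pool = candidates.sorted_keywords()
    if len(pool) == 0:
        raise ValueError("candidate pool is empty")
    if len(pool) == 1:
        out = KeywordSet()
        out.add(pool[0], "optimized")
        return out

    fitness = KeywordFitness(pool, seed_tweets, vectors, params.size_penalty)
    rng = np.random.default_rng(seed)
    n, p = len(pool), params.n_particles

    pos = rng.integers(0, 2, size=(p, n)).astype(float)
    pos[0] = 1.0  # elitist anchor: evaluate the full pool
    vel = rng.uniform(-1.0, 1.0, size=(p, n))
    fit = np.array([fitness(row) for row in pos])
    pbest, pbest_fit = pos.copy(), fit.copy()
    g = int(np.argmax(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

    for _ in range(params.n_iterations):
        r1 = rng.random((p, n))
        r2 = rng.random((p, n))
        vel = (
            params.inertia * vel
            + params.cognitive * r1 * (pbest - pos)
            + params.social * r2 * (gbest - pos)
        )
        np.clip(vel, -params.velocity_clip, params.velocity_clip, out=vel)
        prob = 1.0 / (1.0 + np.exp(-vel))
        pos = (rng.random((p, n)) < prob).astype(float)
        fit = np.array([fitness(row) for row in pos])
        improved = fit > pbest_fit
        pbest[improved] = pos[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:  # global best never worsens
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

    out = KeywordSet()
    for i, kw in enumerate(pool):
        if gbest[i] > 0.5:
            out.add(kw, "optimized")
    return out
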