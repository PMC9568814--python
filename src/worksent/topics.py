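"""Bag-of-words construction, LDA fitting across a topic-count range, coherence
curves, and overlap-aware selection of the optimal topic count.

The selection rule mirrors the published practice of taking the coherence
maximum but breaking near-ties by topic overlap: among all K whose coherence is
within a tolerance of the best, the K with the largest mean pairwise
Jensen-Shannon distance between topic-word distributions (least overlap) wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial.distance import jensenshannon
from sklearn.decomposition import LatentDirichletAllocation

from .coherence import cv_coherence
from .preprocessing import ProcessedTweet

logger = logging.getLogger(__name__)


@dataclass
class BowCorpus:
    """Id-term dictionary plus per-document sparse count vectors."""

    token2id: dict[str, int]
    vocab: list[str]
    matrix: csr_matrix  # n_docs x vocab_size
    doc_ids: list[str]

    @property
    def n_docs(self) -> int:
        return self.matrix.shape[0]

    def doc_token_sets(self) -> list[set[str]]:
        out = []
        for i in range(self.n_docs):
            row = self.matrix.getrow(i)
            out.append({self.vocab[j] for j in row.indices})
        return out


@dataclass
class TopicModel:
    """A fitted topic model: per-topic word distributions and per-doc topic mixtures."""

    k: int
    topic_word: np.ndarray  # k x vocab, rows sum to 1
    doc_topic: np.ndarray  # n_docs x k, rows sum to 1
    vocab: list[str]
    seed: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("K must be >= 2")
        if not np.allclose(self.topic_word.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("topic-word rows must sum to 1")


@dataclass
class CoherenceCurve:
    """Ordered (K, coherence) pairs for the scanned K-range."""

    points: list[tuple[int, float]]

    def ks(self) -> list[int]:
        return [k for k, _ in self.points]

    def scores(self) -> list[float]:
        return [s for _, s in self.points]


@dataclass
class TopicScan:
    curve: CoherenceCurve
    models: dict[int, TopicModel]


def build_bow(processed: Sequence[ProcessedTweet]) -> BowCorpus:
    """Build the id-term dictionary and count matrix; empty docs keep empty rows."""
    vocab = sorted({t for doc in processed for t in doc.tokens})
    if not vocab:
        raise ValueError("corpus has no tokens")
    token2id = {t: i for i, t in enumerate(vocab)}
    indptr, indices, data = [0], [], []
    for doc in processed:
        counts: dict[int, int] = {}
        for t in doc.tokens:
            j = token2id[t]
            counts[j] = counts.get(j, 0) + 1
        for j in sorted(counts):
            indices.append(j)
            data.append(counts[j])
        indptr.append(len(indices))
    matrix = csr_matrix(
        (np.array(data), np.array(indices), np.array(indptr)),
        shape=(len(processed), len(vocab)),
        dtype=np.int64,
    )
    return BowCorpus(token2id, vocab, matrix, [d.tweet_id for d in processed])


def fit_topic_model(
    bow: BowCorpus, k: int, seed: int = 0, max_iter: int = 25, n_restarts: int = 3
) -> TopicModel:
    """Fit a K-topic LDA model by batch variational inference.

    Variational LDA is sensitive to initialization, so the fit is restarted
    ``n_restarts`` times from seeds derived deterministically from ``seed`` and
    the model with the highest variational bound is kept.
    """
    best: tuple[float, LatentDirichletAllocation, np.ndarray] | None = None
    for restart in range(max(n_restarts, 1)):
        lda = LatentDirichletAllocation(
            n_components=k,
            random_state=seed + 7919 * restart,
            learning_method="batch",
            max_iter=max_iter,
        )
        doc_topic = lda.fit_transform(bow.matrix)
        bound = lda.score(bow.matrix)
        if best is None or bound > best[0]:
            best = (bound, lda, doc_topic)
    _, lda, doc_topic = best
    topic_word = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicModel(k, topic_word, doc_topic, bow.vocab, seed)


def scan_topic_counts(
    bow: BowCorpus,
    k_min: int = 2,
    k_max: int = 31,
    seed: int = 0,
    coherence_top_n: int = 10,
    max_iter: int = 25,
) -> TopicScan:
    """Fit one model per K in [k_min, k_max] and record its coherence.

    A K exceeding the number of documents is skipped with a warning.
    """
    if k_min < 2 or k_max < k_min:
        raise ValueError("require 2 <= k_min <= k_max")
    doc_sets = bow.doc_token_sets()
    points: list[tuple[int, float]] = []
    models: dict[int, TopicModel] = {}
    for k in range(k_min, k_max + 1):
        if k > bow.n_docs:
            logger.warning("K=%d exceeds corpus size %d, skipping", k, bow.n_docs)
            continue
        model = fit_topic_model(bow, k, seed=seed, max_iter=max_iter)
        tops = [[w for w, _ in top_words(model, t, coherence_top_n)] for t in range(k)]
        score = cv_coherence(doc_sets, tops)
        points.append((k, score))
        models[k] = model
    return TopicScan(CoherenceCurve(points), models)


def topic_distance_matrix(model: TopicModel) -> np.ndarray:
    """Pairwise Jensen-Shannon distances (base 2) between topic word distributions."""
    k = model.k
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = float(jensenshannon(model.topic_word[i], model.topic_word[j], base=2))
            dist[i, j] = dist[j, i] = 0.0 if np.isnan(d) else d
    return dist


def mean_pairwise_distance(model: TopicModel) -> float:
    dist = topic_distance_matrix(model)
    k = model.k
    return float(dist[np.triu_indices(k, 1)].mean()) if k > 1 else 0.0


def select_optimal_k(
    curve: CoherenceCurve, models: dict[int, TopicModel], tolerance: float = 0.005
) -> int:
    """Among K within ``tolerance`` of the coherence maximum, pick the K whose
    model has the largest mean pairwise topic distance (least overlap); remaining
    ties go to the smallest K. Permutation-invariant in curve order."""
    if not curve.points:
        raise ValueError("empty coherence curve")
    best = max(s for _, s in curve.points)
    candidates = sorted(k for k, s in curve.points if s >= best - tolerance)
    if len(candidates) == 1:
        return candidates[0]
    return max(candidates, key=lambda k: (mean_pairwise_distance(models[k]), -k))


def top_words(model: TopicModel, topic_id: int, n: int = 30) -> list[tuple[str, float]]:
    """The n highest-weight words of a topic; ties break lexicographically."""
    if not 0 <= topic_id < model.k:
        raise ValueError(f"topic_id {topic_id} out of range")
    weights = model.topic_word[topic_id]
    order = sorted(range(len(model.vocab)), key=lambda j: (-weights[j], model.vocab[j]))
    return [(model.vocab[j], float(weights[j])) for j in order[:n]]
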