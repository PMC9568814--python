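"""Ground-truth recovery experiments on synthetic corpora.

These drive the whole pipeline against the generator's planted structure and
measure how much of it is recovered: the selected topic count versus the
planted one, Hungarian-matched topic cosines, lexicon-vote topic polarity
versus each topic's dominant planted class, and per-tweet scored polarity
versus the planted class. The particle-swarm benchmark pits the swarm against
exhaustive subset enumeration on a pool small enough to enumerate.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from datetime import date

import numpy as np
from scipy.optimize import linear_sum_assignment

from .corpus_io import RawTweet, WordVectorTable
from .keywords import KeywordFitness, KeywordSet, SwarmParams, optimize_keywords
from .lexicon import opinion_lexicon
from .preprocessing import preprocess_corpus
from .sentiment import score_corpus
from .synthetic import default_spec, generate_corpus, generate_labeled_subset, stemmed_topic_distributions
from .topic_polarity import assign_topic_polarity, class_top_words
from .topics import build_bow, scan_topic_counts, select_optimal_k, top_words


@dataclass(frozen=True)
class RecoveryResult:
    """Recovery metrics of one seeded end-to-end run."""

    seed: int
    n_tweets: int
    selected_k: int
    k_true: int
    matched_cosine: float
    topic_polarity_accuracy: float
    sentiment_agreement: float
    n_nonneutral: int


def matched_topic_cosine(model, planted_distributions, token2id) -> float:
    """Mean cosine between planted and fitted topics under the best one-to-one
    assignment (Hungarian matching on the negated cosine matrix)."""
    n_planted = len(planted_distributions)
    planted = np.zeros((n_planted, len(token2id)))
    for i, dist in enumerate(planted_distributions):
        for word, p in dist.items():
            if word in token2id:
                planted[i, token2id[word]] = p
    planted /= np.maximum(np.linalg.norm(planted, axis=1, keepdims=True), 1e-12)
    fitted = model.topic_word / np.linalg.norm(model.topic_word, axis=1, keepdims=True)
    cos = planted @ fitted.T
    rows, cols = linear_sum_assignment(-cos)
    return float(cos[rows, cols].mean())


def topic_recovery_run(
    seed: int,
    n_tweets: int = 2000,
    k_true: int = 3,
    injection: float = 0.4,
    k_min: int = 2,
    k_max: int = 6,
    n_labeled: int = 800,
    class_top_n: int = 50,
) -> RecoveryResult:
    """One seeded pipeline pass over a planted-structure corpus."""
    spec = default_spec(seed=seed, n_tweets=n_tweets, k_true=k_true, injection=injection)
    corpus, truth = generate_corpus(spec)
    by_id = truth.by_id()

    # per-tweet polarity agreement on planted non-neutral tweets
    scores = score_corpus(corpus)
    nonneutral = [s for s in scores if by_id[s.tweet_id].polarity != "neutral"]
    agreement = float(
        np.mean([s.polarity == by_id[s.tweet_id].polarity for s in nonneutral])
    )

    processed, _ = preprocess_corpus(corpus)
    nonempty = [p for p in processed if p.tokens]
    bow = build_bow(nonempty)
    scan = scan_topic_counts(bow, k_min, k_max, seed=seed)
    selected_k = select_optimal_k(scan.curve, scan.models)

    model = scan.models[k_true]
    cosine = matched_topic_cosine(model, stemmed_topic_distributions(spec), bow.token2id)

    labeled = generate_labeled_subset(corpus, truth, n_labeled, seed=seed)
    pos_words = class_top_words(labeled, "positive", class_top_n)
    neg_words = class_top_words(labeled, "negative", class_top_n)
    doc_topic = model.doc_topic.argmax(axis=1)
    lexicon = opinion_lexicon()
    correct = 0
    for t in range(model.k):
        words = [w for w, _ in top_words(model, t, 30)]
        label, _ = assign_topic_polarity(words, lexicon, pos_words, neg_words)
        members = [
            by_id[nonempty[i].tweet_id].polarity
            for i in range(len(nonempty))
            if doc_topic[i] == t
        ]
        if not members:
            continue
        dominant = Counter(members).most_common(1)[0][0]
        correct += label.lower() == dominant
    return RecoveryResult(
        seed=seed,
        n_tweets=n_tweets,
        selected_k=selected_k,
        k_true=k_true,
        matched_cosine=cosine,
        topic_polarity_accuracy=correct / model.k,
        sentiment_agreement=agreement,
        n_nonneutral=len(nonneutral),
    )


@dataclass(frozen=True)
class SwarmBenchmark:
    pso_fitness: float
    exhaustive_fitness: float
    n_irrelevant_excluded: int
    n_irrelevant: int
    kept: tuple[str, ...]


def planted_keyword_pool(seed: int = 7):
    """5 relevant + 5 irrelevant candidates over a two-cluster embedding space.

    Relevant keywords retrieve on-topic tweets (cluster along the first axis);
    irrelevant ones retrieve only off-topic tweets (second axis).
    """
    rng = np.random.default_rng(seed)
    d = 6
    rel = [f"rel{i}" for i in range(5)]
    irr = [f"irr{i}" for i in range(5)]
    filler = [f"fill{i}" for i in range(10)]

    def vec(axis: int) -> np.ndarray:
        v = np.zeros(d)
        v[axis] = 1.0
        return v + 0.05 * rng.normal(size=d)

    vectors = {t: vec(0) for t in rel + filler[:5]}
    vectors.update({t: vec(1) for t in irr + filler[5:]})
    table = WordVectorTable(vectors)

    tweets, n = [], 0
    for t in rel:
        for j in range(8):
            tweets.append(RawTweet(f"s{n}", date(2020, 1, 1), f"{t} {filler[j % 5]} chatter"))
            n += 1
    for t in irr:
        for j in range(2):
            tweets.append(RawTweet(f"s{n}", date(2020, 1, 1), f"{t} {filler[5 + j % 5]} chatter"))
            n += 1
    pool = KeywordSet()
    for t in rel + irr:
        pool.add(t, "seed")
    return pool, tweets, table


def exhaustive_best_subset(fitness: KeywordFitness) -> tuple[float, np.ndarray]:
    """Enumerate every subset of the pool; only feasible for small pools."""
    n = len(fitness.candidates)
    best_fit, best_mask = -np.inf, np.zeros(n, dtype=bool)
    for bits in itertools.product((0, 1), repeat=n):
        mask = np.array(bits, dtype=bool)
        f = fitness(mask)
        if f > best_fit:
            best_fit, best_mask = f, mask
    return float(best_fit), best_mask


def pso_benchmark(seed: int = 11, pool_seed: int = 7) -> SwarmBenchmark:
    """Swarm search versus exhaustive enumeration on the planted pool."""
    pool, tweets, table = planted_keyword_pool(pool_seed)
    params = SwarmParams(n_particles=20, n_iterations=50)
    refined = optimize_keywords(pool, tweets, table, params, seed=seed)
    cands = pool.sorted_keywords()
    fitness = KeywordFitness(cands, tweets, table, params.size_penalty)
    kept = {str(k) for k in refined}
    mask = np.array([str(c) in kept for c in cands])
    best_fit, _ = exhaustive_best_subset(fitness)
    n_irr = sum(1 for c in cands if str(c).startswith("irr"))
    excluded = sum(1 for c in cands if str(c).startswith("irr") and str(c) not in kept)
    return SwarmBenchmark(
        pso_fitness=float(fitness(mask)),
        exhaustive_fitness=best_fit,
        n_irrelevant_excluded=excluded,
        n_irrelevant=n_irr,
        kept=tuple(sorted(kept)),
    )
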