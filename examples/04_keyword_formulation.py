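"""Formulate search keywords: category cross-product, embedding synonym
expansion, and particle-swarm refinement against seed tweets."""

import worksent as ws
from worksent.experiments import exhaustive_best_subset, planted_keyword_pool
from worksent.keywords import KeywordFitness

# cross-product of the published two-by-two example
ks = ws.combine_categories(["workplace", "corporate"], ["stress", "good"])
print("seed keywords:", sorted(str(k) for k in ks))

# synonym expansion over the packaged panel nouns with a toy vector table
import numpy as np

vectors = ws.WordVectorTable({
    "work": np.array([1.0, 0.0]), "job": np.array([0.95, 0.05]),
    "office": np.array([0.9, 0.1]), "cat": np.array([0.0, 1.0]),
})
print("expanded:", ws.expand_synonyms(["work"], vectors, k=2))

# swarm refinement on a pool with 5 relevant + 5 planted-irrelevant keywords
pool, seed_tweets, table = planted_keyword_pool(seed=7)
refined = ws.optimize_keywords(pool, seed_tweets, table, seed=11)
kept = sorted(str(k) for k in refined)
print("swarm kept:", kept)

fitness = KeywordFitness(pool.sorted_keywords(), seed_tweets, table)
best, _ = exhaustive_best_subset(fitness)
mask = np.array([str(c) in kept for c in pool.sorted_keywords()])
print(f"swarm fitness {fitness(mask):.4f} vs exhaustive optimum {best:.4f}")

# The swarm should match the enumerated optimum on this 10-candidate pool and
# drop (nearly) all keywords that retrieve only off-topic tweets.
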