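"""Analyze a human-labeled subset: class proportions, per-class top-word
tables, and conjugate (adjacent) words for reading frequent words in context."""

import worksent as ws

spec = ws.default_spec(seed=42, n_tweets=2000)
corpus, truth = ws.generate_corpus(spec)
labeled = ws.generate_labeled_subset(corpus, truth, 600, seed=42)

print("class proportions (%):", ws.class_proportions(labeled))

table = ws.top_frequent_words(labeled, "negative", n=5)
print("\ntop negative-class words (word, count, % of table):")
for word, count, pct in table.rows:
    print(f"  {word:12s} {count:4d}  ({pct}%)")

targets = [w for w, _, _ in table.rows[:3]]
conj = ws.conjugate_words(labeled, targets, window=1, label="negative")
print("\nconjugate words of the top-3 targets:")
for t in targets:
    print(f"  {t}: {dict(conj[t].most_common(4))}")

# Class proportions should track the generator mixture; top negative words are
# the injected negative-lexicon signatures (stemmed), and their conjugates are
# the planted topic's content words that co-occur with them.
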