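"""Clean a corpus through the staged chain and score compound sentiment.

Cleaning and scoring are parallel tracks: topics are fit on cleaned tokens,
but the sentiment rules need the raw surface form (caps, punctuation).
"""

import worksent as ws

spec = ws.default_spec(seed=42, n_tweets=500)
corpus, truth = ws.generate_corpus(spec)

processed, report = ws.preprocess_corpus(corpus)
print(f"cleaned {report.n_output}/{report.n_input} tweets "
      f"({report.n_advertisements} advertisements dropped)")
print("per-stage removals:", dict(report.stage_removals))

scores = ws.score_corpus(corpus)
counts = {p: sum(1 for s in scores if s.polarity == p)
          for p in ("positive", "negative", "neutral")}
pct = ws.proportions(list(counts.values()), 2)
print("\npolarity counts:", counts)
print("polarity percents:", dict(zip(counts, pct)))

hist = ws.intensity_histogram(scores)
print("\nintensity histogram (bin: count, percent):")
for b in ws.INTENSITY_LABELS:
    print(f"  {b:>15s}: {hist.counts[b]:4d}  {hist.percents[b]:6.2f}%")

# With 0.4 injection the planted positive/negative tweets land far from the
# neutral band, so the percent split tracks the generator's 0.4/0.4/0.2 mixture.
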