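"""Generate a synthetic tweet corpus with planted topics, polarity, and noise.

The generator is the package's ground-truth source: every tweet records which
topic and polarity class produced it, so downstream stages can be scored.
"""

from collections import Counter

import worksent as ws

spec = ws.default_spec(seed=42, n_tweets=500)
corpus, truth = ws.generate_corpus(spec)

print(f"generated {len(corpus)} tweets, {len(spec.topics)} planted topics")
print("class mixture:", Counter(r.polarity for r in truth.records))
print("noise applied:", Counter(n for r in truth.records for n in r.noise))
print("\nthree sample tweets (raw text as the cleaner will see it):")
for tweet, record in list(zip(corpus, truth.records))[:3]:
    print(f"  [{record.polarity:8s} topic {record.topic_id}] {tweet.text[:90]}")

# The class counts should track the 0.4/0.4/0.2 mixture; the sample tweets mix
# pseudo-word topic tokens with injected opinion-lexicon words and noise.
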