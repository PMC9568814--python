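# Methods

`worksent` implements a surveillance-style analysis of work-related sentiment
in microblog (tweet) corpora: query-keyword formulation, staged text cleaning,
topic modeling with coherence-based model selection, opinion-lexicon topic
polarity, per-tweet compound sentiment scoring, and labeled-subset word
statistics. The original study corpus (≈1.47M tweets) is not redistributable,
so the package ships a synthetic corpus generator whose planted structure
gives every stage a recoverable ground truth. This note records the models,
the parameters that matter, and the design choices made where the design was
genuinely open.

## Keyword formulation

Search keywords are built in three steps.

1. **Category cross-product.** Panel-elicited work nouns (category 1) and
   sentiment adjectives (category 2) are composed into every "prefix postfix"
   pair; explicit phrases (category 3) join the pool verbatim. Keywords are
   deduplicated on the token multiset because matching is order-insensitive.
2. **Embedding synonym expansion.** Each category word is expanded with its
   `k = 5` nearest neighbors by cosine similarity in a pretrained word-vector
   table (plain-text word-vector format). Out-of-vocabulary words pass
   through unexpanded; cosine ties break lexicographically for determinism.
3. **Binary particle-swarm refinement.** A keyword matches a tweet when every
   keyword token occurs in it as a whole word (hashtag bodies count with `#`
   stripped), in any order and multiplicity. The swarm searches over binary
   inclusion vectors with fitness

   fitness(S) = cos(centroid of tweets retrieved by S, centroid of all seed
   tweets) − λ·|S|/|pool|, λ = 0.1,

   where a tweet is embedded as the mean vector of its in-vocabulary tokens
   and an empty retrieval scores −1. The size penalty keeps the query set
   lean; the cosine term rewards retrieving a stream that looks like the seed
   stream. Velocities pass through a logistic squash giving per-bit
   one-probabilities (standard discrete PSO); inertia 0.7, cognitive and
   social coefficients 1.5, velocities clipped at ±6, 20 particles, 50
   iterations. One particle is initialized at the all-candidates subset, so
   the refined set is never less fit than the unrefined pool, and the global
   best is elitist (never worsens). On pools small enough to enumerate, the
   swarm's optimum is checked against exhaustive subset search in the tests.

## Cleaning chain

Cleaning is a fixed, auditable stage order (counts are reported per stage):
lowercase → contraction expansion → URL removal → markup removal → mention
removal → hashtag removal (the whole `#token`) → digit-bearing word removal →
punctuation stripping → repeated-character collapse (runs of ≥3 to exactly 2)
→ whitespace tokenization → stopword removal → search-keyword elimination →
meaningless/advertising word removal (`thi, wa, rt, ann`; `click, coupon`) →
single-character removal → lemmatization → stemming. Tweets containing an
advertising word as a whole word are dropped wholesale before token cleaning.

Choices worth noting:

- "Digit-bearing word removal" removes any whitespace-delimited token
  containing a digit (`covid19`, `b2b`, `2022`), because the output contract
  forbids digits in tokens; `covid` as a pure-letter token survives.
- Keyword elimination runs on surface tokens before normalization and again
  on stems afterwards (a keyword can reach the stemmer in an inflected form);
  the post-stem pass can be disabled.
- Normalization is a shallow plural lemmatizer followed by the Porter
  stemming algorithm, in that order. Porter is not idempotent on arbitrary
  English (e.g. `agreed → agre → agr`), so the idempotence test asserts the
  fixed point on a curated fixture set, not universally.
- Stage order is observable: a token that is both a hashtag and a keyword is
  accounted as a hashtag removal.

## Topic modeling and model selection

Cleaned token lists become an id-term dictionary and sparse count matrix.
Topic models are latent Dirichlet allocation fit by batch variational
inference (scikit-learn) with a fixed seed; the scan covers K = 2..31 by
default (callers choose the range; the tests and the acceptance script use
2..6 against a 3-topic planted corpus). Variational LDA is sensitive to
initialization, so each fit is restarted three times from deterministically
derived seeds and the restart with the highest variational bound is kept;
without restarts an unlucky initialization at the true K can depress its
coherence enough to distort model selection.

Coherence is a context-window c_v-style measure: word probabilities are
boolean window occurrences (tweets are far shorter than the conventional
110-token window, so each document is one window and probabilities reduce to
document frequencies); each top word is represented by its NPMI vector
against the topic's top-10 words, and topic coherence is the mean cosine
between each word's vector and the summed vector. Model coherence is the
mean over topics.

Published practice picks the coherence maximum but resolves near-ties by
looking at topic overlap on the intertopic map. The computable counterpart
implemented here: among all K with coherence within `tolerance = 0.005` of
the maximum, select the K whose model has the largest mean pairwise
Jensen–Shannon distance (base 2) between topic-word distributions; remaining
ties go to the smallest K. The selection is permutation-invariant in curve
order.

## Topic polarity (lexicon voting)

Each topic's top-word list is scored word by word against four vocabularies:
the positive and negative opinion lexicons and the top-n (default n = 50)
cleaned tokens of positively / negatively labeled tweets. A word in the
positive union increments the positive count; in the negative union the
negative count; in neither, the neutral count. Membership within one polarity
is a union (a word in both the lexicon and the labeled set counts once); a
word in both a positive and a negative vocabulary increments both counters.
The topic label is the strict-majority class; without a strict majority the
topic is Neutral (the least committal completion of three strict
inequalities). Topic-level proportions are reported as nearest-integer
percentages (half-up): 17/28 → 61, 3/28 → 11, 8/28 → 29.

## Compound sentiment scoring

Per-tweet sentiment uses the package's lexicon-and-rule scorer on the **raw**
text — the rules need the surface form (casing, punctuation) that cleaning
destroys; cleaning and scoring are parallel tracks, not a sequence. The
valence lexicon maps ~330 sentiment-bearing words to signed strengths on a
nominal ±4 scale; it also induces the binary opinion lexicon (positive =
valence > 0), keeping the two resources consistent by construction. Rules:

- negation within the three preceding tokens flips and damps the valence
  (× −0.74);
- degree adverbs within three tokens boost/damp by ±0.293 with distance
  decay (1.0, 0.95, 0.9);
- an all-caps word gains ±0.733 emphasis unless the whole text is shouted;
- exclamation marks add ±0.292 each (capped at four) in the direction of the
  running total;
- the total is squashed to a compound in [−1, +1] via s/√(s² + 15).

Polarity: neutral iff −0.05 ≤ c ≤ +0.05 (band inclusive), else the sign.
Intensity uses nine fixed bins with edges (−1, −0.75, −0.5, −0.25, −0.05,
0.05, 0.25, 0.5, 0.75, 1); interior edges belong to the right (higher) bin
and +1.0 to the last. The published table and figure disagree by 213 tweets
in the neutral band — evidence of two boundary conventions — so one
convention is used everywhere here and stated explicitly.

Term-stratified counts (e.g. mentions of "covid") match the term
case-insensitively at word boundaries in the raw text, so `covid19` is not a
match for `covid`.

## Labeled-subset analysis

Per-class top-word tables rank cleaned tokens by frequency (ties
lexicographic); the percent column is taken against the sum of the table's
own counts, since the published tables' denominator is not recoverable.
Conjugate words collect, for each target, the tokens within a window
(default 1) of any occurrence across the cleaned token stream — "previous or
next" means the nearest surviving content token; a raw-adjacency mode exists
for auditing. Class proportions are nearest-integer percentages.

## Synthetic corpus generator

The generator emulates the statistical structure the analysis assumes:
topical clusters, polarity-bearing lexicon words, and platform noise.

- **Content vocabulary.** Pseudo-words sampled from consonant–vowel
  syllables, screened against the valence lexicon, stopword, meaningless and
  advertising lists, with unique stems — planted topics therefore have
  disjoint supports that remain disjoint after normalization, and carry no
  sentiment.
- **Planted topics.** K_true topics (default 3) of 30 words each with
  Zipf-shaped weights.
- **Classes and coupling.** Class mixture defaults to 0.4/0.4/0.2
  (positive/negative/neutral). Topic i is affiliated with class i mod 3, and
  a tweet's topic is its class's affiliate with probability 0.9
  (`class_topic_coupling`), else uniform. Coupling is needed for the
  end-to-end recovery property — if topics and classes were independent,
  every topic's dominant class would be the global majority and topic
  polarity would be unrecoverable in principle.
- **Polarity injection.** In non-neutral tweets each token is, with
  probability 0.4, drawn from a 20-word class signature sampled from the
  opinion lexicon — deliberately the same lexicon the pipeline scores with,
  so recovery tests isolate pipeline correctness from lexicon coverage. The
  20-word signatures concentrate sentiment mass enough that injected words
  reach the fitted topics' top-30 lists.
- **Noise.** Per-tweet probabilities: URL 0.15, mention 0.15, hashtag 0.15,
  contraction 0.15 (only contractions that expand to stopwords, never
  negators), meaningless word 0.10, advertisement 0.03, letter stretching
  0.08 and misspelling 0.08 (both applied only to non-lexicon content
  tokens, so the planted polarity class is never changed; a corrupted
  content token may survive cleaning as a rare junk token, which the
  recovery metrics tolerate).
- **Length.** Poisson with mean 12, floored at 3 tokens.

What passing recovery tests show: the pipeline recovers structure *that
matches its own modeling assumptions* — disjoint topics, lexicon-aligned
sentiment, removable noise. They do not show robustness to real-language
phenomena the generator omits: sarcasm, negated sentiment ("not happy" is
generated never), topic overlap, emoji, code-switching, misspelled sentiment
words, or lexicon gaps.

## Problem sizes and numerical choices

The recovery experiments use five seeded corpora of n = 2000 tweets each,
scan K over 2..6, label 800 tweets per corpus, and use top-30 topic words
for polarity voting; the swarm benchmark enumerates all 2¹⁰ subsets of a
10-candidate pool. Percent rounding is half-up at the printed precision (two
decimals for corpus-level shares, integers for labeled/topic shares).
Distribution normalization is checked at 1e-6; Jensen–Shannon distances are
verified against a direct formula evaluation at 1e-9. All stochastic
components (generator, LDA, swarm) consume explicit integer seeds and are
reproducible bit-for-bit.

## Known limitations

- The lexicons (valence, stopwords, contractions) are compact curated lists,
  adequate for the synthetic conditions and worked examples but far smaller
  than production sentiment lexicons; coverage, not the rule engine, is the
  first limit on real-tweet accuracy.
- The lemmatizer handles noun plurals only; verbs rely on the stemmer.
- Coherence uses document-level co-occurrence, which equals the windowed
  definition only for documents shorter than the window (true for tweets).
- The exact published topic count (28 on the original corpus) is not
  reproducible without the original data and is not claimed; the selection
  *rule* is tested on constructed ties and on planted corpora instead.
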