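# Methods

This note documents the models, conventions and design choices behind
`conceptrank`: what is computed, under which assumptions, and what the
synthetic experiments do and do not show.

## Evaluation protocol

Annotations are (CUI, semantic type) pairs attached to sentences; character
spans are out of scope. A predicted pair is a true positive only when both
fields match a gold pair of the same sentence (joint matching); a correct CUI
with a wrong type therefore counts as one false positive *and* leaves the
gold pair as a false negative — the plain set-difference reading. All
counting is over deduplicated sets: the sentence-level protocol has no span
multiplicity, so a concept suggested twice counts once.

Two aggregations are exposed:

* **overall ("macro")** — TP/FP/FN pooled over all sentences, then P/R/F1;
* **type-based ("micro")** — the same pooling restricted per semantic type.

Both pool counts rather than averaging per-sentence metrics because pooled
counts behave predictably under set union (recall can only grow) and sum
exactly across the type partition. A per-sentence-averaged variant is
available behind `aggregate_overall(..., average="sentence")` for comparison.

Zero denominators yield 0 for the affected metric. One deliberate exception:
the **per-sentence F1 used as the ranking signal** scores an empty prediction
on an empty-gold sentence as 1.0 (and any non-empty prediction as 0.0).
Rank labels must order systems on sentences with no disorders, and abstention
is the correct behaviour there; without the convention all systems would tie
at 0 and those sentences would carry no training signal.

The semantic-type inventory defaults to the ten disorder types
(T047, T184, T046, T037, T019, T190, T191, T048, T033, T020); minor classes
seen only once in the reference corpus profile (T002, T031, T049, T058, T059,
T121, T197) are filtered out. Filtering keeps sentences whose concept set
becomes empty, so evaluation denominators are unchanged, and is idempotent.

Sentences are keyed by `(doc_id, sent_index)` with a 0-based index — a stable
join key across the gold corpus and any number of system runs. Systems that
skip a sentence contribute an empty prediction set rather than an error.
CUIs are carried as opaque strings; no UMLS lookup is performed or required.

## Features and rank labels

Each gold sentence is one instance; each registered system contributes one
sparse vector, laid out in fixed block order:

| block | content | size (defaults) |
|-------|---------|------|
| FB1 | system identity one-hot | 9 |
| FB2 | per-type paired indicators: predicted-present / predicted-absent | 20 |
| FB3 | counts of predicted-concept label tokens over a lexicon vocabulary | lexicon-dependent |
| FB4 | sentence bag-of-words counts over a training-text vocabulary | vocabulary-dependent |
| FB5 | counts of the 45 distributional clusters of the FB3 tokens | 45 |

FB1, FB2 and FB4 are enabled by default — the configuration found most
effective for this ensemble; FB3/FB5 are implemented but off by default.
FB2 encodes only the scored system's own prediction (the literal reading of
the block description), as two complementary bits per inventory type. FB4
depends only on the sentence, so it is identical across the nine vectors of
one instance; for linear rankers it cancels in within-instance score
differences and the sentence context reaches the ranking through FB2 (which
systems predict what) — for RankNet it can interact with FB1 nonlinearly.

Tokenisation is lowercasing plus splitting on Unicode whitespace/punctuation,
with a configurable minimum count (default 1) and deterministic lexicographic
index order. FB3 reads "vocabulary terms appearing in predicted concepts" as
concept-label tokens supplied by a pluggable `ConceptLexicon`; the 45-cluster
table for FB5 is likewise pluggable (an external clustering resource or a
synthetic table both work), so nothing requires a download.

Relevance labels: within an instance, systems are dense-ranked by descending
per-sentence F1; ties share a rank, and relevance = (number of distinct F1
values) − dense rank, so the best systems get the highest integer and the
worst get 0. Rankers consume these integers, not raw F1 — the convention
expected by standard learn-to-rank tooling.

## Rankers

All four rankers are implemented from their defining loss functions, with the
published settings as defaults (hinge trade-off C = 30; RankNet 100 epochs,
one hidden layer of 10 sigmoid units, learning rate 5·10⁻⁵; RankBoost 300
rounds, 10 threshold candidates; ListNet 1500 epochs, learning rate 10⁻⁵).
Weight-level parity with any particular released ranking toolkit is neither
promised nor testable; objective-level behaviour is what the tests pin down.
Training pairs are formed only within an instance and only across distinct
relevance levels.

Optimisation choices (the published settings do not fix them):

* **hinge_svm** — full-batch subgradient descent from zero initialisation on
  the per-pair rescaled objective λ/2‖w‖² + (1/n)Σ hinge, λ = 1/(C·n_pairs),
  with diminishing steps η_t = η₀/√t (η₀ = 1.0, 200 epochs). A
  Pegasos-style η_t = 1/(λt) schedule was tried first and oscillates badly
  here: with thousands of pairs λ is ~10⁻⁶ and the early steps are enormous.
  The chosen schedule is deterministic and converges on all tested inputs.
* **ranknet** — full-batch gradient descent; seed-controlled
  uniform(−0.1, 0.1) initialisation; numerically stable log(1+exp(−Δs)).
* **listnet** — full-batch gradient descent from zero initialisation; the
  target distribution is softmax over the relevance integers; the analytic
  gradient is verified against central differences to 10⁻⁵ relative error.
* **rankboost** — threshold candidates are evenly spaced interior quantiles
  per feature (scale-free), duplicates collapsed, constant features skipped.
  Each round maximises |r|, r = Σ D(i,j)(h(xᵢ)−h(xⱼ)), with
  α = ½ln((1+r)/(1−r)) (r clipped by 10⁻¹⁰ to avoid infinities) and the
  usual multiplicative distribution update. Argmax ties resolve to the lowest
  candidate index. Note the monotone quantity is the exponential bound
  Π_t Z_t on the ranking loss (each Z_t ≤ 1); the raw 0-1 pairwise error
  fluctuates round to round while trending down.

Models serialise to JSON and round-trip bit-exactly (Python's float repr is
lossless); scoring is deterministic, and identical data + config + seed
produce byte-identical model files. A diagnostic `pairwise_error` reports the
fraction of discordant within-instance pairs, score ties counting 0.5.
Features are used as raw counts/indicators; an optional per-feature
max-scaling flag exists but is off by default and claims no equivalence to
any external toolkit's normalisation.

## Ensemble

`rank_instance` sorts systems by descending score with the registry index as
a deterministic tie-key, then chains scores whose consecutive gaps are within
ε (default 10⁻⁹, configurable) into shared dense ranks — exact ties arise
naturally for systems whose features differ only in FB1. Top-K selects all
systems with dense rank ≤ K.

* **union** merges the selected systems' sets — deployable, needs no gold.
* **oracle** keeps the single selected system with the highest per-sentence
  F1 — an upper-bound diagnostic. Ties on F1 are broken by fewer false
  positives, then lowest registry index. (Breaking by registry index alone
  can pick an equal-F1 prediction with more false positives when the pool
  grows, and was observed to make pooled oracle F1 dip by ~0.001 between
  adjacent K; the precision-leaning tie-break removes that artefact while
  staying fully deterministic. Pooled-ratio monotonicity in K has no general
  proof either way; it holds empirically under the study conditions.)

Contributions divide, per system, the number of instances in which it
participated (selected set for union; chosen system for oracle) by the total
number of instances — so oracle contributions sum to 1 and union
contributions may sum to more. A selected system counts even if it
contributed zero annotations on that instance.

Cross-validation uses documents as the sampling unit: a seeded shuffle,
near-equal parts (the first `n mod folds` parts take one extra document),
training from scratch per fold with the FB4 vocabulary rebuilt from the
training part only, and pooled metrics over the concatenated held-out
predictions.

## Synthetic data

The generator emulates the statistical structure of the target setting, not
its language:

* ten disorder types with skewed frequency weights
  (1803/842/518/213/184/103/92/84/45/40) and per-type catalogue sizes
  (410/163/133/96/25/36/49/32/15/17 distinct CUIs);
* concept labels of 1–4 tokens drawn from per-type token pools; sentence
  text is the concatenation of the concept labels, an optional context
  marker, and background tokens — so FB4 carries real signal;
* per-sentence concept counts with distribution (0.30, 0.38, 0.20, 0.08,
  0.04) over 0..4, i.e. roughly one annotation per sentence with a
  substantial abstention mass;
* default corpus size 60 documents of 4–8 sentences (≈340 sentences) —
  large enough for stable pooled metrics and 10-fold document CV while
  keeping a full cross-validated experiment in seconds;
* nine system profiles: independent Bernoulli recovery of each gold concept
  at a per-type sensitivity, plus Poisson spurious concepts drawn within-type
  from the catalogue (excluding that sentence's gold), spread over types
  proportionally to the type weights. The preset roster has a high-recall/
  low-precision system (M3), a high-precision system (M5), a weak system
  (M2), near-clone mid-field variants (M4, M6–M9), and two *context rules*:
  M1's sensitivity is boosted ×3.2 on sentences containing the `alpha`
  marker, M5's on `beta` (markers appear on 30% of sentences each). The
  context rules make different systems the per-sentence best on textually
  identifiable subsets — exactly the signal a learn-to-rank ensemble must
  pick up to beat every stand-alone system.

All sampling flows through seeded generators; the same seed reproduces
byte-identical JSONL. The noise model is our own construction — the simplest
one that reproduces the precision/recall asymmetries of real annotators. It
contains none of the linguistics that makes the real task hard
(abbreviations, coordination, inference, sentence segmentation), so passing
results demonstrate that the pipeline and the rankers work as specified and
that the ensemble exploits complementarity when it exists; they do not
predict absolute performance on clinical text.

A separate `planted_utility_instances` generator produces abstract ranking
instances whose relevance follows a planted linear utility over standard
normal features — the canonical diagnostic for the pairwise rankers
(a correct implementation recovers the direction and orders held-out
instances almost perfectly).

## Problem sizes and runtime

The shipped experiments use the default 60-document suite; the uplift
experiment repeats generation + 10-fold CV for five seeds (≈1 min total),
and statistical generator checks (multinomial type proportions, binomial
recall, near-clone F1 proximity) use 400–1500 document corpora where the
3σ bands are meaningful.

## Known limitations

* RankNet and ListNet at their pinned default learning rates move slowly on
  count-scaled features; they train correctly (loss decreases, gradients
  verified) but the hinge and RankBoost rankers reach much lower pairwise
  error at their defaults, and the hinge ranker is the one used in the
  headline uplift experiment.
* The oracle strategy requires gold labels and is a diagnostic only.
* Mention-level (span) evaluation, UMLS validation, negation/temporal
  attributes, and running the real base annotators are out of scope.
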