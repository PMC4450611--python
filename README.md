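# conceptrank

Learn-to-rank ensembling of clinical concept-annotation systems at the
sentence level.

## The problem

Off-the-shelf concept recognisers (MetaMap and its option variants, cTAKES,
NCBO Annotator, BeCAS, ...) map clinical text to UMLS concepts — pairs of a
concept unique identifier (CUI, e.g. `C0018681` *headache*) and a semantic
type (e.g. `T184` *Sign or symptom*). No single system wins everywhere: one
may have strong recall but poor precision, another the reverse, and their
relative quality shifts from sentence to sentence and from semantic type to
semantic type. `conceptrank` exploits that complementarity: instead of voting,
it *learns to rank* the systems per sentence and lets the top-ranked system(s)
decide the final annotation set.

Evaluation is at the **sentence level**: a prediction counts as a true
positive only if both the CUI and the semantic type match a gold annotation of
the same sentence. With pooled counts TP/FP/FN,

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2PR / (P + R).

The retained label space is the ten disorder semantic types
T047, T184, T046, T037, T019, T190, T191, T048, T033, T020.

## The method

Each gold sentence is a ranking *instance*. For every base system
M1..M9 a sparse feature vector is built from up to five blocks (FB1 system
identity one-hot; FB2 predicted-present/absent indicators per semantic type;
FB3 predicted-concept label-token counts; FB4 sentence bag-of-words counts;
FB5 45 distributional token clusters; FB1+FB2+FB4 is the default). The
supervision signal is each system's per-sentence F1, dense-ranked into integer
relevance labels. Four rankers are implemented from scratch on that signal:

* **hinge_svm** — pairwise linear ranking SVM objective,
  ½‖w‖² + C·Σ hinge(1 − w·(xᵢ − xⱼ)) over within-instance pairs (C = 30);
* **ranknet** — one-hidden-layer network with pairwise logistic loss
  (100 epochs, 10 hidden nodes, learning rate 5·10⁻⁵);
* **rankboost** — boosted threshold weak rankers `[x_f > θ]`
  (300 rounds, 10 quantile threshold candidates per feature);
* **listnet** — listwise top-one-probability cross entropy on a linear scorer
  (1500 epochs, learning rate 10⁻⁵).

At prediction time the per-sentence ranking is cut off at **top-K** (tied
scores share a dense rank, so even K = 1 can select several systems) and
turned into one concept set by a **union** of the selected systems'
predictions, or — as a diagnostic upper bound that peeks at the gold — by an
**oracle** that keeps the single best selected system. Per-system
*contributions* record how often each base system participates in the outcome.
Evaluation of the trained ensemble uses randomised 10-fold cross-validation
with documents as the sampling unit.

The real corpus this protocol targets is access-restricted, so the package
ships a synthetic generator (`conceptrank.synthetic`) producing gold corpora
with the published skewed type-frequency profile and nine simulated systems
with heterogeneous, partly context-dependent precision/recall profiles — the
statistical structure the ensemble needs, without any download.

## Worked example

```bash
conceptrank simulate --seed 42 --out data
conceptrank evaluate --gold data/gold.jsonl --preds data/preds.jsonl --system M3 | head -2
conceptrank cv --gold data/gold.jsonl --preds data/preds.jsonl \
    --model hinge_svm --folds 10 --seed 42 | head -2
```

prints (abridged):

```
INFO conceptrank: simulated 344 sentences across 60 documents, 9 systems
scope    P       R       F1      tp   fp   fn   system
overall  0.2756  0.6005  0.3778  266  699  177  M3
scope    P       R       F1      tp   fp   fn   system
overall  0.5760  0.7788  0.6622  345  254  98   hinge_svm/top1/union
```

The simulated M3 behaves like a high-recall/low-precision annotator
(R = 0.60, P = 0.28, F1 = 0.38); the best stand-alone system on this corpus is
the high-precision M5 at F1 = 0.5802. The cross-validated top-1 union
ensemble reaches F1 = 0.6622 on held-out documents — above every stand-alone
system, because the ranker learns which system to trust on which sentence
(including the context-marker subsets where M1 or M5 dominate).

The same pipeline is available as library calls (`preset_suite`,
`build_training_set`, `train`, `apply_model`, `cross_validate`) — see the
module docstrings and `docs/methods.md`.

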