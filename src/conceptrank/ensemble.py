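"""Top-K system combination and document-level cross-validation.

A trained ranker only orders the base systems on each sentence; to evaluate
it as an annotator, the ranking is turned into a hard outcome with a top-K
cut-off: every system whose *dense* rank is at most K participates.  Because
tied scores share a rank, several systems can participate even at K = 1.
Two tie-breaking strategies turn participants into one concept set:

* ``union`` — set union of the participants' predictions (deployable);
* ``oracle`` — with gold access, keep only the single participant whose
  prediction maximises the per-sentence F1 (an upper-bound diagnostic that
  also exposes which systems actually carry the ensemble).

Contribution bookkeeping records, per system, the fraction of sentences in
which it participated in the final outcome: oracle contributions sum to 1,
union contributions may sum to more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import AbstractSet, Mapping, Sequence

import numpy as np

from .corpus_io import (
    DEFAULT_SYSTEMS,
    ConceptAnnotation,
    Corpus,
    SentenceKey,
    SystemRun,
)
from .evaluation import MetricTriple, aggregate_overall, sentence_f1
from .features import (
    DEFAULT_BLOCKS,
    ConceptLexicon,
    FeatureSpace,
    FeatureVector,
    Vocabulary,
    build_training_set,
)
from .rankers import RankerConfig, RankModel, train

__all__ = [
    "EnsembleConfig",
    "RankedSystem",
    "SentenceOutcome",
    "EnsembleResult",
    "rank_instance",
    "select_topk",
    "combine_union",
    "combine_oracle",
    "contributions",
    "apply_model",
    "cross_validate",
    "CVResult",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EnsembleConfig:
    top_k: int = 1
    strategy: str = "union"
    epsilon: float = 1e-9  # score-tie tolerance, chained after sorting

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if self.strategy not in ("union", "oracle"):
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if self.epsilon < 0:
            raise ConfigError("epsilon must be non-negative")


@dataclass(frozen=True)
class RankedSystem:
    system_id: str
    score: float
    dense_rank: int  # 1 = best


@dataclass(frozen=True)
class SentenceOutcome:
    key: SentenceKey
    ranking: tuple[RankedSystem, ...]
    selected: frozenset[str]
    combined: frozenset[ConceptAnnotation]
    chosen: str | None = None  # oracle only


@dataclass
class EnsembleResult:
    config: EnsembleConfig
    outcomes: dict[SentenceKey, SentenceOutcome] = field(default_factory=dict)

    def predictions(self) -> dict[SentenceKey, frozenset[ConceptAnnotation]]:
        return {k: o.combined for k, o in self.outcomes.items()}


def rank_instance(
    model: RankModel,
    vectors: Mapping[str, FeatureVector],
    systems: Sequence[str] = DEFAULT_SYSTEMS,
    epsilon: float = 1e-9,
) -> tuple[RankedSystem, ...]:
    """Score and dense-rank the systems of one instance.

    Sorting is by descending score with the system registry index as the
    deterministic secondary key; after sorting, scores whose consecutive gap
    is within ``epsilon`` are chained into the same dense rank.
    """
    reg_index = {s: i for i, s in enumerate(systems)}
    sids = [s for s in systems if s in vectors]
    if not sids:
        raise ConfigError("no systems to rank")
    scored = sorted(
        ((model.score_vector(vectors[s]), s) for s in sids),
        key=lambda t: (-t[0], reg_index[t[1]]),
    )
    out = []
    rank = 1
    prev_score = scored[0][0]
    for sc, sid in scored:
        if prev_score - sc > epsilon:
            rank += 1
        out.append(RankedSystem(system_id=sid, score=sc, dense_rank=rank))
        prev_score = sc
    return tuple(out)


def select_topk(ranking: Sequence[RankedSystem], k: int) -> frozenset[str]:
    """Systems with dense rank <= K (may exceed K systems under ties)."""
    if not 1 <= k <= len(ranking):
        raise ConfigError(f"top_k {k} out of range 1..{len(ranking)}")
    return frozenset(r.system_id for r in ranking if r.dense_rank <= k)


def combine_union(
    selected: AbstractSet[str],
    predictions: Mapping[str, AbstractSet[ConceptAnnotation]],
) -> frozenset[ConceptAnnotation]:
    out: set[ConceptAnnotation] = set()
    for sid in selected:
        out |= set(predictions.get(sid, frozenset()))
    return frozenset(out)


def combine_oracle(
    selected: AbstractSet[str],
    predictions: Mapping[str, AbstractSet[ConceptAnnotation]],
    gold: AbstractSet[ConceptAnnotation],
    systems: Sequence[str] = DEFAULT_SYSTEMS,
) -> tuple[str, frozenset[ConceptAnnotation]]:
    """Best single participant by per-sentence F1.

    Ties on F1 are broken by fewer false positives (among equally scoring
    participants, prefer the more precise suggestion set), then by lowest
    registry index; all keys are deterministic.
    """
    reg_index = {s: i for i, s in enumerate(systems)}
    ordered = sorted(selected, key=lambda s: reg_index.get(s, len(systems)))
    if not ordered:
        raise ConfigError("oracle combination requires a non-empty selection")

    def key(s: str) -> tuple[float, int, int]:
        pred = frozenset(predictions.get(s, frozenset()))
        return (sentence_f1(pred, gold), -len(pred - set(gold)), -reg_index.get(s, len(systems)))

    best = max(ordered, key=key)
    return best, frozenset(predictions.get(best, frozenset()))


def contributions(
    result: EnsembleResult, systems: Sequence[str] = DEFAULT_SYSTEMS
) -> dict[str, float]:
    """Fraction of instances in which each system participated in the outcome."""
    n = len(result.outcomes)
    if n == 0:
        raise ConfigError("no instances")
    counts = {s: 0 for s in systems}
    for o in result.outcomes.values():
        if result.config.strategy == "oracle":
            if o.chosen is not None:
                counts[o.chosen] += 1
        else:
            for s in o.selected:
                counts[s] += 1
    return {s: c / n for s, c in counts.items()}


def apply_model(
    model: RankModel,
    space: FeatureSpace,
    gold: Corpus,
    runs: Sequence[SystemRun],
    config: EnsembleConfig,
) -> EnsembleResult:
    """Rank, cut off at top-K and combine on every sentence of ``gold``.

    The oracle strategy reads the gold annotations at combination time; union
    never does.
    """
    by_sid = {r.system_id: r for r in runs}
    result = EnsembleResult(config=config)
    for s in gold:
        preds = {sid: by_sid[sid].get(s.key) for sid in space.systems if sid in by_sid}
        vectors = {sid: space.extract(s, preds[sid], sid) for sid in preds}
        ranking = rank_instance(model, vectors, systems=space.systems, epsilon=config.epsilon)
        selected = select_topk(ranking, config.top_k)
        if config.strategy == "union":
            combined = combine_union(selected, preds)
            chosen = None
        else:
            chosen, combined = combine_oracle(selected, preds, s.concept_set, systems=space.systems)
        result.outcomes[s.key] = SentenceOutcome(
            key=s.key, ranking=ranking, selected=selected, combined=combined, chosen=chosen
        )
    return result


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_documents: list[list[str]]
    fold_metrics: list[MetricTriple]
    pooled: MetricTriple
    predictions: dict[SentenceKey, frozenset[ConceptAnnotation]]
    contributions: dict[str, float]


def _fold_partition(documents: Sequence[str], folds: int, seed: int) -> list[list[str]]:
    docs = list(documents)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(docs))
    shuffled = [docs[i] for i in order]
    base, extra = divmod(len(docs), folds)
    parts = []
    start = 0
    for f in range(folds):
        size = base + (1 if f < extra else 0)
        parts.append(shuffled[start:start + size])
        start += size
    return parts


def cross_validate(
    gold: Corpus,
    runs: Sequence[SystemRun],
    *,
    ranker_config: RankerConfig,
    ensemble_config: EnsembleConfig = EnsembleConfig(),
    blocks: Sequence[str] = DEFAULT_BLOCKS,
    systems: Sequence[str] = DEFAULT_SYSTEMS,
    inventory: Sequence[str] | None = None,
    lexicon: ConceptLexicon | None = None,
    min_count: int = 1,
    folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Randomised K-fold cross-validation with documents as the sampling unit.

    Documents are shuffled by ``seed`` and split into near-equal parts (the
    first ``n mod folds`` parts take one extra document).  For each fold the
    ranker is trained from scratch on the other parts — the FB4 vocabulary is
    rebuilt from the training part only — and applied to the held-out part.
    The held-out predictions of all folds are then joined and pooled metrics
    computed over the concatenation.
    """
    from .corpus_io import DEFAULT_TYPE_INVENTORY

    inventory = tuple(inventory) if inventory is not None else DEFAULT_TYPE_INVENTORY
    documents = gold.documents()
    if len(documents) < folds:
        raise ConfigError(f"need at least {folds} documents, got {len(documents)}")
    parts = _fold_partition(documents, folds, seed)

    all_preds: dict[SentenceKey, frozenset[ConceptAnnotation]] = {}
    fold_metrics: list[MetricTriple] = []
    contrib_counts = {s: 0 for s in systems}
    for f, held_out in enumerate(parts):
        held = set(held_out)
        train_sents = [s for s in gold if s.doc_id not in held]
        test_sents = [s for s in gold if s.doc_id in held]
        train_corpus = Corpus(train_sents)
        test_corpus = Corpus(test_sents)
        vocab = None
        if "FB4" in blocks:
            vocab = Vocabulary.from_texts((s.text for s in train_corpus), min_count)
        space = FeatureSpace(
            blocks=blocks, systems=systems, inventory=inventory, vocab=vocab, lexicon=lexicon
        )
        instances = build_training_set(train_corpus, runs, space)
        model = train(ranker_config, instances, dim=space.dim, systems=list(space.systems))
        result = apply_model(model, space, test_corpus, runs, ensemble_config)
        for key, outcome in result.outcomes.items():
            all_preds[key] = outcome.combined
            if ensemble_config.strategy == "oracle":
                if outcome.chosen is not None:
                    contrib_counts[outcome.chosen] += 1
            else:
                for s in outcome.selected:
                    contrib_counts[s] += 1
        fold_metrics.append(aggregate_overall(test_corpus, result.predictions()))
    pooled = aggregate_overall(gold, all_preds)
    n = len(gold)
    return CVResult(
        fold_documents=parts,
        fold_metrics=fold_metrics,
        pooled=pooled,
        predictions=all_preds,
        contributions={s: c / n for s, c in contrib_counts.items()},
    )
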