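"""Sentence-level evaluation of concept annotation.

A predicted concept counts as a true positive only when both its CUI and its
semantic type match a gold annotation of the same sentence (joint matching).
All counting operates on deduplicated sets — a concept suggested twice counts
once, since the sentence-level protocol has no notion of span multiplicity.

Two aggregations are provided:

* *overall* ("macro"): TP/FP/FN pooled over all sentences, then
  P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R);
* *type-based* ("micro"): the same pooling restricted to each semantic type.

Zero denominators yield a metric of 0.  For the per-sentence F1 used as the
ranking supervision signal only, a sentence with empty gold and an empty
prediction scores 1.0 (abstention on a sentence with no disorders is the best
possible behaviour and must outrank spurious suggestions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping, Sequence

from .corpus_io import (
    DEFAULT_TYPE_INVENTORY,
    ConceptAnnotation,
    Corpus,
    SentenceKey,
    SystemRun,
)

__all__ = [
    "EvalCounts",
    "MetricTriple",
    "count_matches",
    "prf",
    "sentence_f1",
    "aggregate_overall",
    "aggregate_by_type",
]


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricTriple:
    precision: float
    recall: float
    f1: float

    def rounded(self, ndigits: int = 4) -> tuple[float, float, float]:
        return (
            round(self.precision, ndigits),
            round(self.recall, ndigits),
            round(self.f1, ndigits),
        )


def count_matches(
    pred: AbstractSet[ConceptAnnotation], gold: AbstractSet[ConceptAnnotation]
) -> EvalCounts:
    """TP/FP/FN under joint (CUI, type) matching: set intersection/differences."""
    pred, gold = frozenset(pred), frozenset(gold)
    tp = len(pred & gold)
    return EvalCounts(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean F1 = 2PR/(P+R), defined as 0 when P+R = 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def prf(counts: EvalCounts) -> MetricTriple:
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return MetricTriple(precision=p, recall=r, f1=f1_from_pr(p, r))


def sentence_f1(
    pred: AbstractSet[ConceptAnnotation], gold: AbstractSet[ConceptAnnotation]
) -> float:
    """Per-sentence F1 used to derive rank labels.

    Empty gold: 1.0 for an empty prediction (correct abstention), 0.0
    otherwise.  Everything else is plain F1 of the joint-match counts.
    """
    if not gold:
        return 1.0 if not pred else 0.0
    return prf(count_matches(pred, gold)).f1


Predictions = Mapping[SentenceKey, AbstractSet[ConceptAnnotation]]


def _as_mapping(run: "SystemRun | Predictions") -> Predictions:
    if isinstance(run, SystemRun):
        return run.predictions
    return run


def aggregate_overall(
    gold: Corpus,
    run: "SystemRun | Predictions",
    *,
    average: str = "pooled",
) -> MetricTriple:
    """Overall metrics of a run against a gold corpus.

    ``average='pooled'`` (default) pools TP/FP/FN counts over all sentences
    before computing P/R/F1.  ``average='sentence'`` instead averages the
    per-sentence F1 (with the abstention convention) — an alternative reading
    of "macro" provided for comparison; its precision/recall fields are the
    averaged per-sentence P and R.
    """
    preds = _as_mapping(run)
    if average == "pooled":
        total = EvalCounts()
        for s in gold:
            total = total + count_matches(preds.get(s.key, frozenset()), s.concept_set)
        return prf(total)
    if average == "sentence":
        if len(gold) == 0:
            return MetricTriple(0.0, 0.0, 0.0)
        ps = rs = fs = 0.0
        for s in gold:
            p_set = frozenset(preds.get(s.key, frozenset()))
            g_set = s.concept_set
            if not g_set:
                val = 1.0 if not p_set else 0.0
                ps += val
                rs += val
                fs += val
            else:
                m = prf(count_matches(p_set, g_set))
                ps += m.precision
                rs += m.recall
                fs += m.f1
        n = len(gold)
        return MetricTriple(ps / n, rs / n, fs / n)
    raise ValueError(f"unknown average {average!r}")


def overall_counts(gold: Corpus, run: "SystemRun | Predictions") -> EvalCounts:
    """Pooled TP/FP/FN over all sentences."""
    preds = _as_mapping(run)
    total = EvalCounts()
    for s in gold:
        total = total + count_matches(preds.get(s.key, frozenset()), s.concept_set)
    return total


def aggregate_by_type(
    gold: Corpus,
    run: "SystemRun | Predictions",
    inventory: Sequence[str] = DEFAULT_TYPE_INVENTORY,
) -> dict[str, MetricTriple]:
    """Type-based metrics: pooled counts restricted to each semantic type."""
    preds = _as_mapping(run)
    counts = {t: EvalCounts() for t in inventory}
    for s in gold:
        p_set = frozenset(preds.get(s.key, frozenset()))
        g_set = s.concept_set
        for t in inventory:
            counts[t] = counts[t] + count_matches(
                {c for c in p_set if c.stype == t},
                {c for c in g_set if c.stype == t},
            )
    return {t: prf(c) for t, c in counts.items()}


def by_type_counts(
    gold: Corpus,
    run: "SystemRun | Predictions",
    inventory: Sequence[str] = DEFAULT_TYPE_INVENTORY,
) -> dict[str, EvalCounts]:
    preds = _as_mapping(run)
    counts = {t: EvalCounts() for t in inventory}
    for s in gold:
        p_set = frozenset(preds.get(s.key, frozenset()))
        g_set = s.concept_set
        for t in inventory:
            counts[t] = counts[t] + count_matches(
                {c for c in p_set if c.stype == t},
                {c for c in g_set if c.stype == t},
            )
    return counts
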