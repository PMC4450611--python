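"""Feature vectors and rank labels for learn-to-rank training.

Each gold sentence is one ranking *instance*; within an instance every base
system contributes one feature vector and one relevance label derived from
its per-sentence F1.  Feature vectors are the concatenation of up to five
blocks, always laid out in the fixed order FB1..FB5:

FB1  one-hot system identity (one bit per registered system);
FB2  paired present/absent indicators, per inventory semantic type, of the
     types the scored system predicts for the sentence;
FB3  counts of concept-label tokens of the predicted concepts, over a
     vocabulary built from a concept lexicon;
FB4  counts of sentence tokens over a vocabulary built from training text
     (identical across the systems of one instance — it carries the sentence
     context that lets a ranker prefer different systems on different
     sentences);
FB5  counts of the 45 distributional-semantics clusters of the FB3 tokens.

The default enabled blocks are FB1, FB2 and FB4 — the combination found most
effective for this ensemble; FB3/FB5 are implemented but off by default.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import AbstractSet, Iterable, Mapping, Sequence

from .corpus_io import (
    DEFAULT_SYSTEMS,
    DEFAULT_TYPE_INVENTORY,
    AnnotatedSentence,
    ConceptAnnotation,
    Corpus,
    IntegrityError,
    SentenceKey,
    SystemRun,
)
from .evaluation import sentence_f1

__all__ = [
    "ALL_BLOCKS",
    "DEFAULT_BLOCKS",
    "Vocabulary",
    "ConceptLexicon",
    "FeatureSpace",
    "FeatureVector",
    "RankLabel",
    "Instance",
    "tokenize",
    "build_vocab",
    "make_rank_labels",
    "build_training_set",
    "write_feature_file",
    "read_feature_file",
]

ALL_BLOCKS: tuple[str, ...] = ("FB1", "FB2", "FB3", "FB4", "FB5")
DEFAULT_BLOCKS: tuple[str, ...] = ("FB1", "FB2", "FB4")
N_CLUSTERS = 45

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase and split on Unicode whitespace/punctuation."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class Vocabulary:
    """Token -> contiguous index, in deterministic lexicographic order."""

    index: Mapping[str, int]

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], min_count: int = 1) -> "Vocabulary":
        tokens = sorted(t for t, n in counts.items() if n >= min_count)
        return cls(index={t: i for i, t in enumerate(tokens)})

    @classmethod
    def from_texts(cls, texts: Iterable[str], min_count: int = 1) -> "Vocabulary":
        counts: Counter[str] = Counter()
        for text in texts:
            counts.update(tokenize(text))
        return cls.from_counts(counts, min_count)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for t, i in sorted(self.index.items(), key=lambda kv: kv[1]):
                fh.write(f"{t}\t{i}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Vocabulary":
        index: dict[str, int] = {}
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                tok, idx = line.rstrip("\n").split("\t")
                index[tok] = int(idx)
        return cls(index=index)


@dataclass(frozen=True)
class ConceptLexicon:
    """CUI -> concept-label tokens, with an optional token -> cluster table.

    Cluster identifiers live in ``0..44`` (45 distributional classes).  The
    table is pluggable: a table derived from an external clustering resource
    or a synthetic one both work.
    """

    labels: Mapping[str, tuple[str, ...]]
    clusters: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.clusters is not None:
            bad = {t: c for t, c in self.clusters.items() if not 0 <= c < N_CLUSTERS}
            if bad:
                raise ValueError(f"cluster ids out of range 0..{N_CLUSTERS - 1}: {bad}")

    def label_tokens(self, cui: str) -> tuple[str, ...]:
        return self.labels.get(cui, ())

    def vocabulary(self, min_count: int = 1) -> Vocabulary:
        counts: Counter[str] = Counter()
        for toks in self.labels.values():
            counts.update(t.lower() for t in toks)
        return Vocabulary.from_counts(counts, min_count)


def build_vocab(
    corpus: "Corpus | ConceptLexicon",
    min_count: int = 1,
    source: str = "sentences",
) -> Vocabulary:
    """Build a vocabulary from training sentence text or a concept lexicon."""
    if source == "sentences":
        if not isinstance(corpus, Corpus):
            raise TypeError("source='sentences' requires a Corpus")
        return Vocabulary.from_texts((s.text for s in corpus), min_count)
    if source == "lexicon":
        if not isinstance(corpus, ConceptLexicon):
            raise TypeError("source='lexicon' requires a ConceptLexicon")
        return corpus.vocabulary(min_count)
    raise ValueError(f"unknown source {source!r}")


@dataclass(frozen=True)
class FeatureVector:
    """Sparse feature map for one (sentence, system) pair."""

    key: SentenceKey
    system_id: str
    feats: Mapping[int, float]


@dataclass(frozen=True)
class RankLabel:
    """F1-derived relevance: higher per-sentence F1, strictly higher relevance."""

    relevance: int
    dense_rank: int  # 1 = best
    f1: float


@dataclass(frozen=True)
class Instance:
    """One ranking instance: a sentence with one labelled vector per system."""

    key: SentenceKey
    vectors: Mapping[str, FeatureVector]
    labels: Mapping[str, RankLabel]


class FeatureSpace:
    """Fixed block layout mapping (sentence, prediction, system) to indices.

    The layout is computed once from the enabled blocks and the resources they
    need; disabling a block removes exactly its index range.
    """

    def __init__(
        self,
        blocks: Sequence[str] = DEFAULT_BLOCKS,
        systems: Sequence[str] = DEFAULT_SYSTEMS,
        inventory: Sequence[str] = DEFAULT_TYPE_INVENTORY,
        vocab: Vocabulary | None = None,
        lexicon: ConceptLexicon | None = None,
    ) -> None:
        blocks = tuple(b for b in ALL_BLOCKS if b in set(blocks))
        if not blocks:
            raise ValueError("at least one feature block must be enabled")
        unknown = set(blocks) - set(ALL_BLOCKS)
        if unknown:
            raise ValueError(f"unknown blocks: {sorted(unknown)}")
        if ("FB4" in blocks) and vocab is None:
            raise ValueError("FB4 requires a sentence vocabulary")
        if ("FB3" in blocks or "FB5" in blocks) and lexicon is None:
            raise ValueError("FB3/FB5 require a concept lexicon")
        self.blocks = blocks
        self.systems = tuple(systems)
        self._sys_index = {s: i for i, s in enumerate(self.systems)}
        self.inventory = tuple(inventory)
        self._type_index = {t: i for i, t in enumerate(self.inventory)}
        self.vocab = vocab
        self.lexicon = lexicon
        self._concept_vocab = lexicon.vocabulary() if lexicon is not None else None

        sizes = {
            "FB1": len(self.systems),
            "FB2": 2 * len(self.inventory),
            "FB3": len(self._concept_vocab) if self._concept_vocab is not None else 0,
            "FB4": len(vocab) if vocab is not None else 0,
            "FB5": N_CLUSTERS,
        }
        self.offsets: dict[str, tuple[int, int]] = {}
        start = 0
        for b in self.blocks:
            self.offsets[b] = (start, sizes[b])
            start += sizes[b]
        self.dim = start

    def system_index(self, system_id: str) -> int:
        try:
            return self._sys_index[system_id]
        except KeyError:
            raise IntegrityError(f"system {system_id!r} not in registry {self.systems}")

    def extract(
        self,
        sentence: AnnotatedSentence,
        prediction: AbstractSet[ConceptAnnotation],
        system_id: str,
    ) -> FeatureVector:
        feats: dict[int, float] = {}
        sidx = self.system_index(system_id)
        if "FB1" in self.offsets:
            off, _ = self.offsets["FB1"]
            feats[off + sidx] = 1.0
        if "FB2" in self.offsets:
            off, _ = self.offsets["FB2"]
            predicted_types = {c.stype for c in prediction}
            for i, t in enumerate(self.inventory):
                if t in predicted_types:
                    feats[off + 2 * i] = 1.0  # predicted present
                else:
                    feats[off + 2 * i + 1] = 1.0  # predicted absent
        if "FB3" in self.offsets:
            off, _ = self.offsets["FB3"]
            assert self.lexicon is not None and self._concept_vocab is not None
            for c in sorted(prediction):
                for tok in self.lexicon.label_tokens(c.cui):
                    j = self._concept_vocab.index.get(tok.lower())
                    if j is not None:
                        feats[off + j] = feats.get(off + j, 0.0) + 1.0
        if "FB4" in self.offsets:
            off, _ = self.offsets["FB4"]
            assert self.vocab is not None
            for tok in tokenize(sentence.text):
                j = self.vocab.index.get(tok)
                if j is not None:
                    feats[off + j] = feats.get(off + j, 0.0) + 1.0
        if "FB5" in self.offsets:
            off, _ = self.offsets["FB5"]
            assert self.lexicon is not None
            clusters = self.lexicon.clusters or {}
            for c in sorted(prediction):
                for tok in self.lexicon.label_tokens(c.cui):
                    k = clusters.get(tok.lower())
                    if k is not None:
                        feats[off + k] = feats.get(off + k, 0.0) + 1.0
        return FeatureVector(key=sentence.key, system_id=system_id, feats=feats)


def make_rank_labels(per_system_f1: Mapping[str, float]) -> dict[str, RankLabel]:
    """Dense-rank systems by descending per-sentence F1.

    Systems with equal F1 share a rank; relevance is
    ``(number of distinct F1 values) - dense_rank`` so the best shared rank
    carries the highest relevance and the worst carries 0.
    """
    if not per_system_f1:
        raise ValueError("at least one system required")
    distinct = sorted(set(per_system_f1.values()), reverse=True)
    n_levels = len(distinct)
    rank_of = {f1: i + 1 for i, f1 in enumerate(distinct)}
    return {
        sid: RankLabel(relevance=n_levels - rank_of[f1], dense_rank=rank_of[f1], f1=f1)
        for sid, f1 in per_system_f1.items()
    }


def build_training_set(
    gold: Corpus,
    runs: Sequence[SystemRun],
    space: FeatureSpace,
) -> list[Instance]:
    """One labelled instance per gold sentence, one vector per registered system.

    Runs missing a sentence contribute an empty prediction set there.  Every
    system in the feature space's registry must be covered by exactly one run.
    """
    by_sid: dict[str, SystemRun] = {}
    for run in runs:
        if run.system_id in by_sid:
            raise IntegrityError(f"duplicate system id {run.system_id!r} across runs")
        by_sid[run.system_id] = run
    missing = set(space.systems) - set(by_sid)
    if missing:
        raise IntegrityError(f"no run provided for systems: {sorted(missing)}")

    instances = []
    for s in gold:
        vectors: dict[str, FeatureVector] = {}
        f1s: dict[str, float] = {}
        for sid in space.systems:
            pred = by_sid[sid].get(s.key)
            vectors[sid] = space.extract(s, pred, sid)
            f1s[sid] = sentence_f1(pred, s.concept_set)
        instances.append(Instance(key=s.key, vectors=vectors, labels=make_rank_labels(f1s)))
    return instances


def write_feature_file(instances: Sequence[Instance], path: str | Path) -> None:
    """Serialize instances as JSONL, one instance per line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for inst in instances:
            doc, sent = inst.key
            rec = {
                "doc": doc,
                "sent": sent,
                "systems": {
                    sid: {
                        "feats": {str(i): v for i, v in sorted(inst.vectors[sid].feats.items())},
                        "rel": inst.labels[sid].relevance,
                        "f1": inst.labels[sid].f1,
                    }
                    for sid in sorted(inst.vectors)
                },
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_feature_file(path: str | Path) -> list[Instance]:
    instances = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            key = (str(rec["doc"]), int(rec["sent"]))
            f1s = {sid: float(d["f1"]) for sid, d in rec["systems"].items()}
            labels = make_rank_labels(f1s)
            vectors = {
                sid: FeatureVector(
                    key=key,
                    system_id=sid,
                    feats={int(i): float(v) for i, v in d["feats"].items()},
                )
                for sid, d in rec["systems"].items()
            }
            instances.append(Instance(key=key, vectors=vectors, labels=labels))
    return instances
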