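"""Corpora of sentence-level concept annotations.

A gold corpus maps sentences, identified by ``(doc_id, sent_index)``, to sets
of :class:`ConceptAnnotation` — pairs of a UMLS concept unique identifier
(CUI, e.g. ``C0018681`` for *headache*) and a UMLS semantic type (e.g.
``T184`` *Sign or symptom*).  Predictions from individual concept-recognition
systems are held as :class:`SystemRun` objects keyed the same way, so gold and
any number of runs can be joined sentence by sentence.

Two plain-text interchange formats are supported: a JSONL format (one record
per sentence or per (system, sentence)) and a configurable pipe-delimited
stand-off format with one annotation per line.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "ConceptAnnotation",
    "AnnotatedSentence",
    "Corpus",
    "SystemRun",
    "StandoffDialect",
    "ParseError",
    "IntegrityError",
    "DEFAULT_TYPE_INVENTORY",
    "REMOVED_MINOR_TYPES",
    "DEFAULT_SYSTEMS",
    "read_jsonl_corpus",
    "write_jsonl_corpus",
    "read_jsonl_runs",
    "write_jsonl_runs",
    "read_standoff",
    "write_standoff",
    "filter_types",
    "corpus_stats",
]

#: The ten disorder semantic types retained after dropping minor classes
#: (classes observed only once in the reference corpus).
DEFAULT_TYPE_INVENTORY: tuple[str, ...] = (
    "T047",  # Disease or syndrome
    "T184",  # Sign or symptom
    "T046",  # Pathologic function
    "T037",  # Injury or poisoning
    "T019",  # Congenital abnormality
    "T190",  # Anatomical abnormality
    "T191",  # Neoplastic process
    "T048",  # Mental or behavioral dysfunction
    "T033",  # Finding
    "T020",  # Acquired abnormality
)

#: Minor semantic-type classes excluded from evaluation.
REMOVED_MINOR_TYPES: tuple[str, ...] = (
    "T002", "T031", "T049", "T058", "T059", "T121", "T197",
)

#: Registry of base annotation systems combined by the ensemble.
DEFAULT_SYSTEMS: tuple[str, ...] = tuple(f"M{i}" for i in range(1, 10))

SentenceKey = tuple[str, int]


class ParseError(ValueError):
    """A malformed input line; the message names the file line number."""


class IntegrityError(ValueError):
    """A structural violation, e.g. a duplicate sentence key in one corpus."""


@dataclass(frozen=True, order=True)
class ConceptAnnotation:
    """One (CUI, semantic type) pair — the atomic unit matched against gold."""

    cui: str
    stype: str

    def __post_init__(self) -> None:
        if not self.cui:
            raise ValueError("cui must be non-empty")
        if not self.stype:
            raise ValueError("stype must be non-empty")


@dataclass(frozen=True)
class AnnotatedSentence:
    """A sentence with its (deduplicated) set of concept annotations.

    ``term_lengths``, when present, holds the surface length in tokens of each
    concept's mention, aligned with ``concepts``; it is only meaningful for
    gold corpora and feeds the per-type corpus statistics.
    """

    doc_id: str
    sent_index: int
    text: str = ""
    concepts: tuple[ConceptAnnotation, ...] = ()
    term_lengths: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.sent_index < 0:
            raise ValueError("sent_index must be non-negative")
        # Collapse duplicate (cui, stype) pairs, keeping first occurrence and
        # (when given) its aligned term length.
        seen: dict[ConceptAnnotation, int] = {}
        for i, c in enumerate(self.concepts):
            if c not in seen:
                seen[c] = i
        if len(seen) != len(self.concepts):
            keep = sorted(seen.values())
            object.__setattr__(
                self, "concepts", tuple(self.concepts[i] for i in keep)
            )
            if self.term_lengths is not None:
                object.__setattr__(
                    self, "term_lengths", tuple(self.term_lengths[i] for i in keep)
                )
        if self.term_lengths is not None and len(self.term_lengths) != len(self.concepts):
            raise ValueError("term_lengths must align with concepts")

    @property
    def key(self) -> SentenceKey:
        return (self.doc_id, self.sent_index)

    @property
    def concept_set(self) -> frozenset[ConceptAnnotation]:
        return frozenset(self.concepts)


class Corpus:
    """An ordered collection of :class:`AnnotatedSentence`, unique by key."""

    def __init__(self, sentences: Iterable[AnnotatedSentence] = ()) -> None:
        self._by_key: dict[SentenceKey, AnnotatedSentence] = {}
        for s in sentences:
            if s.key in self._by_key:
                raise IntegrityError(f"duplicate sentence key {s.key!r}")
            self._by_key[s.key] = s
        self._by_key = dict(sorted(self._by_key.items()))

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[AnnotatedSentence]:
        return iter(self._by_key.values())

    def __contains__(self, key: SentenceKey) -> bool:
        return key in self._by_key

    def __getitem__(self, key: SentenceKey) -> AnnotatedSentence:
        return self._by_key[key]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        if self.keys() != other.keys():
            return False
        for k in self.keys():
            a, b = self[k], other[k]
            if (a.text, a.concept_set, a.term_lengths is None) != (
                b.text, b.concept_set, b.term_lengths is None
            ):
                return False
            if a.term_lengths is not None:
                if sorted(zip(a.concepts, a.term_lengths)) != sorted(
                    zip(b.concepts, b.term_lengths)
                ):
                    return False
        return True

    def keys(self) -> list[SentenceKey]:
        return list(self._by_key)

    def documents(self) -> list[str]:
        """Document identifiers in sorted order."""
        return sorted({d for d, _ in self._by_key})

    def gold_sets(self) -> dict[SentenceKey, frozenset[ConceptAnnotation]]:
        return {k: s.concept_set for k, s in self._by_key.items()}


@dataclass
class SystemRun:
    """One system's predictions over a gold corpus.

    Sentences absent from ``predictions`` are treated as empty prediction
    sets — real systems routinely emit nothing for some sentences.
    """

    system_id: str
    predictions: dict[SentenceKey, frozenset[ConceptAnnotation]] = field(default_factory=dict)

    def get(self, key: SentenceKey) -> frozenset[ConceptAnnotation]:
        return self.predictions.get(key, frozenset())


# ---------------------------------------------------------------------------
# JSONL interchange
# ---------------------------------------------------------------------------

def _parse_concepts(raw: object, path: str, lineno: int) -> tuple[ConceptAnnotation, ...]:
    if not isinstance(raw, list):
        raise ParseError(f"{path}:{lineno}: 'concepts' must be a list")
    out = []
    for c in raw:
        try:
            out.append(ConceptAnnotation(cui=str(c["cui"]), stype=str(c["type"])))
        except (TypeError, KeyError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: bad concept record: {exc}") from exc
    return tuple(out)


def read_jsonl_corpus(path: str | Path, role: str = "gold") -> "Corpus | dict[str, SystemRun]":
    """Read a JSONL corpus file.

    With ``role='gold'`` returns a :class:`Corpus`; with ``role='prediction'``
    returns a mapping ``system_id -> SystemRun`` (one file may interleave
    records of several systems).
    """
    if role not in ("gold", "prediction"):
        raise ValueError(f"unknown role {role!r}")
    path = Path(path)
    sentences: list[AnnotatedSentence] = []
    runs: dict[str, SystemRun] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            try:
                doc, sent = str(rec["doc"]), int(rec["sent"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: missing/invalid doc or sent") from exc
            concepts = _parse_concepts(rec.get("concepts", []), str(path), lineno)
            if role == "gold":
                lens = rec.get("lens")
                sentences.append(
                    AnnotatedSentence(
                        doc_id=doc,
                        sent_index=sent,
                        text=str(rec.get("text", "")),
                        concepts=concepts,
                        term_lengths=tuple(int(x) for x in lens) if lens is not None else None,
                    )
                )
            else:
                try:
                    sid = str(rec["system"])
                except KeyError as exc:
                    raise ParseError(f"{path}:{lineno}: prediction record lacks 'system'") from exc
                run = runs.setdefault(sid, SystemRun(system_id=sid))
                key = (doc, sent)
                if key in run.predictions:
                    raise IntegrityError(
                        f"{path}:{lineno}: duplicate key {key!r} for system {sid}"
                    )
                run.predictions[key] = frozenset(concepts)
    if role == "gold":
        return Corpus(sentences)
    return runs


def write_jsonl_corpus(corpus: Corpus, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in corpus:
            rec: dict = {
                "doc": s.doc_id,
                "sent": s.sent_index,
                "text": s.text,
                "concepts": [{"cui": c.cui, "type": c.stype} for c in sorted(s.concepts)],
            }
            if s.term_lengths is not None:
                order = sorted(range(len(s.concepts)), key=lambda i: s.concepts[i])
                rec["lens"] = [s.term_lengths[i] for i in order]
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def write_jsonl_runs(runs: Mapping[str, SystemRun] | Sequence[SystemRun], path: str | Path) -> None:
    if isinstance(runs, Mapping):
        runs = list(runs.values())
    with Path(path).open("w", encoding="utf-8") as fh:
        for run in sorted(runs, key=lambda r: r.system_id):
            for key in sorted(run.predictions):
                doc, sent = key
                fh.write(
                    json.dumps(
                        {
                            "system": run.system_id,
                            "doc": doc,
                            "sent": sent,
                            "concepts": [
                                {"cui": c.cui, "type": c.stype}
                                for c in sorted(run.predictions[key])
                            ],
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Pipe-delimited stand-off
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandoffDialect:
    """Column layout of a pipe-delimited stand-off annotation file."""

    separator: str = "||"
    columns: tuple[str, ...] = ("doc", "sent", "cui", "type")
    comment: str = "#"

    def __post_init__(self) -> None:
        required = {"doc", "sent", "cui", "type"}
        if set(self.columns) != required:
            raise ValueError(f"columns must be a permutation of {sorted(required)}")


def read_standoff(path: str | Path, dialect: StandoffDialect | None = None) -> Corpus:
    """Read a stand-off file (one annotation per line) into a gold corpus."""
    dialect = dialect or StandoffDialect()
    path = Path(path)
    col = {name: i for i, name in enumerate(dialect.columns)}
    grouped: dict[SentenceKey, list[ConceptAnnotation]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(dialect.comment):
                continue
            fields = line.split(dialect.separator)
            if len(fields) != len(dialect.columns):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(dialect.columns)} fields, got {len(fields)}"
                )
            try:
                key = (fields[col["doc"]], int(fields[col["sent"]]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: sentence index not an integer") from exc
            ann = ConceptAnnotation(cui=fields[col["cui"]], stype=fields[col["type"]])
            grouped.setdefault(key, []).append(ann)
    return Corpus(
        AnnotatedSentence(doc_id=d, sent_index=i, concepts=tuple(cs))
        for (d, i), cs in grouped.items()
    )


def write_standoff(corpus: Corpus, path: str | Path, dialect: StandoffDialect | None = None) -> None:
    dialect = dialect or StandoffDialect()
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in corpus:
            for c in sorted(s.concepts):
                values = {"doc": s.doc_id, "sent": str(s.sent_index), "cui": c.cui, "type": c.stype}
                fh.write(dialect.separator.join(values[n] for n in dialect.columns) + "\n")


# ---------------------------------------------------------------------------
# Filtering and statistics
# ---------------------------------------------------------------------------

def filter_types(
    corpus: Corpus, inventory: Sequence[str] = DEFAULT_TYPE_INVENTORY
) -> Corpus:
    """Drop annotations whose semantic type is outside ``inventory``.

    Sentences whose concept set becomes empty are retained with empty sets, so
    the sentence key space (and hence evaluation denominators) is unchanged.
    Idempotent by construction.
    """
    allowed = set(inventory)
    out = []
    for s in corpus:
        keep = [i for i, c in enumerate(s.concepts) if c.stype in allowed]
        out.append(
            AnnotatedSentence(
                doc_id=s.doc_id,
                sent_index=s.sent_index,
                text=s.text,
                concepts=tuple(s.concepts[i] for i in keep),
                term_lengths=tuple(s.term_lengths[i] for i in keep)
                if s.term_lengths is not None
                else None,
            )
        )
    return Corpus(out)


def filter_run_types(run: SystemRun, inventory: Sequence[str] = DEFAULT_TYPE_INVENTORY) -> SystemRun:
    """Same semantic-type filter, applied to a system run."""
    allowed = set(inventory)
    return SystemRun(
        system_id=run.system_id,
        predictions={
            k: frozenset(c for c in v if c.stype in allowed)
            for k, v in run.predictions.items()
        },
    )


def corpus_stats(
    corpus: Corpus, inventory: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-semantic-type corpus statistics.

    Returns a DataFrame indexed by semantic type with columns ``freq`` (number
    of annotation instances, one per sentence occurrence), ``unique`` (number
    of distinct CUIs of that type) and ``avg_term_length`` (mean surface
    length in tokens over annotations carrying a recorded length; NaN where no
    lengths are available).  Types are ordered by descending frequency, with
    an explicit ``inventory`` ordering honoured if given.
    """
    freq: Counter[str] = Counter()
    cuis: dict[str, set[str]] = {}
    len_sum: Counter[str] = Counter()
    len_n: Counter[str] = Counter()
    for s in corpus:
        lengths = s.term_lengths
        for i, c in enumerate(s.concepts):
            freq[c.stype] += 1
            cuis.setdefault(c.stype, set()).add(c.cui)
            if lengths is not None:
                len_sum[c.stype] += lengths[i]
                len_n[c.stype] += 1
    if inventory is None:
        types = sorted(freq, key=lambda t: (-freq[t], t))
    else:
        types = list(inventory)
    rows = []
    for t in types:
        rows.append(
            {
                "freq": freq.get(t, 0),
                "unique": len(cuis.get(t, ())),
                "avg_term_length": (len_sum[t] / len_n[t]) if len_n.get(t) else float("nan"),
            }
        )
    return pd.DataFrame(rows, index=pd.Index(types, name="stype"))
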