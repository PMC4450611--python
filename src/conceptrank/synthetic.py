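"""Synthetic gold corpora and correlated multi-system predictions.

The real study data — clinical notes with sentence-level (CUI, semantic type)
annotations and the outputs of nine black-box concept recognisers — is access
restricted.  This module generates a stand-in with the statistical structure
the ensemble exploits:

* ten disorder semantic types with heavily skewed frequencies and per-type
  catalogue sizes matching the published corpus profile (T047 dominating,
  T020 rare);
* concept surface forms of 1–4 tokens whose tokens also appear in the
  sentence text, so sentence bag-of-words features carry signal;
* nine simulated systems with heterogeneous per-type sensitivity and
  false-positive profiles, including near-clone variants, one high-recall /
  low-precision system and one high-precision system, mirroring the
  qualitative spread of real off-the-shelf annotators;
* *context rules*: some systems get a sensitivity boost on sentences
  containing a marker token, making different systems the best choice on
  different, textually identifiable subsets — the signal a learn-to-rank
  ensemble must pick up to beat every stand-alone system.

The noise model is deliberately simple — independent Bernoulli recovery of
gold concepts plus Poisson spurious suggestions drawn within-type from the
concept catalogue — and is our own construction; it reproduces the
precision/recall asymmetries of real systems, not their linguistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import (
    DEFAULT_TYPE_INVENTORY,
    AnnotatedSentence,
    ConceptAnnotation,
    Corpus,
    SystemRun,
)

__all__ = [
    "DEFAULT_TYPE_WEIGHTS",
    "DEFAULT_TYPE_UNIQUE",
    "SimulationConfig",
    "SystemProfile",
    "ConceptCatalog",
    "build_catalog",
    "generate_gold",
    "generate_run",
    "preset_profiles",
    "preset_suite",
    "planted_utility_instances",
    "SuiteBundle",
]

#: Per-type annotation frequencies of the reference training corpus profile.
DEFAULT_TYPE_WEIGHTS: dict[str, int] = {
    "T047": 1803, "T184": 842, "T046": 518, "T037": 213, "T019": 184,
    "T190": 103, "T191": 92, "T048": 84, "T033": 45, "T020": 40,
}

#: Distinct CUIs per type in the same profile.
DEFAULT_TYPE_UNIQUE: dict[str, int] = {
    "T047": 410, "T184": 163, "T046": 133, "T037": 96, "T019": 25,
    "T190": 36, "T191": 49, "T048": 32, "T033": 15, "T020": 17,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions emulated."""

    seed: int = 0
    n_documents: int = 60
    sentences_per_document: tuple[int, int] = (4, 8)       # inclusive range
    type_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_WEIGHTS)
    )
    type_unique: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_UNIQUE)
    )
    #: P(k concepts in a sentence) for k = 0, 1, 2, ...
    concepts_per_sentence: tuple[float, ...] = (0.30, 0.38, 0.20, 0.08, 0.04)
    label_length_range: tuple[int, int] = (1, 4)           # tokens, inclusive
    tokens_per_type: int = 60        # size of each type's label-token pool
    background_vocab_size: int = 150
    background_tokens_per_sentence: tuple[int, int] = (2, 5)
    #: Marker tokens and their sentence probabilities (at most one marker per
    #: sentence; the remainder is marker-free).
    marker_probs: Mapping[str, float] = field(
        default_factory=lambda: {"alpha": 0.3, "beta": 0.3}
    )

    def __post_init__(self) -> None:
        w = list(self.type_weights.values())
        if any(x < 0 for x in w) or not any(x > 0 for x in w):
            raise ValueError("type weights must be non-negative, not all zero")
        if abs(sum(self.concepts_per_sentence) - 1.0) > 1e-9:
            raise ValueError("concepts_per_sentence must sum to 1")
        lo, hi = self.label_length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid label_length_range")
        if sum(self.marker_probs.values()) > 1.0 + 1e-9:
            raise ValueError("marker probabilities must sum to at most 1")


@dataclass(frozen=True)
class SystemProfile:
    """Behaviour of one simulated annotation system.

    ``sensitivity`` is the probability that a gold concept of a type is
    recovered; ``fp_rate`` the expected number of spurious concepts per
    sentence (spread over types proportionally to the type weights).  When
    ``marker`` occurs among the sentence tokens, the sensitivity is multiplied
    by ``marker_multiplier`` and clamped to [0, 1].
    """

    system_id: str
    sensitivity: float | Mapping[str, float] = 0.5
    fp_rate: float | Mapping[str, float] = 0.1
    marker: str | None = None
    marker_multiplier: float = 1.0

    def type_sensitivity(self, stype: str, has_marker: bool) -> float:
        base = (
            self.sensitivity.get(stype, 0.0)
            if isinstance(self.sensitivity, Mapping)
            else self.sensitivity
        )
        if has_marker:
            base *= self.marker_multiplier
        return min(max(base, 0.0), 1.0)

    def type_fp_rate(self, stype: str, weight_share: float) -> float:
        if isinstance(self.fp_rate, Mapping):
            return max(self.fp_rate.get(stype, 0.0), 0.0)
        return max(self.fp_rate, 0.0) * weight_share


@dataclass(frozen=True)
class ConceptCatalog:
    """Per-type CUI inventories with generated surface labels."""

    entries: Mapping[str, tuple[tuple[str, tuple[str, ...]], ...]]  # stype -> ((cui, tokens), ...)

    def cuis(self, stype: str) -> list[str]:
        return [cui for cui, _ in self.entries.get(stype, ())]

    def label(self, stype: str, cui: str) -> tuple[str, ...]:
        for c, toks in self.entries.get(stype, ()):
            if c == cui:
                return toks
        return ()


def build_catalog(config: SimulationConfig) -> ConceptCatalog:
    """Deterministic per-type CUI catalogue with 1–4 token labels.

    Derived from the config seed only, so gold corpora and system runs drawn
    with different seeds share one concept universe.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x0C47]))
    lo, hi = config.label_length_range
    entries: dict[str, tuple[tuple[str, tuple[str, ...]], ...]] = {}
    serial = 0
    for t_index, stype in enumerate(sorted(config.type_unique)):
        pool = [f"{stype.lower()}w{j:03d}" for j in range(config.tokens_per_type)]
        items = []
        for _ in range(config.type_unique[stype]):
            serial += 1
            cui = f"C{serial:07d}"
            length = int(rng.integers(lo, hi + 1))
            toks = tuple(pool[i] for i in rng.choice(len(pool), size=length, replace=True))
            items.append((cui, toks))
        entries[stype] = tuple(items)
    return ConceptCatalog(entries=entries)


def generate_gold(config: SimulationConfig, catalog: ConceptCatalog | None = None) -> Corpus:
    """Sample a gold corpus under the configured study conditions."""
    catalog = catalog or build_catalog(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x601D]))
    types = [t for t in config.type_weights if config.type_weights[t] > 0]
    weights = np.array([config.type_weights[t] for t in types], dtype=float)
    probs = weights / weights.sum()
    markers = list(config.marker_probs)
    marker_p = [config.marker_probs[m] for m in markers] + [
        1.0 - sum(config.marker_probs.values())
    ]
    bg_vocab = [f"bg{j:03d}" for j in range(config.background_vocab_size)]
    count_probs = np.array(config.concepts_per_sentence)

    sentences = []
    lo_s, hi_s = config.sentences_per_document
    lo_b, hi_b = config.background_tokens_per_sentence
    for d in range(config.n_documents):
        doc_id = f"doc{d:03d}"
        n_sent = int(rng.integers(lo_s, hi_s + 1))
        for si in range(n_sent):
            m_idx = int(rng.choice(len(markers) + 1, p=marker_p))
            marker = markers[m_idx] if m_idx < len(markers) else None
            n_concepts = int(rng.choice(len(count_probs), p=count_probs))
            concepts: list[ConceptAnnotation] = []
            lengths: list[int] = []
            tokens: list[str] = []
            chosen: set[tuple[str, str]] = set()
            for _ in range(n_concepts):
                stype = types[int(rng.choice(len(types), p=probs))]
                cuis = catalog.cuis(stype)
                cui = cuis[int(rng.integers(len(cuis)))]
                if (cui, stype) in chosen:
                    continue  # duplicate draw collapses, like real set semantics
                chosen.add((cui, stype))
                label = catalog.label(stype, cui)
                concepts.append(ConceptAnnotation(cui=cui, stype=stype))
                lengths.append(len(label))
                tokens.extend(label)
            if marker is not None:
                tokens.append(marker)
            n_bg = int(rng.integers(lo_b, hi_b + 1))
            tokens.extend(bg_vocab[i] for i in rng.integers(len(bg_vocab), size=n_bg))
            sentences.append(
                AnnotatedSentence(
                    doc_id=doc_id,
                    sent_index=si,
                    text=" ".join(tokens),
                    concepts=tuple(concepts),
                    term_lengths=tuple(lengths),
                )
            )
    return Corpus(sentences)


def generate_run(
    gold: Corpus,
    profile: SystemProfile,
    seed: int,
    catalog: ConceptCatalog | None = None,
    config: SimulationConfig | None = None,
) -> SystemRun:
    """Simulate one system's predictions over a gold corpus.

    Each gold concept is recovered independently with the profile's effective
    per-type sensitivity (context rule applied when the marker token occurs in
    the sentence text); spurious concepts are added per type with a Poisson
    count at the profile's rate, sampled from the catalogue excluding that
    sentence's gold concepts of the type.  Without an explicit catalogue the
    concept universe observed in the gold corpus is used.
    """
    config = config or SimulationConfig()
    if catalog is None:
        observed: dict[str, dict[str, tuple[str, ...]]] = {}
        for s in gold:
            for c in s.concepts:
                observed.setdefault(c.stype, {})[c.cui] = ()
        catalog = ConceptCatalog(
            entries={t: tuple(sorted(d.items())) for t, d in observed.items()}
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E5]))
    weights = {t: float(w) for t, w in config.type_weights.items()}
    total_w = sum(weights.values())
    run = SystemRun(system_id=profile.system_id)
    for s in gold:
        toks = set(s.text.split())
        has_marker = profile.marker is not None and profile.marker in toks
        pred: set[ConceptAnnotation] = set()
        for c in s.concepts:
            if rng.random() < profile.type_sensitivity(c.stype, has_marker):
                pred.add(c)
        gold_by_type: dict[str, set[str]] = {}
        for c in s.concepts:
            gold_by_type.setdefault(c.stype, set()).add(c.cui)
        for stype in sorted(catalog.entries):
            rate = profile.type_fp_rate(stype, weights.get(stype, 0.0) / total_w)
            if rate <= 0:
                continue
            k = int(rng.poisson(rate))
            if k == 0:
                continue
            pool = [c for c in catalog.cuis(stype) if c not in gold_by_type.get(stype, ())]
            if not pool:
                continue
            for i in rng.choice(len(pool), size=min(k, len(pool)), replace=False):
                pred.add(ConceptAnnotation(cui=pool[int(i)], stype=stype))
        run.predictions[s.key] = frozenset(pred)
    return run


def preset_profiles() -> list[SystemProfile]:
    """Nine profiles mirroring the qualitative spread of real base systems.

    M3 is the strong high-recall / low-precision system; M5 the high-precision
    one; M2 is weak; M4/M6–M9 are near-clones of a moderate mid-field system.
    M1 and M5 carry complementary context rules: M1 excels on sentences with
    the ``alpha`` marker, M5 on sentences with ``beta``.
    """
    return [
        SystemProfile("M1", sensitivity=0.25, fp_rate=0.20, marker="alpha", marker_multiplier=3.2),
        SystemProfile("M2", sensitivity=0.05, fp_rate=0.30),
        SystemProfile("M3", sensitivity=0.62, fp_rate=2.00),
        SystemProfile("M4", sensitivity=0.35, fp_rate=0.08),
        SystemProfile("M5", sensitivity=0.25, fp_rate=0.05, marker="beta", marker_multiplier=3.2),
        SystemProfile("M6", sensitivity=0.34, fp_rate=0.08),
        SystemProfile("M7", sensitivity=0.36, fp_rate=0.08),
        SystemProfile("M8", sensitivity=0.35, fp_rate=0.09),
        SystemProfile("M9", sensitivity=0.35, fp_rate=0.08),  # near-clone of M4
    ]


def planted_utility_instances(
    n_instances: int,
    n_systems: int,
    dim: int,
    seed: int,
    w_star: "np.ndarray | None" = None,
) -> "tuple[list, np.ndarray]":
    """Ranking instances whose relevance follows a planted linear utility.

    Feature vectors are standard normal; within each instance the systems'
    relevance is the dense rank of ``w_star . x``.  A ranker that recovers the
    utility direction orders held-out instances perfectly, which makes these
    instances the canonical diagnostic for the pairwise rankers.
    """
    from .features import FeatureVector, Instance, make_rank_labels

    rng = np.random.default_rng(seed)
    if w_star is None:
        w_star = rng.normal(size=dim)
    instances = []
    for n in range(n_instances):
        X = rng.normal(size=(n_systems, dim))
        util = X @ w_star
        f1s = {f"S{j}": float(util[j]) for j in range(n_systems)}
        vectors = {
            f"S{j}": FeatureVector(
                key=(f"d{n}", 0),
                system_id=f"S{j}",
                feats={i: float(X[j, i]) for i in range(dim)},
            )
            for j in range(n_systems)
        }
        instances.append(
            Instance(key=(f"d{n}", 0), vectors=vectors, labels=make_rank_labels(f1s))
        )
    return instances, w_star


@dataclass
class SuiteBundle:
    config: SimulationConfig
    catalog: ConceptCatalog
    gold: Corpus
    runs: dict[str, SystemRun]
    profiles: list[SystemProfile]


def preset_suite(seed: int, config: SimulationConfig | None = None) -> SuiteBundle:
    """Deterministic (gold, 9 runs) bundle for ensemble experiments."""
    config = replace(config, seed=seed) if config is not None else SimulationConfig(seed=seed)
    catalog = build_catalog(config)
    gold = generate_gold(config, catalog)
    profiles = preset_profiles()
    runs = {}
    for i, prof in enumerate(profiles):
        run_seed = int(np.random.SeedSequence([seed, 0x2B5, i]).generate_state(1)[0] % (2**31))
        runs[prof.system_id] = generate_run(gold, prof, run_seed, catalog=catalog, config=config)
    return SuiteBundle(config=config, catalog=catalog, gold=gold, runs=runs, profiles=profiles)
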