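import numpy as np
import pytest

from conceptrank.corpus_io import AnnotatedSentence, ConceptAnnotation, Corpus, SystemRun
from conceptrank.ensemble import (
    ConfigError,
    EnsembleConfig,
    EnsembleResult,
    RankedSystem,
    SentenceOutcome,
    apply_model,
    combine_oracle,
    combine_union,
    contributions,
    cross_validate,
    rank_instance,
    select_topk,
    _fold_partition,
)
from conceptrank.evaluation import aggregate_overall, sentence_f1
from conceptrank.features import FeatureSpace, FeatureVector, Vocabulary, build_training_set
from conceptrank.rankers import RankerConfig, RankModel, train

C = ConceptAnnotation


def linear_model(w):
    return RankModel("hinge_svm", dim=len(w), params={"w": np.asarray(w, float)},
                     config=RankerConfig(kind="hinge_svm"))


def vectors_for(scores):
    """One 1-D feature whose value equals the desired score under w=[1]."""
    return {s: FeatureVector(("d", 0), s, {0: float(v)}) for s, v in scores.items()}


class TestRankInstance:
    def test_exact_tie_shares_dense_rank(self):
        ranking = rank_instance(linear_model([1.0]),
                                vectors_for({"A": 0.9, "B": 0.9, "C": 0.3}),
                                systems=("A", "B", "C"))
        assert {r.system_id: r.dense_rank for r in ranking} == {"A": 1, "B": 1, "C": 2}

    def test_distinct_scores_rank_in_order(self):
        ranking = rank_instance(linear_model([1.0]),
                                vectors_for({"A": 0.1, "B": 0.5, "C": 0.3}),
                                systems=("A", "B", "C"))
        assert [r.system_id for r in ranking] == ["B", "C", "A"]
        assert [r.dense_rank for r in ranking] == [1, 2, 3]

    def test_epsilon_chaining(self):
        ranking = rank_instance(linear_model([1.0]),
                                vectors_for({"A": 0.5, "B": 0.5 + 1e-12, "C": 0.1}),
                                systems=("A", "B", "C"))
        ranks = {r.system_id: r.dense_rank for r in ranking}
        assert ranks["A"] == ranks["B"] == 1 and ranks["C"] == 2

    def test_secondary_order_is_registry_index(self):
        ranking = rank_instance(linear_model([1.0]),
                                vectors_for({"B": 0.5, "A": 0.5}),
                                systems=("A", "B"))
        assert [r.system_id for r in ranking] == ["A", "B"]


class TestSelectTopK:
    def test_shared_first_rank(self):
        ranking = (RankedSystem("A", 0.9, 1), RankedSystem("B", 0.9, 1),
                   RankedSystem("C", 0.3, 2))
        assert select_topk(ranking, 1) == {"A", "B"}

    def test_k_covers_all_distinct_ranks(self):
        ranking = tuple(RankedSystem(f"S{i}", 1.0 - i / 10, i + 1) for i in range(9))
        assert select_topk(ranking, 2) == {"S0", "S1"}
        assert select_topk(ranking, 9) == {f"S{i}" for i in range(9)}

    def test_out_of_range_k(self):
        ranking = (RankedSystem("A", 1.0, 1),)
        with pytest.raises(ConfigError):
            select_topk(ranking, 0)
        with pytest.raises(ConfigError):
            select_topk(ranking, 2)


class TestCombine:
    def test_union_merges_sets(self):
        preds = {"A": {C("C1", "T047")}, "B": {C("C1", "T047"), C("C2", "T184")}}
        assert combine_union({"A", "B"}, preds) == {C("C1", "T047"), C("C2", "T184")}

    def test_single_selected_system_unchanged(self):
        preds = {"A": {C("C1", "T047")}, "B": {C("C2", "T184")}}
        assert combine_union({"A"}, preds) == {C("C1", "T047")}

    def test_union_of_empties(self):
        assert combine_union({"A", "B"}, {"A": set(), "B": set()}) == frozenset()

    def test_oracle_argmax(self):
        gold = {C("C1", "T047"), C("C2", "T047")}
        preds = {"A": {C("C1", "T047"), C("C9", "T047"), C("C8", "T047")},
                 "B": {C("C1", "T047")}}
        chosen, out = combine_oracle({"A", "B"}, preds, gold, systems=("A", "B"))
        assert chosen == "B"  # F1 2/3 beats 2/5

    def test_oracle_tie_prefers_lowest_registry(self):
        gold = {C("C1", "T047")}
        preds = {"A": {C("C1", "T047")}, "B": {C("C1", "T047")}}
        chosen, _ = combine_oracle({"A", "B"}, preds, gold, systems=("A", "B"))
        assert chosen == "A"

    def test_oracle_full_pool_attains_max_f1(self, suite0):
        systems = sorted(suite0.runs)
        for s in list(suite0.gold)[:40]:
            preds = {sid: suite0.runs[sid].get(s.key) for sid in systems}
            _, out = combine_oracle(set(systems), preds, s.concept_set, systems=systems)
            best = max(sentence_f1(preds[sid], s.concept_set) for sid in systems)
            assert sentence_f1(out, s.concept_set) == best


class TestContributions:
    @staticmethod
    def result_from(outcomes, strategy="union"):
        res = EnsembleResult(config=EnsembleConfig(strategy=strategy))
        res.outcomes = outcomes
        return res

    def test_oracle_single_winner(self):
        outcomes = {
            ("d", i): SentenceOutcome(("d", i), (), frozenset({"A"}), frozenset(), chosen="A")
            for i in range(4)
        }
        contrib = contributions(self.result_from(outcomes, "oracle"), systems=("A", "B"))
        assert contrib == {"A": 1.0, "B": 0.0}

    def test_union_tied_pair_sums_to_two(self):
        outcomes = {
            ("d", i): SentenceOutcome(("d", i), (), frozenset({"A", "B"}), frozenset())
            for i in range(4)
        }
        contrib = contributions(self.result_from(outcomes), systems=("A", "B"))
        assert contrib == {"A": 1.0, "B": 1.0}

    def test_matches_independent_tally(self, suite0, trained_suite0):
        space, _, model = trained_suite0
        runs = list(suite0.runs.values())
        res = apply_model(model, space, suite0.gold, runs, EnsembleConfig(top_k=2))
        contrib = contributions(res, systems=space.systems)
        n = len(res.outcomes)
        for sid in space.systems:
            manual = sum(1 for o in res.outcomes.values() if sid in o.selected) / n
            assert contrib[sid] == manual

    def test_oracle_contributions_sum_to_one(self, suite0, trained_suite0):
        space, _, model = trained_suite0
        runs = list(suite0.runs.values())
        res = apply_model(model, space, suite0.gold, runs,
                          EnsembleConfig(top_k=3, strategy="oracle"))
        total = sum(contributions(res, systems=space.systems).values())
        assert abs(total - 1.0) < 1e-9


class TestStrategyEquivalence:
    def test_union_equals_oracle_without_rank1_tie(self, suite0, trained_suite0):
        space, _, model = trained_suite0
        runs = list(suite0.runs.values())
        u = apply_model(model, space, suite0.gold, runs, EnsembleConfig(top_k=1))
        o = apply_model(model, space, suite0.gold, runs,
                        EnsembleConfig(top_k=1, strategy="oracle"))
        for key, ou in u.outcomes.items():
            if len(ou.selected) == 1:
                assert ou.combined == o.outcomes[key].combined


class TestCrossValidation:
    def test_fold_partition_disjoint_exhaustive_and_sized(self):
        docs = [f"doc{i}" for i in range(23)]
        parts = _fold_partition(docs, 10, seed=3)
        sizes = sorted(len(p) for p in parts)
        assert sizes == [2] * 7 + [3] * 3  # first n mod folds get the extra
        flat = [d for p in parts for d in p]
        assert sorted(flat) == sorted(docs)

    def test_same_seed_same_partition(self):
        docs = [f"doc{i}" for i in range(15)]
        assert _fold_partition(docs, 5, seed=9) == _fold_partition(docs, 5, seed=9)

    def test_fewer_documents_than_folds(self, tiny_gold, tiny_runs):
        with pytest.raises(ConfigError):
            cross_validate(tiny_gold, tiny_runs,
                           ranker_config=RankerConfig(kind="hinge_svm"),
                           blocks=("FB1", "FB2"), systems=("M1", "M2"), folds=10)

    def test_two_folds_equal_manual_concatenation(self, suite0):
        docs = suite0.gold.documents()[:4]
        keep = set(docs)
        gold = Corpus([s for s in suite0.gold if s.doc_id in keep])
        runs = list(suite0.runs.values())
        cfg = RankerConfig(kind="hinge_svm", seed=0, epochs=20)
        res = cross_validate(gold, runs, ranker_config=cfg,
                             blocks=("FB1", "FB2"), folds=2, seed=5)
        # Manual re-run: same partition, same training, concatenated predictions
        parts = _fold_partition(docs, 2, seed=5)
        manual = {}
        for held in parts:
            held_set = set(held)
            train_corpus = Corpus([s for s in gold if s.doc_id not in held_set])
            test_corpus = Corpus([s for s in gold if s.doc_id in held_set])
            space = FeatureSpace(blocks=("FB1", "FB2"))
            instances = build_training_set(train_corpus, runs, space)
            model = train(cfg, instances, dim=space.dim, systems=list(space.systems))
            out = apply_model(model, space, test_corpus, runs, EnsembleConfig())
            manual.update(out.predictions())
        assert manual == res.predictions
        assert aggregate_overall(gold, manual).f1 == res.pooled.f1
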