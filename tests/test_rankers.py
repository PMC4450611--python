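import numpy as np
import pytest

from conceptrank.features import FeatureVector, Instance, make_rank_labels
from conceptrank.rankers import (
    RankerConfig,
    RankModel,
    TrainingError,
    instances_to_arrays,
    listnet_loss_grad,
    pairwise_error,
    rankboost_candidates,
    train,
)

from conftest import make_planted_instances


def one_d_instances(n=20):
    """Relevance strictly increasing with the single feature."""
    instances = []
    rng = np.random.default_rng(7)
    for k in range(n):
        vals = rng.permutation([0.0, 1.0, 2.0])
        f1s = {f"S{j}": float(vals[j]) / 2 for j in range(3)}
        vectors = {
            f"S{j}": FeatureVector((f"d{k}", 0), f"S{j}", {0: float(vals[j])})
            for j in range(3)
        }
        instances.append(Instance((f"d{k}", 0), vectors, make_rank_labels(f1s)))
    return instances


class TestScoring:
    def test_zero_model_scores_zero(self):
        m = RankModel("hinge_svm", dim=3, params={"w": np.zeros(3)},
                      config=RankerConfig(kind="hinge_svm"))
        assert m.score_vector(FeatureVector(("d", 0), "M1", {0: 5.0})) == 0.0

    def test_linear_dot_product(self):
        m = RankModel("hinge_svm", dim=2, params={"w": np.array([1.0, -2.0])},
                      config=RankerConfig(kind="hinge_svm"))
        assert m.score_vector(FeatureVector(("d", 0), "M1", {0: 3.0, 1: 1.0})) == 1.0

    def test_out_of_dim_indices_ignored(self):
        m = RankModel("hinge_svm", dim=2, params={"w": np.array([1.0, 1.0])},
                      config=RankerConfig(kind="hinge_svm"))
        assert m.score_vector(FeatureVector(("d", 0), "M1", {0: 1.0, 7: 9.0})) == 1.0

    def test_ranknet_equal_vectors_give_pair_probability_half(self):
        instances = one_d_instances(5)
        m = train(RankerConfig(kind="ranknet", seed=0, epochs=2), instances)
        fv = FeatureVector(("d", 0), "S0", {0: 1.5})
        s1, s2 = m.score_vector(fv), m.score_vector(fv)
        assert 1.0 / (1.0 + np.exp(-(s1 - s2))) == 0.5


class TestHinge:
    def test_separable_1d_learns_positive_weight(self):
        train_set = one_d_instances(20)
        held_out = one_d_instances(10)
        m = train(RankerConfig(kind="hinge_svm", seed=0), train_set)
        assert m.params["w"][0] > 0
        assert pairwise_error(m, held_out) == 0.0

    def test_planted_utility_recovery(self):
        instances, w_star = make_planted_instances(60, 9, 10, seed=1)
        held, _ = make_planted_instances(30, 9, 10, seed=2, w_star=w_star)
        m = train(RankerConfig(kind="hinge_svm", seed=0), instances)
        assert pairwise_error(m, held) <= 0.05

    def test_no_valid_pairs_is_an_error(self):
        vectors = {"A": FeatureVector(("d", 0), "A", {0: 1.0}),
                   "B": FeatureVector(("d", 0), "B", {0: 2.0})}
        flat = [Instance(("d", 0), vectors, make_rank_labels({"A": 0.5, "B": 0.5}))]
        with pytest.raises(TrainingError):
            train(RankerConfig(kind="hinge_svm"), flat)


class TestListNet:
    def test_single_system_instance_contributes_zero_loss(self):
        inst = Instance(("d", 0),
                        {"A": FeatureVector(("d", 0), "A", {0: 2.0})},
                        make_rank_labels({"A": 0.7}))
        X, rel, _ = instances_to_arrays([inst], dim=1)
        loss, _ = listnet_loss_grad(np.array([3.0]), X, rel)
        assert abs(loss) < 1e-12  # softmax of one element is a point mass

    def test_analytic_gradient_matches_central_differences(self):
        rng = np.random.default_rng(0)
        instances, _ = make_planted_instances(5, 3, 4, seed=3)
        X, rel, _ = instances_to_arrays(instances, dim=4)
        w = rng.normal(size=4)
        _, grad = listnet_loss_grad(w, X, rel)
        h = 1e-6
        for i in range(4):
            e = np.zeros(4)
            e[i] = h
            num = (listnet_loss_grad(w + e, X, rel)[0]
                   - listnet_loss_grad(w - e, X, rel)[0]) / (2 * h)
            assert abs(grad[i] - num) <= 1e-5 * max(1.0, abs(num))

    def test_loss_decreases_on_separable_toy_set(self):
        m = train(RankerConfig(kind="listnet", seed=0), one_d_instances(10))
        assert m.loss_trace[-1] < m.loss_trace[0]


class TestRankNet:
    def test_loss_decreases_on_separable_toy_set(self):
        m = train(RankerConfig(kind="ranknet", seed=0), one_d_instances(10))
        assert m.loss_trace[-1] < m.loss_trace[0]


class TestRankBoost:
    def test_round_one_matches_exhaustive_enumeration(self):
        instances, _ = make_planted_instances(20, 3, 5, seed=11)
        X, rel, _ = instances_to_arrays(instances, dim=5)
        n_inst, n_sys, d = X.shape
        Xf = X.reshape(-1, d)
        # Brute-force oracle: uniform distribution over discordant pairs,
        # evaluate every candidate (feature, threshold) directly.
        pairs = []
        for n in range(n_inst):
            for i in range(n_sys):
                for j in range(n_sys):
                    if rel[n, i] > rel[n, j]:
                        pairs.append((n * n_sys + i, n * n_sys + j))
        cands = rankboost_candidates(Xf, 10)
        best_k, best_r = 0, -1.0
        for k, (f, theta) in enumerate(cands):
            r = sum(
                int(Xf[a, f] > theta) - int(Xf[b, f] > theta) for a, b in pairs
            ) / len(pairs)
            if abs(r) > best_r:
                best_k, best_r = k, abs(r)
        m = train(RankerConfig(kind="rankboost", rounds=1), instances)
        f0, theta0, _ = m.params["weak"][0]
        assert (f0, theta0) == cands[best_k]

    def test_loss_bound_monotone_and_error_decreases(self):
        # The quantity boosting provably drives down is the exponential bound
        # prod_t Z_t on the ranking loss: every per-round normaliser Z_t <= 1.
        # The raw 0-1 pairwise error fluctuates round to round but must end
        # far below where it started.
        instances, _ = make_planted_instances(30, 5, 6, seed=4)
        full = train(RankerConfig(kind="rankboost", rounds=50), instances)
        assert all(z <= 1.0 + 1e-12 for z in full.loss_trace)
        first = RankModel("rankboost", dim=full.dim,
                          params={"weak": full.params["weak"][:1]}, config=full.config)
        assert pairwise_error(full, instances) < pairwise_error(first, instances)
        assert pairwise_error(full, instances) < 0.5


class TestPairwiseError:
    def test_perfect_and_constant_models(self):
        instances = one_d_instances(10)
        perfect = RankModel("hinge_svm", dim=1, params={"w": np.array([1.0])},
                            config=RankerConfig(kind="hinge_svm"))
        constant = RankModel("hinge_svm", dim=1, params={"w": np.array([0.0])},
                             config=RankerConfig(kind="hinge_svm"))
        assert pairwise_error(perfect, instances) == 0.0
        assert pairwise_error(constant, instances) == 0.5

    def test_model_uninformative_of_labels_scores_near_half(self):
        # Relevance drawn independently of the features: any fixed scorer
        # should sit at chance level over many pairs.
        rng = np.random.default_rng(5)
        instances = []
        for n in range(300):
            f1s = {f"S{j}": float(rng.random()) for j in range(9)}
            vectors = {
                f"S{j}": FeatureVector(
                    (f"d{n}", 0), f"S{j}", {i: float(rng.normal()) for i in range(6)}
                )
                for j in range(9)
            }
            instances.append(Instance((f"d{n}", 0), vectors, make_rank_labels(f1s)))
        model = RankModel("hinge_svm", dim=6, params={"w": rng.normal(size=6)},
                          config=RankerConfig(kind="hinge_svm"))
        assert abs(pairwise_error(model, instances) - 0.5) < 0.05


class TestDeterminismAndSerialization:
    @pytest.mark.parametrize("kind", ["hinge_svm", "ranknet", "rankboost", "listnet"])
    def test_identical_seed_gives_byte_identical_model(self, kind, tmp_path):
        instances, _ = make_planted_instances(15, 4, 5, seed=9)
        cfg = RankerConfig(kind=kind, seed=3, epochs=5 if kind != "rankboost" else None,
                           rounds=5)
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        train(cfg, instances).save(a)
        train(cfg, instances).save(b)
        assert a.read_bytes() == b.read_bytes()

    @pytest.mark.parametrize("kind", ["hinge_svm", "ranknet", "rankboost", "listnet"])
    def test_round_trip_preserves_scores(self, kind, tmp_path):
        instances, _ = make_planted_instances(15, 4, 5, seed=9)
        cfg = RankerConfig(kind=kind, seed=3, epochs=5 if kind != "rankboost" else None,
                           rounds=5)
        m = train(cfg, instances)
        m.save(tmp_path / "m.json")
        back = RankModel.load(tmp_path / "m.json")
        fv = FeatureVector(("d", 0), "S0", {0: 0.3, 2: -1.2, 4: 2.0})
        assert back.score_vector(fv) == m.score_vector(fv)

    def test_config_defaults_match_published_settings(self):
        # Default hyperparameters are the documented best settings.
        assert RankerConfig(kind="hinge_svm").C == 30
        rn = RankerConfig(kind="ranknet").resolved()
        assert (rn.epochs, rn.hidden_nodes, rn.learning_rate) == (100, 10, 5e-5)
        rb = RankerConfig(kind="rankboost")
        assert (rb.rounds, rb.threshold_candidates) == (300, 10)
        ln = RankerConfig(kind="listnet").resolved()
        assert (ln.epochs, ln.learning_rate) == (1500, 1e-5)
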