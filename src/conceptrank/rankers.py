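"""From-scratch learn-to-rank models.

Four rankers over per-instance labelled feature vectors, trained to score a
(sentence, system) vector so that within every sentence the better-performing
system scores higher:

* ``hinge_svm`` — pairwise linear ranking with hinge loss, the ranking-SVM
  objective (1/2)||w||^2 + C * sum hinge(1 - w.(x_i - x_j)) over all
  within-instance pairs with rel_i > rel_j.  Optimised by deterministic
  full-batch subgradient descent from zero initialisation on the per-pair
  rescaled objective (lambda = 1/(C n_pairs)) with the diminishing step
  schedule eta_t = eta0 / sqrt(t).
* ``ranknet`` — one-hidden-layer network (sigmoid hidden units, linear
  output) trained with the pairwise logistic loss log(1 + exp(-(s_i - s_j))),
  full-batch gradient descent, seed-controlled uniform(-0.1, 0.1) init.
* ``rankboost`` — additive model over threshold weak rankers
  h(x) = [x_f > theta].  Each round selects, from `threshold_candidates`
  evenly spaced quantile thresholds per feature, the weak ranker maximising
  |r|, r = sum_pairs D(i,j) (h(x_i) - h(x_j)), with the closed-form weight
  alpha = 0.5 ln((1+r)/(1-r)) and the multiplicative distribution update.
* ``listnet`` — linear scorer minimising the listwise top-one-probability
  cross entropy between softmax(scores) and softmax(relevances), full-batch
  gradient descent from zero initialisation.

Pairs are formed only within an instance and only across distinct relevance
levels.  Defaults mirror the settings that worked best in the setting this
package targets (C = 30; RankNet 100 epochs / 10 hidden nodes / lr 5e-5;
RankBoost 300 rounds / 10 threshold candidates; ListNet 1500 epochs /
lr 1e-5).  Objective-level behaviour, not weight-level parity with any
particular released ranking toolkit, is what is promised and tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .features import FeatureSpace, FeatureVector, Instance

__all__ = [
    "RANKER_KINDS",
    "RankerConfig",
    "RankModel",
    "train",
    "score",
    "pairwise_error",
    "instances_to_arrays",
    "listnet_loss_grad",
]

RANKER_KINDS = ("hinge_svm", "ranknet", "rankboost", "listnet")

_KIND_DEFAULTS = {
    "hinge_svm": {"epochs": 200, "learning_rate": 1.0},
    "ranknet": {"epochs": 100, "learning_rate": 5e-5},
    "listnet": {"epochs": 1500, "learning_rate": 1e-5},
    "rankboost": {"epochs": None, "learning_rate": None},
}


class TrainingError(RuntimeError):
    """Raised when a model cannot be trained on the given data."""


class DivergenceError(TrainingError):
    """Raised when training produces a non-finite loss."""


@dataclass(frozen=True)
class RankerConfig:
    """Hyperparameters of one ranker; unset fields take per-kind defaults."""

    kind: str = "hinge_svm"
    C: float = 30.0                      # hinge trade-off (error vs margin)
    epochs: int | None = None            # gradient-descent kinds
    hidden_nodes: int = 10               # ranknet
    learning_rate: float | None = None   # ranknet / listnet
    rounds: int = 300                    # rankboost
    threshold_candidates: int = 10       # rankboost
    seed: int = 0
    scale_features: bool = False         # optional per-feature max scaling

    def __post_init__(self) -> None:
        if self.kind not in RANKER_KINDS:
            raise ValueError(f"unknown ranker kind {self.kind!r}")
        if self.C <= 0 or self.hidden_nodes <= 0 or self.rounds <= 0:
            raise ValueError("C, hidden_nodes and rounds must be positive")
        if self.threshold_candidates <= 0:
            raise ValueError("threshold_candidates must be positive")
        if self.epochs is not None and self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def resolved(self) -> "RankerConfig":
        d = _KIND_DEFAULTS[self.kind]
        out = self
        if out.epochs is None and d["epochs"] is not None:
            out = replace(out, epochs=d["epochs"])
        if out.learning_rate is None and d["learning_rate"] is not None:
            out = replace(out, learning_rate=d["learning_rate"])
        return out

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "C": self.C,
            "epochs": self.epochs,
            "hidden_nodes": self.hidden_nodes,
            "learning_rate": self.learning_rate,
            "rounds": self.rounds,
            "threshold_candidates": self.threshold_candidates,
            "seed": self.seed,
            "scale_features": self.scale_features,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RankerConfig":
        return cls(**dict(d))


@dataclass
class RankModel:
    """A trained ranker: deterministic scorer plus training metadata."""

    kind: str
    dim: int
    params: dict
    config: RankerConfig
    loss_trace: list[float] = field(default_factory=list)
    scale: np.ndarray | None = None  # per-feature divisors when scaling is on

    # -- scoring ------------------------------------------------------------

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Scores for a 2-D array of dense feature rows."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.dim:
            raise ValueError(f"expected dim {self.dim}, got {X.shape[1]}")
        if self.scale is not None:
            X = X / self.scale
        if self.kind in ("hinge_svm", "listnet"):
            return X @ self.params["w"]
        if self.kind == "ranknet":
            z = _sigmoid(X @ self.params["W1"] + self.params["b1"])
            return z @ self.params["W2"] + self.params["b2"]
        if self.kind == "rankboost":
            s = np.zeros(X.shape[0])
            for f, theta, alpha in self.params["weak"]:
                s += alpha * (X[:, int(f)] > theta)
            return s
        raise ValueError(f"unknown kind {self.kind!r}")

    def score_vector(self, fv: FeatureVector) -> float:
        x = np.zeros(self.dim)
        for i, v in fv.feats.items():
            if 0 <= i < self.dim:  # indices beyond training dim are ignored
                x[i] = v
        return float(self.score_matrix(x[None, :])[0])

    # -- serialization ------------------------------------------------------

    def to_json_dict(self) -> dict:
        params: dict
        if self.kind in ("hinge_svm", "listnet"):
            params = {"w": self.params["w"].tolist()}
        elif self.kind == "ranknet":
            params = {
                "W1": self.params["W1"].tolist(),
                "b1": self.params["b1"].tolist(),
                "W2": self.params["W2"].tolist(),
                "b2": float(self.params["b2"]),
            }
        else:
            params = {
                "weak": [[int(f), float(t), float(a)] for f, t, a in self.params["weak"]]
            }
        return {
            "kind": self.kind,
            "config": self.config.to_dict(),
            "dim": self.dim,
            "params": params,
            "loss_trace": self.loss_trace,
            "scale": self.scale.tolist() if self.scale is not None else None,
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "RankModel":
        kind = d["kind"]
        raw = d["params"]
        if kind in ("hinge_svm", "listnet"):
            params = {"w": np.asarray(raw["w"], dtype=float)}
        elif kind == "ranknet":
            params = {
                "W1": np.asarray(raw["W1"], dtype=float),
                "b1": np.asarray(raw["b1"], dtype=float),
                "W2": np.asarray(raw["W2"], dtype=float),
                "b2": float(raw["b2"]),
            }
        elif kind == "rankboost":
            params = {"weak": [(int(f), float(t), float(a)) for f, t, a in raw["weak"]]}
        else:
            raise ValueError(f"unknown kind {kind!r}")
        scale = d.get("scale")
        return cls(
            kind=kind,
            dim=int(d["dim"]),
            params=params,
            config=RankerConfig.from_dict(d["config"]),
            loss_trace=list(d.get("loss_trace", [])),
            scale=np.asarray(scale, dtype=float) if scale is not None else None,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "RankModel":
        return cls.from_json_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# Dense training arrays
# ---------------------------------------------------------------------------

def instances_to_arrays(
    instances: Sequence[Instance],
    dim: int | None = None,
    systems: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack instances into X (n_inst, n_sys, dim) and rel (n_inst, n_sys)."""
    if not instances:
        raise TrainingError("no training instances")
    if systems is None:
        systems = sorted(instances[0].vectors)
    systems = list(systems)
    if dim is None:
        dim = 1 + max(
            (i for inst in instances for fv in inst.vectors.values() for i in fv.feats),
            default=-1,
        )
    X = np.zeros((len(instances), len(systems), dim))
    rel = np.zeros((len(instances), len(systems)))
    for n, inst in enumerate(instances):
        for s, sid in enumerate(systems):
            for i, v in inst.vectors[sid].feats.items():
                if i < dim:
                    X[n, s, i] = v
            rel[n, s] = inst.labels[sid].relevance
    return X, rel, systems


def _pair_indices(rel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flattened indices (a, b) of within-instance pairs with rel_a > rel_b."""
    n_inst, n_sys = rel.shape
    ai, bi = [], []
    for n in range(n_inst):
        for i in range(n_sys):
            for j in range(n_sys):
                if rel[n, i] > rel[n, j]:
                    ai.append(n * n_sys + i)
                    bi.append(n * n_sys + j)
    return np.asarray(ai, dtype=np.intp), np.asarray(bi, dtype=np.intp)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(
    config: RankerConfig,
    instances: Sequence[Instance],
    dim: int | None = None,
    systems: Sequence[str] | None = None,
) -> RankModel:
    """Train a ranker of ``config.kind`` on labelled instances."""
    config = config.resolved()
    X, rel, _ = instances_to_arrays(instances, dim=dim, systems=systems)
    n_inst, n_sys, d = X.shape
    Xf = X.reshape(n_inst * n_sys, d)
    scale = None
    if config.scale_features:
        scale = np.abs(Xf).max(axis=0)
        scale[scale == 0] = 1.0
        Xf = Xf / scale

    if config.kind == "listnet":
        model = _train_listnet(config, Xf.reshape(n_inst, n_sys, d), rel)
    else:
        ai, bi = _pair_indices(rel)
        if ai.size == 0:
            raise TrainingError(
                "no within-instance pairs with distinct relevance; "
                "pairwise rankers need at least one"
            )
        if config.kind == "hinge_svm":
            model = _train_hinge(config, Xf, ai, bi)
        elif config.kind == "ranknet":
            model = _train_ranknet(config, Xf, ai, bi)
        else:
            model = _train_rankboost(config, Xf, ai, bi)
    model.scale = scale
    return model


def _train_hinge(config: RankerConfig, Xf: np.ndarray, ai: np.ndarray, bi: np.ndarray) -> RankModel:
    D = Xf[ai] - Xf[bi]                      # (n_pairs, dim)
    n_pairs, dim = D.shape
    # Equivalent per-pair scaling of (1/2)||w||^2 + C sum_ij hinge:
    # lam/2 ||w||^2 + (1/n) sum hinge with lam = 1/(C n_pairs).
    lam = 1.0 / (config.C * n_pairs)
    eta0 = config.learning_rate or 1.0
    w = np.zeros(dim)
    trace = []
    for t in range(1, (config.epochs or 100) + 1):
        margins = D @ w
        viol = margins < 1.0
        g = lam * w
        if viol.any():
            g = g - D[viol].sum(axis=0) / n_pairs
        w = w - (eta0 / np.sqrt(t)) * g
        # Objective recorded on the un-normalised scale
        obj = 0.5 * float(w @ w) + config.C * float(np.maximum(0.0, 1.0 - D @ w).sum())
        if not np.isfinite(obj):
            raise DivergenceError(f"hinge_svm diverged at epoch {t}")
        trace.append(obj)
    return RankModel(kind="hinge_svm", dim=dim, params={"w": w}, config=config, loss_trace=trace)


def _train_ranknet(config: RankerConfig, Xf: np.ndarray, ai: np.ndarray, bi: np.ndarray) -> RankModel:
    rng = np.random.default_rng(config.seed)
    n, dim = Xf.shape
    h = config.hidden_nodes
    lr = config.learning_rate or 5e-5
    W1 = rng.uniform(-0.1, 0.1, size=(dim, h))
    b1 = rng.uniform(-0.1, 0.1, size=h)
    W2 = rng.uniform(-0.1, 0.1, size=h)
    b2 = float(rng.uniform(-0.1, 0.1))
    n_pairs = ai.size
    trace = []
    for epoch in range(1, (config.epochs or 100) + 1):
        A = Xf @ W1 + b1
        Z = _sigmoid(A)
        s = Z @ W2 + b2
        ds = s[ai] - s[bi]
        # log(1 + exp(-ds)), numerically stable
        loss = float(np.mean(np.logaddexp(0.0, -ds)))
        if not np.isfinite(loss):
            raise DivergenceError(f"ranknet diverged at epoch {epoch}")
        trace.append(loss)
        coef = -_sigmoid(-ds) / n_pairs           # dL/d(ds)
        gs = np.zeros(n)
        np.add.at(gs, ai, coef)
        np.add.at(gs, bi, -coef)
        gW2 = Z.T @ gs
        gb2 = float(gs.sum())
        gZ = np.outer(gs, W2)
        gA = gZ * Z * (1.0 - Z)
        gW1 = Xf.T @ gA
        gb1 = gA.sum(axis=0)
        W1 -= lr * gW1
        b1 -= lr * gb1
        W2 -= lr * gW2
        b2 -= lr * gb2
    return RankModel(
        kind="ranknet",
        dim=dim,
        params={"W1": W1, "b1": b1, "W2": W2, "b2": b2},
        config=config,
        loss_trace=trace,
    )


def listnet_loss_grad(
    w: np.ndarray, X: np.ndarray, rel: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean top-one-probability cross entropy and its gradient in w.

    ``X`` has shape (n_inst, n_sys, dim); the target distribution per instance
    is softmax over the relevance integers.
    """
    S = X @ w                              # (n_inst, n_sys)
    Py = _softmax(rel, axis=1)
    logPs = S - S.max(axis=1, keepdims=True)
    logPs = logPs - np.log(np.exp(logPs).sum(axis=1, keepdims=True))
    loss = float(-(Py * logPs).sum(axis=1).mean())
    G = (_softmax(S, axis=1) - Py) / X.shape[0]
    grad = np.einsum("ns,nsd->d", G, X)
    return loss, grad


def _train_listnet(config: RankerConfig, X: np.ndarray, rel: np.ndarray) -> RankModel:
    dim = X.shape[2]
    lr = config.learning_rate or 1e-5
    w = np.zeros(dim)
    trace = []
    for epoch in range(1, (config.epochs or 1500) + 1):
        loss, grad = listnet_loss_grad(w, X, rel)
        if not np.isfinite(loss):
            raise DivergenceError(f"listnet diverged at epoch {epoch}")
        trace.append(loss)
        w = w - lr * grad
    return RankModel(kind="listnet", dim=dim, params={"w": w}, config=config, loss_trace=trace)


def rankboost_candidates(Xf: np.ndarray, n_thresholds: int) -> list[tuple[int, float]]:
    """Evenly spaced quantile threshold candidates per feature.

    For each feature, ``n_thresholds`` interior quantiles of the observed
    values; duplicates within a feature are collapsed.  Candidates are ordered
    by (feature, threshold), which fixes the argmax tie-break.
    """
    cands: list[tuple[int, float]] = []
    qs = np.linspace(0.0, 1.0, n_thresholds + 2)[1:-1]
    for f in range(Xf.shape[1]):
        vals = Xf[:, f]
        if np.all(vals == vals[0]):
            continue  # constant feature can never split a pair
        thetas = np.unique(np.quantile(vals, qs))
        for theta in thetas:
            cands.append((f, float(theta)))
    return cands


def _train_rankboost(config: RankerConfig, Xf: np.ndarray, ai: np.ndarray, bi: np.ndarray) -> RankModel:
    n, dim = Xf.shape
    cands = rankboost_candidates(Xf, config.threshold_candidates)
    if not cands:
        raise TrainingError("rankboost: no non-constant features to threshold")
    # Weak-ranker response matrix H[k, sample] in {0, 1}
    H = np.empty((len(cands), n), dtype=np.float64)
    for k, (f, theta) in enumerate(cands):
        H[k] = Xf[:, f] > theta
    n_pairs = ai.size
    Dw = np.full(n_pairs, 1.0 / n_pairs)
    weak: list[tuple[int, float, float]] = []
    trace = []
    eps = 1e-10
    for _ in range(config.rounds):
        v = np.zeros(n)
        np.add.at(v, ai, Dw)
        np.add.at(v, bi, -Dw)
        r = H @ v                          # (K,) in [-1, 1]
        k = int(np.argmax(np.abs(r)))      # ties -> lowest candidate index
        rk = float(np.clip(r[k], -1.0 + eps, 1.0 - eps))
        alpha = 0.5 * np.log((1.0 + rk) / (1.0 - rk))
        margins = H[k, ai] - H[k, bi]
        Dw = Dw * np.exp(-alpha * margins)
        Z = Dw.sum()
        if not np.isfinite(Z) or Z <= 0:
            raise DivergenceError(f"rankboost diverged at round {len(weak) + 1}")
        Dw /= Z
        f, theta = cands[k]
        weak.append((f, theta, float(alpha)))
        trace.append(float(Z))
    return RankModel(kind="rankboost", dim=dim, params={"weak": weak}, config=config, loss_trace=trace)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def score(model: RankModel, fv: FeatureVector) -> float:
    """Score one sparse feature vector under a trained model."""
    return model.score_vector(fv)


def pairwise_error(model: RankModel, instances: Sequence[Instance]) -> float:
    """Fraction of discordant within-instance pairs, score ties counting 0.5."""
    X, rel, _ = instances_to_arrays(instances, dim=model.dim)
    n_inst, n_sys, d = X.shape
    s = model.score_matrix(X.reshape(n_inst * n_sys, d))
    ai, bi = _pair_indices(rel)
    if ai.size == 0:
        raise TrainingError("no discordant-relevance pairs to evaluate")
    sa, sb = s[ai], s[bi]
    return float((np.sum(sa < sb) + 0.5 * np.sum(sa == sb)) / ai.size)
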