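"""Learning-to-rank algorithms under one query-grouped fit/score contract.

Seven models are provided, covering the three learning-to-rank families plus
a regression baseline:

* point-wise : PRank (ordinal perceptron), SVR baseline
* pair-wise  : RankNet, RankBoost, SVMRank (pair-difference reduction)
* list-wise  : AdaRank, ListNet

Training data is a list of :class:`RankingGroup` objects, one per query
(here: one protein target and its compounds).  All pairwise constructions
are strictly within-query -- order pairs are never formed across targets,
which is what makes heterogeneous per-target affinity scales usable: any
strictly increasing transform of one query's labels leaves its ordered
pairs, and hence the fitted pairwise model, unchanged.

Every fitter is deterministic given its data and seed.  Models serialize to
JSON and the round-trip is bit-faithful for scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .core_data import InvalidInputError
from .evaluation import ndcg_at_k, rank_order

_RANKBOOST_R_CAP = 1.0 - 1e-10


@dataclass
class RankingGroup:
    """One query: a target, its compounds' feature rows, and grade labels."""

    target_id: str
    features: np.ndarray          # (n_compounds, d)
    grades: np.ndarray            # integer grades, shape (n_compounds,)
    compound_ids: List[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.grades = np.asarray(self.grades)
        if self.features.ndim != 2:
            raise InvalidInputError("features must be a 2-D matrix")
        n = self.features.shape[0]
        if len(self.grades) != n or len(self.compound_ids) != n:
            raise InvalidInputError(
                f"group {self.target_id!r}: row counts disagree"
            )
        if np.any(self.grades < 0):
            raise InvalidInputError("grades must be non-negative")

    def __len__(self) -> int:
        return self.features.shape[0]


class OrderedPair(NamedTuple):
    """A within-query preference: grade(preferred) > grade(other)."""

    query: str
    preferred_index: int
    other_index: int


def enumerate_pairs(group: RankingGroup) -> List[OrderedPair]:
    """All within-group ordered pairs (i, j) with grade_i > grade_j.

    Deterministic order: i ascending, then j ascending.  Pairs are never
    formed across queries.
    """
    grades = group.grades
    n = len(grades)
    return [
        OrderedPair(group.target_id, i, j)
        for i in range(n)
        for j in range(n)
        if grades[i] > grades[j]
    ]


def _check_feature_dim(groups: Sequence[RankingGroup]) -> int:
    if not groups:
        raise InvalidInputError("no training groups")
    dims = {g.features.shape[1] for g in groups}
    if len(dims) != 1:
        raise InvalidInputError(f"inconsistent feature dimensions {sorted(dims)}")
    return dims.pop()


def _all_pairs(groups: Sequence[RankingGroup]) -> List[OrderedPair]:
    pairs: List[OrderedPair] = []
    for g in groups:
        pairs.extend(enumerate_pairs(g))
    return pairs


def subsample_pairs(
    pairs: List[OrderedPair], max_per_query: Optional[int], seed: int
) -> List[OrderedPair]:
    """Seeded per-query cap on ordered pairs (off when max_per_query is None)."""
    if max_per_query is None:
        return pairs
    rng = np.random.default_rng(seed)
    by_query: Dict[str, List[OrderedPair]] = {}
    for p in pairs:
        by_query.setdefault(p.query, []).append(p)
    out: List[OrderedPair] = []
    for query in by_query:  # insertion order: deterministic
        qp = by_query[query]
        if len(qp) > max_per_query:
            idx = rng.choice(len(qp), size=max_per_query, replace=False)
            qp = [qp[i] for i in sorted(idx)]
        out.extend(qp)
    return out


# ---------------------------------------------------------------------------
# model classes

class RankerModel:
    """Base class: a fitted ranking function exposing score(X) -> scores."""

    algorithm: str = "base"

    def __init__(self) -> None:
        self.fitted = False
        self.hyperparameters: dict = {}
        self.rng_seed: int = 0

    def score(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _check_input(self, X: np.ndarray, dim: int) -> np.ndarray:
        if not self.fitted:
            raise InvalidInputError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != dim:
            raise InvalidInputError(
                f"feature dimension {X.shape[1]} != training dimension {dim}"
            )
        return X

    # --- JSON serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "hyperparameters": self.hyperparameters,
            "rng_seed": self.rng_seed,
            "parameters": self._params_to_dict(),
        }

    def _params_to_dict(self) -> dict:
        raise NotImplementedError

    def _params_from_dict(self, params: dict) -> None:
        raise NotImplementedError

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @staticmethod
    def from_dict(data: dict) -> "RankerModel":
        cls = _MODEL_CLASSES[data["algorithm"]]
        model = cls.__new__(cls)
        RankerModel.__init__(model)
        model.hyperparameters = data["hyperparameters"]
        model.rng_seed = data["rng_seed"]
        model._params_from_dict(data["parameters"])
        model.fitted = True
        return model

    @staticmethod
    def load_json(path) -> "RankerModel":
        with open(path) as fh:
            return RankerModel.from_dict(json.load(fh))


class LinearRankerModel(RankerModel):
    """A linear scoring function f(x) = w . x."""

    def __init__(self, algorithm: str, w: np.ndarray) -> None:
        super().__init__()
        self.algorithm = algorithm
        self.w = np.asarray(w, dtype=float)

    def score(self, X: np.ndarray) -> np.ndarray:
        X = self._check_input(X, self.w.shape[0])
        return X @ self.w

    def _params_to_dict(self) -> dict:
        return {"w": self.w.tolist()}

    def _params_from_dict(self, params: dict) -> None:
        self.w = np.asarray(params["w"], dtype=float)


class PRankModel(RankerModel):
    """Ordinal perceptron: weights w plus ordered thresholds b_1..b_{K-1}."""

    algorithm = "prank"

    def __init__(self, w: np.ndarray, b: np.ndarray) -> None:
        super().__init__()
        self.w = np.asarray(w, dtype=float)
        self.b = np.asarray(b, dtype=float)

    def score(self, X: np.ndarray) -> np.ndarray:
        X = self._check_input(X, self.w.shape[0])
        return X @ self.w

    def predict_rank(self, X: np.ndarray) -> np.ndarray:
        """Predicted ordinal rank in 1..K: min{r : w.x - b_r < 0}, b_K = +inf."""
        s = self.score(X)
        ranks = np.empty(len(s), dtype=int)
        for i, v in enumerate(s):
            r = 1
            for threshold in self.b:
                if v - threshold < 0:
                    break
                r += 1
            ranks[i] = r
        return ranks

    def _params_to_dict(self) -> dict:
        return {"w": self.w.tolist(), "b": self.b.tolist()}

    def _params_from_dict(self, params: dict) -> None:
        self.w = np.asarray(params["w"], dtype=float)
        self.b = np.asarray(params["b"], dtype=float)


class ThresholdEnsembleModel(RankerModel):
    """Weighted sum of threshold weak rankers: score = sum_t a_t 1[x_f > theta]."""

    algorithm = "rankboost"

    def __init__(self, weak_rankers: List[Tuple[int, float, float]], dim: int) -> None:
        super().__init__()
        self.weak_rankers = weak_rankers  # (feature, threshold, alpha)
        self.dim = dim

    def score(self, X: np.ndarray) -> np.ndarray:
        X = self._check_input(X, self.dim)
        scores = np.zeros(X.shape[0])
        for f, theta, alpha in self.weak_rankers:
            scores += alpha * (X[:, f] > theta)
        return scores

    def _params_to_dict(self) -> dict:
        return {
            "weak_rankers": [[int(f), float(t), float(a)] for f, t, a in self.weak_rankers],
            "dim": self.dim,
        }

    def _params_from_dict(self, params: dict) -> None:
        self.weak_rankers = [(int(f), float(t), float(a)) for f, t, a in params["weak_rankers"]]
        self.dim = int(params["dim"])


class FeatureEnsembleModel(RankerModel):
    """Weighted sum of raw single-feature scorers (AdaRank)."""

    algorithm = "adarank"

    def __init__(self, weak_rankers: List[Tuple[int, float]], dim: int) -> None:
        super().__init__()
        self.weak_rankers = weak_rankers  # (feature, alpha)
        self.dim = dim

    def score(self, X: np.ndarray) -> np.ndarray:
        X = self._check_input(X, self.dim)
        scores = np.zeros(X.shape[0])
        for f, alpha in self.weak_rankers:
            scores += alpha * X[:, f]
        return scores

    def _params_to_dict(self) -> dict:
        return {
            "weak_rankers": [[int(f), float(a)] for f, a in self.weak_rankers],
            "dim": self.dim,
        }

    def _params_from_dict(self, params: dict) -> None:
        self.weak_rankers = [(int(f), float(a)) for f, a in params["weak_rankers"]]
        self.dim = int(params["dim"])


class MLPRankerModel(RankerModel):
    """One-hidden-layer scorer with sigmoid activations (RankNet, hidden > 0)."""

    algorithm = "ranknet_mlp"

    def __init__(self, W1: np.ndarray, b1: np.ndarray, w2: np.ndarray) -> None:
        super().__init__()
        self.W1 = np.asarray(W1, dtype=float)  # (hidden, d)
        self.b1 = np.asarray(b1, dtype=float)
        self.w2 = np.asarray(w2, dtype=float)

    def score(self, X: np.ndarray) -> np.ndarray:
        X = self._check_input(X, self.W1.shape[1])
        h = 1.0 / (1.0 + np.exp(-(X @ self.W1.T + self.b1)))
        return h @ self.w2

    def _params_to_dict(self) -> dict:
        return {"W1": self.W1.tolist(), "b1": self.b1.tolist(), "w2": self.w2.tolist()}

    def _params_from_dict(self, params: dict) -> None:
        self.W1 = np.asarray(params["W1"], dtype=float)
        self.b1 = np.asarray(params["b1"], dtype=float)
        self.w2 = np.asarray(params["w2"], dtype=float)


class SVRModel(RankerModel):
    """Epsilon-SVR baseline; scoring re-implements the kernel expansion."""

    algorithm = "svr_baseline"

    def __init__(self, support_vectors, dual_coef, intercept, gamma, kernel) -> None:
        super().__init__()
        self.support_vectors = np.asarray(support_vectors, dtype=float)
        self.dual_coef = np.asarray(dual_coef, dtype=float)
        self.intercept = float(intercept)
        self.gamma = float(gamma)
        self.kernel = kernel

    def score(self, X: np.ndarray) -> np.ndarray:
        X = self._check_input(X, self.support_vectors.shape[1])
        if self.kernel == "rbf":
            d2 = (
                np.sum(X ** 2, axis=1)[:, None]
                + np.sum(self.support_vectors ** 2, axis=1)[None, :]
                - 2.0 * X @ self.support_vectors.T
            )
            K = np.exp(-self.gamma * d2)
        elif self.kernel == "linear":
            K = X @ self.support_vectors.T
        else:
            raise InvalidInputError(f"unsupported kernel {self.kernel!r}")
        return K @ self.dual_coef + self.intercept

    def _params_to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "kernel": self.kernel,
        }

    def _params_from_dict(self, params: dict) -> None:
        self.support_vectors = np.asarray(params["support_vectors"], dtype=float)
        self.dual_coef = np.asarray(params["dual_coef"], dtype=float)
        self.intercept = float(params["intercept"])
        self.gamma = float(params["gamma"])
        self.kernel = params["kernel"]


_MODEL_CLASSES = {
    "prank": PRankModel,
    "ranknet": LinearRankerModel,
    "ranknet_mlp": MLPRankerModel,
    "rankboost": ThresholdEnsembleModel,
    "svmrank": LinearRankerModel,
    "adarank": FeatureEnsembleModel,
    "listnet": LinearRankerModel,
    "svr_baseline": SVRModel,
}


def _finish(model: RankerModel, algorithm: str, hyperparameters: dict, seed: int):
    model.algorithm = algorithm
    model.hyperparameters = hyperparameters
    model.rng_seed = seed
    model.fitted = True
    return model


# ---------------------------------------------------------------------------
# point-wise: PRank

def fit_prank(
    groups: Sequence[RankingGroup], epochs: int = 50, seed: int = 0
) -> PRankModel:
    """Online ordinal perceptron over pooled instances.

    Grades 0..K-1 become ordinal ranks 1..K.  The model keeps a weight
    vector w (init 0) and non-decreasing thresholds b_1 <= ... <= b_{K-1}
    (init 0, with b_K = +inf implied).  Prediction for x is the smallest r
    with w.x - b_r < 0.  On a training example (x, y): for r = 1..K-1 let
    y_r = +1 if y > r else -1; if (w.x - b_r) y_r <= 0 then tau_r = y_r else
    tau_r = 0; finally w += (sum_r tau_r) x and b_r -= tau_r.  The update
    provably keeps the thresholds sorted.  Instance order is reshuffled each
    epoch with the given seed.
    """
    dim = _check_feature_dim(groups)
    X = np.vstack([g.features for g in groups])
    ranks = np.concatenate([g.grades for g in groups]).astype(int) + 1
    K = int(ranks.max())
    if K < 2:
        raise InvalidInputError("PRank needs at least 2 distinct rank levels")
    w = np.zeros(dim)
    b = np.zeros(K - 1)
    rng = np.random.default_rng(seed)
    r_levels = np.arange(1, K)
    for _ in range(epochs):
        order = rng.permutation(len(ranks))
        for idx in order:
            x, y = X[idx], ranks[idx]
            margins = w @ x - b
            y_r = np.where(y > r_levels, 1.0, -1.0)
            tau = np.where(margins * y_r <= 0.0, y_r, 0.0)
            if np.any(tau):
                w += tau.sum() * x
                b -= tau
    model = PRankModel(w, b)
    return _finish(model, "prank", {"epochs": epochs}, seed)


def prank_update(
    w: np.ndarray, b: np.ndarray, x: np.ndarray, y: int
) -> Tuple[np.ndarray, np.ndarray]:
    """One PRank update step (exposed for auditing); y is a rank in 1..K."""
    w = np.asarray(w, dtype=float).copy()
    b = np.asarray(b, dtype=float).copy()
    r_levels = np.arange(1, len(b) + 1)
    y_r = np.where(y > r_levels, 1.0, -1.0)
    margins = w @ x - b
    tau = np.where(margins * y_r <= 0.0, y_r, 0.0)
    w += tau.sum() * np.asarray(x, dtype=float)
    b -= tau
    return w, b


# ---------------------------------------------------------------------------
# pair-wise: RankNet

def ranknet_pair_loss(score_diff: np.ndarray) -> np.ndarray:
    """Cross-entropy of P_ij = sigmoid(f_i - f_j) against target 1."""
    return np.log1p(np.exp(-np.asarray(score_diff, dtype=float)))


def fit_ranknet(
    groups: Sequence[RankingGroup],
    hidden_units: int = 0,
    learning_rate: float = 0.01,
    epochs: int = 200,
    seed: int = 0,
) -> RankerModel:
    """Pairwise cross-entropy ranker trained by full-batch gradient descent.

    For each within-query ordered pair (i preferred over j) the modeled
    preference probability is sigmoid(f(x_i) - f(x_j)) with target 1; the
    loss is the summed binary cross-entropy.  The scorer is linear when
    ``hidden_units`` is 0 (the default) or a one-hidden-layer network with
    sigmoid activations otherwise.
    """
    dim = _check_feature_dim(groups)
    pairs = _all_pairs(groups)
    if not pairs:
        raise InvalidInputError("no ordered pairs in the training data")
    # instance matrix + per-pair index arrays
    X = np.vstack([g.features for g in groups])
    offsets = np.cumsum([0] + [len(g) for g in groups])
    by_id = {g.target_id: k for k, g in enumerate(groups)}
    i_idx = np.array([offsets[by_id[p.query]] + p.preferred_index for p in pairs])
    j_idx = np.array([offsets[by_id[p.query]] + p.other_index for p in pairs])

    rng = np.random.default_rng(seed)
    hp = {
        "hidden_units": hidden_units,
        "learning_rate": learning_rate,
        "epochs": epochs,
    }
    if hidden_units == 0:
        w = rng.normal(scale=0.01, size=dim)
        for _ in range(epochs):
            d = (X[i_idx] - X[j_idx]) @ w
            g = -(1.0 - 1.0 / (1.0 + np.exp(-d)))  # dLoss/dd per pair
            grad = (X[i_idx] - X[j_idx]).T @ g
            w -= learning_rate * grad
        return _finish(LinearRankerModel("ranknet", w), "ranknet", hp, seed)

    h = hidden_units
    W1 = rng.normal(scale=0.1, size=(h, dim))
    b1 = np.zeros(h)
    w2 = rng.normal(scale=0.1, size=h)
    for _ in range(epochs):
        A = 1.0 / (1.0 + np.exp(-(X @ W1.T + b1)))  # (n, h)
        f = A @ w2
        d = f[i_idx] - f[j_idx]
        g = -(1.0 - 1.0 / (1.0 + np.exp(-d)))
        # accumulate dL/df per instance
        df = np.zeros(len(f))
        np.add.at(df, i_idx, g)
        np.add.at(df, j_idx, -g)
        grad_w2 = A.T @ df
        dA = np.outer(df, w2) * A * (1.0 - A)
        grad_W1 = dA.T @ X
        grad_b1 = dA.sum(axis=0)
        W1 -= learning_rate * grad_W1
        b1 -= learning_rate * grad_b1
        w2 -= learning_rate * grad_w2
    return _finish(MLPRankerModel(W1, b1, w2), "ranknet_mlp", hp, seed)


# ---------------------------------------------------------------------------
# pair-wise: RankBoost

def fit_rankboost(
    groups: Sequence[RankingGroup],
    rounds: int = 100,
    seed: int = 0,
    max_pairs_per_query: Optional[int] = None,
) -> ThresholdEnsembleModel:
    """Boosting over ordered pairs with single-feature threshold weak rankers.

    A distribution D over ordered pairs starts uniform.  Weak rankers are
    h(x) = 1[x_f > theta] with candidate thresholds at midpoints between
    consecutive distinct observed values of each feature.  Each round picks
    the weak ranker maximizing r = sum_pairs D(i,j)(h(x_i) - h(x_j)), sets
    alpha = 0.5 ln((1+r)/(1-r)) (r capped at +/-(1 - 1e-10)), reweights
    D(i,j) *= exp(-alpha (h(x_i) - h(x_j))) and renormalizes.
    """
    dim = _check_feature_dim(groups)
    pairs = subsample_pairs(_all_pairs(groups), max_pairs_per_query, seed)
    if not pairs:
        raise InvalidInputError("no ordered pairs in the training data")
    X = np.vstack([g.features for g in groups])
    offsets = np.cumsum([0] + [len(g) for g in groups])
    by_id = {g.target_id: k for k, g in enumerate(groups)}
    i_idx = np.array([offsets[by_id[p.query]] + p.preferred_index for p in pairs])
    j_idx = np.array([offsets[by_id[p.query]] + p.other_index for p in pairs])

    n_inst = X.shape[0]
    D = np.full(len(pairs), 1.0 / len(pairs))
    # per feature: instance order by value and candidate midpoints
    sort_idx = np.argsort(X, axis=0)
    weak: List[Tuple[int, float, float]] = []
    for _ in range(rounds):
        # potential pi(i) = sum_j D(i,j) - sum_j D(j,i); then
        # r(f, theta) = sum_{x_i[f] > theta} pi(i)
        pi = np.zeros(n_inst)
        np.add.at(pi, i_idx, D)
        np.add.at(pi, j_idx, -D)
        best = None  # (r, feature, theta)
        for f in range(dim):
            order = sort_idx[:, f][::-1]  # descending by feature value
            vals = X[order, f]
            csum = np.cumsum(pi[order])
            # thresholds between distinct consecutive values (descending)
            distinct = vals[:-1] > vals[1:]
            if not np.any(distinct):
                continue
            ks = np.nonzero(distinct)[0]
            rs = csum[ks]  # r for theta = midpoint below vals[k]
            k_best = ks[np.argmax(rs)]
            r_f = csum[k_best]
            theta = 0.5 * (vals[k_best] + vals[k_best + 1])
            if best is None or r_f > best[0]:
                best = (r_f, f, theta)
        if best is None or best[0] <= 0.0:
            break
        r, f, theta = best
        r = float(np.clip(r, -_RANKBOOST_R_CAP, _RANKBOOST_R_CAP))
        alpha = rankboost_alpha(r)
        h = (X[:, f] > theta).astype(float)
        D = D * np.exp(-alpha * (h[i_idx] - h[j_idx]))
        D /= D.sum()
        weak.append((f, float(theta), float(alpha)))
    model = ThresholdEnsembleModel(weak, dim)
    return _finish(model, "rankboost", {"rounds": rounds}, seed)


def rankboost_alpha(r: float) -> float:
    """RankBoost round weight: 0.5 ln((1+r)/(1-r)), r capped near +/-1."""
    r = float(np.clip(r, -_RANKBOOST_R_CAP, _RANKBOOST_R_CAP))
    return 0.5 * np.log((1.0 + r) / (1.0 - r))


# ---------------------------------------------------------------------------
# pair-wise: SVMRank

def fit_svmrank(
    groups: Sequence[RankingGroup],
    regularization_c: float = 1.0,
    seed: int = 0,
    max_pairs_per_query: Optional[int] = None,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LinearRankerModel:
    """Ranking SVM via the pair-difference reduction.

    Every within-query ordered pair (i preferred over j) yields a margin
    constraint w . (x_i - x_j) >= 1; the L2-regularized squared-hinge primal

        0.5 ||w||^2 + C sum_p max(0, 1 - w . (x_i - x_j))^2

    is minimized with L-BFGS (no intercept; its separating direction matches
    the plain hinge one in the separable case).  Margins and gradients are
    evaluated through the per-item score vector X w, so the pair-difference
    matrix is never materialized and the solver scales to the
    high-dimensional cross-term features.  The objective is convex and the
    start point fixed, so the fit is deterministic; the seed only controls
    optional pair subsampling.  score(x) = w . x.
    """
    from scipy.optimize import minimize

    dim = _check_feature_dim(groups)
    pairs = subsample_pairs(_all_pairs(groups), max_pairs_per_query, seed)
    if not pairs:
        raise InvalidInputError("no ordered pairs in the training data")
    X = np.vstack([g.features for g in groups])
    offsets = np.cumsum([0] + [len(g) for g in groups])
    by_id = {g.target_id: k for k, g in enumerate(groups)}
    i_idx = np.array([offsets[by_id[p.query]] + p.preferred_index for p in pairs])
    j_idx = np.array([offsets[by_id[p.query]] + p.other_index for p in pairs])
    n_items = X.shape[0]
    C = regularization_c

    def objective(w):
        scores = X @ w
        active = np.maximum(1.0 - (scores[i_idx] - scores[j_idx]), 0.0)
        grad_scores = 2.0 * C * (
            np.bincount(j_idx, weights=active, minlength=n_items)
            - np.bincount(i_idx, weights=active, minlength=n_items)
        )
        return 0.5 * (w @ w) + C * (active @ active), w + X.T @ grad_scores

    result = minimize(
        objective,
        np.zeros(dim),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
    )
    model = LinearRankerModel("svmrank", result.x.copy())
    hp = {"regularization_c": regularization_c, "tol": tol, "max_iter": max_iter}
    return _finish(model, "svmrank", hp, seed)


# ---------------------------------------------------------------------------
# list-wise: AdaRank

def fit_adarank(
    groups: Sequence[RankingGroup], rounds: int = 100, k: int = 10
) -> FeatureEnsembleModel:
    """Boosting over queries with single raw features as weak rankers.

    Query weights P start uniform.  Each round selects the feature f
    maximizing sum_q P(q) E_f(q), where E_f(q) is NDCG@k of the ranking of
    query q induced by feature f; its weight is
    alpha = 0.5 ln(sum_q P(q)(1 + E(q)) / sum_q P(q)(1 - E(q))).
    Queries are then reweighted proportional to exp(-NDCG@k of the current
    ensemble) and renormalized.  Final score = sum_t alpha_t x[f_t].
    """
    dim = _check_feature_dim(groups)
    usable = [g for g in groups if len(set(g.grades.tolist())) > 1]
    if not usable:
        raise InvalidInputError("all groups are degenerate (no ranking signal)")
    n_q = len(usable)

    def feature_ndcg(q: RankingGroup, scores: np.ndarray) -> float:
        order = rank_order(q.compound_ids, scores)
        return ndcg_at_k([int(q.grades[i]) for i in order], k)

    # E[f, q]: NDCG@k of ranking query q by raw feature f
    E = np.empty((dim, n_q))
    for qi, q in enumerate(usable):
        for f in range(dim):
            E[f, qi] = feature_ndcg(q, q.features[:, f])

    P = np.full(n_q, 1.0 / n_q)
    weak: List[Tuple[int, float]] = []
    ensemble = [np.zeros(len(q)) for q in usable]
    for _ in range(rounds):
        weighted = E @ P
        f = int(np.argmax(weighted))
        alpha = adarank_alpha(P, E[f])
        if alpha <= 0.0:
            break
        weak.append((f, float(alpha)))
        scores_e = []
        for qi, q in enumerate(usable):
            ensemble[qi] = ensemble[qi] + alpha * q.features[:, f]
            scores_e.append(feature_ndcg(q, ensemble[qi]))
        P = np.exp(-np.asarray(scores_e))
        P /= P.sum()
    model = FeatureEnsembleModel(weak, dim)
    return _finish(model, "adarank", {"rounds": rounds, "k": k}, 0)


def adarank_alpha(P: np.ndarray, E: np.ndarray) -> float:
    """AdaRank round weight: 0.5 ln(sum P(1+E) / sum P(1-E))."""
    num = float(np.dot(P, 1.0 + np.asarray(E, dtype=float)))
    den = float(np.dot(P, 1.0 - np.asarray(E, dtype=float)))
    den = max(den, 1e-12)
    return 0.5 * np.log(num / den)


# ---------------------------------------------------------------------------
# list-wise: ListNet

def listnet_loss(groups: Sequence[RankingGroup], w: np.ndarray) -> float:
    """Top-one cross-entropy between grade and score softmax distributions."""
    total = 0.0
    for g in groups:
        if len(g) < 2:
            continue
        py = _softmax(g.grades.astype(float))
        pf = _softmax(g.features @ w)
        total += -float(py @ np.log(pf))
    return total


def _softmax(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max())
    return e / e.sum()


def fit_listnet(
    groups: Sequence[RankingGroup],
    learning_rate: float = 0.01,
    epochs: int = 200,
    seed: int = 0,
) -> LinearRankerModel:
    """List-wise ranker minimizing top-one softmax cross-entropy.

    Per query the target top-one distribution is softmax of the grades and
    the model distribution is softmax of the linear scores; the loss is the
    summed cross-entropy, minimized by full-batch gradient descent.
    Single-item queries carry zero gradient and are skipped.
    """
    dim = _check_feature_dim(groups)
    usable = [g for g in groups if len(g) >= 2]
    skipped = len(groups) - len(usable)
    if skipped:
        import logging

        logging.getLogger(__name__).info(
            "listnet: skipped %d single-item groups", skipped
        )
    if not usable:
        raise InvalidInputError("no group with >= 2 items")
    rng = np.random.default_rng(seed)
    w = rng.normal(scale=0.01, size=dim)
    targets = [_softmax(g.grades.astype(float)) for g in usable]
    for _ in range(epochs):
        grad = np.zeros(dim)
        for g, py in zip(usable, targets):
            pf = _softmax(g.features @ w)
            grad += g.features.T @ (pf - py)
        w -= learning_rate * grad
    model = LinearRankerModel("listnet", w)
    hp = {"learning_rate": learning_rate, "epochs": epochs}
    return _finish(model, "listnet", hp, seed)


# ---------------------------------------------------------------------------
# baseline: support vector regression on grades

def fit_svr_baseline(
    groups: Sequence[RankingGroup], hyperparameters: Optional[dict] = None
) -> SVRModel:
    """Epsilon-SVR on pooled (feature, grade) instances (libsvm backend)."""
    from sklearn.svm import SVR

    _check_feature_dim(groups)
    X = np.vstack([g.features for g in groups])
    y = np.concatenate([g.grades for g in groups]).astype(float)
    if len(set(y.tolist())) < 2:
        raise InvalidInputError("degenerate training set: a single grade level")
    hp = {"kernel": "rbf", "C": 1.0, "epsilon": 0.1, "gamma": "scale"}
    hp.update(hyperparameters or {})
    svr = SVR(**hp)
    svr.fit(X, y)
    if hp["gamma"] == "scale":
        gamma = 1.0 / (X.shape[1] * X.var()) if X.var() > 0 else 1.0
    elif hp["gamma"] == "auto":
        gamma = 1.0 / X.shape[1]
    else:
        gamma = float(hp["gamma"])
    model = SVRModel(
        svr.support_vectors_, svr.dual_coef_[0], svr.intercept_[0], gamma, hp["kernel"]
    )
    return _finish(model, "svr_baseline", hp, 0)


# ---------------------------------------------------------------------------

FITTERS = {
    "prank": fit_prank,
    "ranknet": fit_ranknet,
    "rankboost": fit_rankboost,
    "svmrank": fit_svmrank,
    "adarank": fit_adarank,
    "listnet": fit_listnet,
    "svr_baseline": fit_svr_baseline,
}

ALGORITHMS = tuple(FITTERS)

#: fitters that consume only within-query ordered pairs
PAIRWISE_ALGORITHMS = ("ranknet", "rankboost", "svmrank")


def fit_ranker(algorithm: str, groups: Sequence[RankingGroup], **kwargs) -> RankerModel:
    """Dispatch to a fitter by algorithm name."""
    if algorithm not in FITTERS:
        raise InvalidInputError(
            f"unknown algorithm {algorithm!r}; choose from {sorted(FITTERS)}"
        )
    return FITTERS[algorithm](groups, **kwargs)


def score_groups(
    model: RankerModel, groups: Sequence[RankingGroup]
) -> Dict[str, np.ndarray]:
    """Score each group with a fitted model; inputs are not mutated."""
    return {g.target_id: model.score(g.features) for g in groups}
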