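import numpy as np
import pytest

from rankscreen.core_data import InvalidInputError
from rankscreen.evaluation import ndcg_at_k, rank_order
from rankscreen.rankers import (
    PAIRWISE_ALGORITHMS,
    RankerModel,
    RankingGroup,
    adarank_alpha,
    enumerate_pairs,
    fit_adarank,
    fit_listnet,
    fit_prank,
    fit_ranker,
    fit_rankboost,
    fit_ranknet,
    fit_svmrank,
    fit_svr_baseline,
    listnet_loss,
    prank_update,
    rankboost_alpha,
    ranknet_pair_loss,
    score_groups,
)
from conftest import random_group


def make_group(grades, features=None, target_id="q"):
    grades = np.asarray(grades)
    if features is None:
        features = np.arange(len(grades), dtype=float)[:, None]
    return RankingGroup(
        target_id=target_id,
        features=np.asarray(features, dtype=float),
        grades=grades,
        compound_ids=[f"{target_id}_c{i:03d}" for i in range(len(grades))],
    )


# ---------------------------------------------------------------------------
# pair enumeration

def brute_force_pairs(group):
    out = []
    n = len(group.grades)
    for i in range(n):
        for j in range(n):
            if group.grades[i] > group.grades[j]:
                out.append((i, j))
    return out


def test_enumerate_pairs_examples():
    assert len(enumerate_pairs(make_group([2, 1, 1, 0]))) == 5
    assert enumerate_pairs(make_group([1, 1, 1])) == []
    pairs = enumerate_pairs(make_group([1, 0]))
    assert [(p.preferred_index, p.other_index) for p in pairs] == [(0, 1)]


def test_enumerate_pairs_matches_brute_force_on_random_groups():
    rng = np.random.default_rng(11)
    for _ in range(50):
        group = random_group(rng, n=int(rng.integers(2, 30)))
        got = [(p.preferred_index, p.other_index) for p in enumerate_pairs(group)]
        assert got == brute_force_pairs(group)
        assert all(p.query == group.target_id for p in enumerate_pairs(group))


# ---------------------------------------------------------------------------
# PRank

def test_prank_single_update_hand_example():
    w, b = prank_update(np.array([0.0]), np.array([0.0, 0.0]), np.array([1.0]), 1)
    assert w.tolist() == [-2.0]
    assert b.tolist() == [1.0, 1.0]


def test_prank_zero_model_scores_constant():
    group = make_group([0, 1, 2], features=np.eye(3))
    model = fit_prank([group], epochs=0, seed=0)
    assert np.array_equal(model.score(np.eye(3)), np.zeros(3))


def test_prank_separable_reaches_zero_rank_error():
    grades = np.array([0] * 5 + [1] * 5 + [2] * 5)
    x = np.concatenate([np.linspace(0, 1, 5), np.linspace(2, 3, 5), np.linspace(4, 5, 5)])
    group = make_group(grades, features=x[:, None])
    model = fit_prank([group], epochs=50, seed=0)
    predicted = model.predict_rank(group.features)
    assert np.array_equal(predicted, grades + 1)


def test_prank_thresholds_stay_sorted_through_training():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 3))
    grades = rng.integers(0, 5, size=40)
    grades[:5] = [0, 1, 2, 3, 4]
    # replay updates one at a time, checking monotonicity after each
    w = np.zeros(3)
    b = np.zeros(4)
    for epoch in range(3):
        order = rng.permutation(40)
        for i in order:
            w, b = prank_update(w, b, X[i], int(grades[i]) + 1)
            assert np.all(np.diff(b) >= 0)


def test_prank_requires_two_levels():
    with pytest.raises(InvalidInputError):
        fit_prank([make_group([0, 0, 0])])


# ---------------------------------------------------------------------------
# RankNet

def test_ranknet_symmetric_scores_loss_is_ln2():
    assert ranknet_pair_loss(np.zeros(3)) == pytest.approx(np.log(2))


def test_ranknet_gradient_at_equality():
    eps = 1e-6
    num_grad = (ranknet_pair_loss(eps) - ranknet_pair_loss(-eps)) / (2 * eps)
    assert num_grad == pytest.approx(-0.5, abs=1e-6)


def test_ranknet_linear_learns_preference_direction():
    group = make_group([1, 0], features=[[1.0], [0.0]])
    model = fit_ranknet([group], epochs=100, seed=0)
    assert model.w[0] > 0


def test_ranknet_loss_non_increasing_linear_case():
    rng = np.random.default_rng(2)
    group = random_group(rng, n=15, dim=3)
    pairs = enumerate_pairs(group)
    i_idx = np.array([p.preferred_index for p in pairs])
    j_idx = np.array([p.other_index for p in pairs])

    def loss(w):
        d = (group.features[i_idx] - group.features[j_idx]) @ w
        return ranknet_pair_loss(d).sum()

    losses = [
        loss(fit_ranknet([group], epochs=e, seed=3).w) for e in (0, 10, 50, 200)
    ]
    assert all(a >= b - 1e-9 for a, b in zip(losses, losses[1:]))


def test_ranknet_hidden_layer_variant_fits_and_scores():
    rng = np.random.default_rng(4)
    group = random_group(rng, n=12, dim=3)
    model = fit_ranknet([group], hidden_units=4, epochs=20, seed=5)
    scores = model.score(group.features)
    assert scores.shape == (12,)
    assert np.all(np.isfinite(scores))


def test_ranknet_requires_pairs():
    with pytest.raises(InvalidInputError):
        fit_ranknet([make_group([1, 1, 1])])


# ---------------------------------------------------------------------------
# RankBoost

def test_rankboost_alpha_closed_form():
    assert rankboost_alpha(0.8) == pytest.approx(0.5 * np.log(9), abs=1e-6)
    assert np.isfinite(rankboost_alpha(1.0))  # capped, not infinite


def test_rankboost_perfect_weak_ranker_after_round_one():
    group = make_group([0, 0, 1, 1])  # feature = index: a single threshold fixes it
    model = fit_rankboost([group], rounds=1, seed=0)
    scores = model.score(group.features)
    assert scores[2] > scores[0] and scores[3] > scores[1]


def test_rankboost_scores_respect_separable_ordering():
    rng = np.random.default_rng(6)
    x = rng.normal(size=20)
    grades = (x > 0).astype(int) + (x > 1).astype(int)
    group = make_group(grades, features=x[:, None])
    model = fit_rankboost([group], rounds=20, seed=0)
    scores = model.score(group.features)
    order = rank_order(group.compound_ids, scores)
    assert ndcg_at_k([int(grades[i]) for i in order], 10) == pytest.approx(1.0)


def test_rankboost_requires_pairs():
    with pytest.raises(InvalidInputError):
        fit_rankboost([make_group([2, 2])])


# ---------------------------------------------------------------------------
# SVMRank

def test_svmrank_sign_forced_in_separable_case():
    group = make_group([1, 0], features=[[1.0], [0.0]])
    model = fit_svmrank([group], seed=0)
    assert model.score(np.array([[1.0]]))[0] > model.score(np.array([[0.0]]))[0]


def test_svmrank_direction_invariant_to_pair_duplication():
    rng = np.random.default_rng(7)
    group = random_group(rng, n=12, dim=3)
    m1 = fit_svmrank([group], seed=0)
    # duplicating every pair: present the same group twice under distinct ids
    twin = RankingGroup("q2", group.features, group.grades,
                        [c + "x" for c in group.compound_ids])
    m2 = fit_svmrank([group, twin], seed=0)
    cos = m1.w @ m2.w / (np.linalg.norm(m1.w) * np.linalg.norm(m2.w))
    assert cos > 0.99


def test_svmrank_training_violations_match_brute_force():
    rng = np.random.default_rng(8)
    group = RankingGroup(
        "q",
        rng.normal(size=(20, 2)),
        rng.integers(0, 3, size=20),
        [f"c{i}" for i in range(20)],
    )
    model = fit_svmrank([group], seed=0)
    scores = model.score(group.features)
    violations = sum(
        1
        for p in enumerate_pairs(group)
        if scores[p.preferred_index] <= scores[p.other_index]
    )
    brute = sum(
        1
        for i in range(20)
        for j in range(20)
        if group.grades[i] > group.grades[j] and scores[i] <= scores[j]
    )
    assert violations == brute


# ---------------------------------------------------------------------------
# AdaRank

def test_adarank_alpha_closed_form():
    assert adarank_alpha(np.array([1.0]), np.array([0.5])) == pytest.approx(
        0.5 * np.log(3), abs=1e-6
    )


def test_adarank_selects_perfect_feature_first():
    rng = np.random.default_rng(9)
    groups = []
    for q in range(3):
        grades = rng.integers(0, 5, size=10)
        grades[0], grades[1] = 4, 0
        feats = rng.normal(size=(10, 4))
        feats[:, 2] = grades  # feature 2 reproduces the grades exactly
        groups.append(
            RankingGroup(f"q{q}", feats, grades, [f"q{q}c{i}" for i in range(10)])
        )
    model = fit_adarank(groups, rounds=1, k=10)
    assert model.weak_rankers[0][0] == 2


def test_adarank_rejects_all_degenerate():
    with pytest.raises(InvalidInputError):
        fit_adarank([make_group([2, 2, 2])], rounds=5)


# ---------------------------------------------------------------------------
# ListNet

def test_listnet_uniform_scorer_loss_is_ln2_for_two_items():
    group = make_group([1, 0], features=[[0.5], [0.5]])
    assert listnet_loss([group], np.zeros(1)) == pytest.approx(np.log(2))


def test_listnet_loss_shift_invariant():
    rng = np.random.default_rng(10)
    group = random_group(rng, n=8, dim=3)
    w = rng.normal(size=3)
    base = listnet_loss([group], w)
    # shift every score by a constant via an added all-ones feature
    feats = np.hstack([group.features, np.ones((8, 1))])
    g2 = RankingGroup("q", feats, group.grades, group.compound_ids)
    w2 = np.append(w, 123.0)
    assert listnet_loss([g2], w2) == pytest.approx(base)


def test_listnet_learns_separable_direction():
    group = make_group([2, 1, 0], features=[[2.0], [1.0], [0.0]])
    model = fit_listnet([group], epochs=300, seed=0)
    assert model.w[0] > 0


def test_listnet_skips_single_item_groups():
    solo = make_group([3], features=[[1.0]])
    pair = make_group([1, 0], features=[[1.0], [0.0]])
    model = fit_listnet([solo, pair], epochs=50, seed=0)
    assert model.fitted
    with pytest.raises(InvalidInputError):
        fit_listnet([solo])


# ---------------------------------------------------------------------------
# SVR baseline

def test_svr_exact_fit_on_linear_toy():
    grades = np.array([0, 1, 2, 3, 4])
    group = make_group(grades, features=grades[:, None].astype(float))
    model = fit_svr_baseline([group], {"kernel": "linear", "epsilon": 0.0, "C": 100.0})
    pred = model.score(group.features)
    assert np.allclose(pred, grades, atol=0.05)


def test_svr_rejects_constant_grades():
    with pytest.raises(InvalidInputError):
        fit_svr_baseline([make_group([2, 2, 2])])


def test_svr_rbf_beats_random_scoring():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(30, 4))
    w_true = rng.normal(size=4)
    raw = X @ w_true
    grades = np.digitize(raw, np.quantile(raw, [0.3, 0.55, 0.75, 0.9]))
    group = RankingGroup("q", X, grades, [f"c{i:02d}" for i in range(30)])
    model = fit_svr_baseline([group])
    scores = model.score(X)
    order = rank_order(group.compound_ids, scores)
    fitted_ndcg = ndcg_at_k([int(grades[i]) for i in order], 10)
    rand_ndcgs = []
    for _ in range(100):
        perm = rng.permutation(30)
        rand_ndcgs.append(ndcg_at_k([int(grades[i]) for i in perm], 10))
    assert fitted_ndcg > np.percentile(rand_ndcgs, 95)


# ---------------------------------------------------------------------------
# shared contracts

ALL_FITTERS = {
    "prank": lambda gs: fit_prank(gs, epochs=10, seed=1),
    "ranknet": lambda gs: fit_ranknet(gs, epochs=20, seed=1),
    "rankboost": lambda gs: fit_rankboost(gs, rounds=10, seed=1),
    "svmrank": lambda gs: fit_svmrank(gs, seed=1),
    "adarank": lambda gs: fit_adarank(gs, rounds=10),
    "listnet": lambda gs: fit_listnet(gs, epochs=20, seed=1),
    "svr_baseline": lambda gs: fit_svr_baseline(gs),
}


@pytest.mark.parametrize("name", sorted(ALL_FITTERS))
def test_fitters_reproducible_and_serializable(name, tmp_path):
    rng = np.random.default_rng(13)
    groups = [random_group(rng, n=12, dim=4, target_id=f"q{i}") for i in range(3)]
    m1 = ALL_FITTERS[name](groups)
    m2 = ALL_FITTERS[name](groups)
    X = np.random.default_rng(14).normal(size=(6, 4))
    assert np.array_equal(m1.score(X), m2.score(X))
    # JSON round-trip is bit-faithful for scoring
    path = tmp_path / f"{name}.json"
    m1.save_json(path)
    m3 = RankerModel.load_json(path)
    assert np.array_equal(m1.score(X), m3.score(X))


def test_score_groups_deterministic_and_matches_dot_product():
    rng = np.random.default_rng(15)
    groups = [random_group(rng, n=8, dim=3, target_id=f"q{i}") for i in range(2)]
    model = fit_listnet(groups, epochs=10, seed=0)
    s1 = score_groups(model, groups)
    s2 = score_groups(model, groups)
    for tid in s1:
        assert np.array_equal(s1[tid], s2[tid])
    for g in groups:
        assert np.allclose(s1[g.target_id], g.features @ model.w)


def test_score_dimension_mismatch_rejected():
    group = make_group([1, 0], features=[[1.0], [0.0]])
    model = fit_listnet([group], epochs=5, seed=0)
    with pytest.raises(InvalidInputError):
        model.score(np.ones((2, 3)))


def test_fit_ranker_dispatch_unknown_name():
    with pytest.raises(InvalidInputError):
        fit_ranker("nonsense", [make_group([1, 0])])


@pytest.mark.parametrize("name", PAIRWISE_ALGORITHMS)
def test_pairwise_fitters_invariant_to_monotone_label_transforms(name):
    """Strictly increasing per-query grade transforms leave pair sets, and
    hence fitted pairwise models at fixed seed, unchanged."""
    rng = np.random.default_rng(16)
    groups = [random_group(rng, n=10, dim=3, target_id=f"q{i}") for i in range(3)]
    transformed = [
        RankingGroup(g.target_id, g.features, g.grades * 2 + 1, g.compound_ids)
        for g in groups
    ]
    for g, t in zip(groups, transformed):
        assert [(p.preferred_index, p.other_index) for p in enumerate_pairs(g)] == [
            (p.preferred_index, p.other_index) for p in enumerate_pairs(t)
        ]
    fitter = ALL_FITTERS[name]
    m1, m2 = fitter(groups), fitter(transformed)
    X = np.random.default_rng(17).normal(size=(5, 3))
    assert np.array_equal(m1.score(X), m2.score(X))
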