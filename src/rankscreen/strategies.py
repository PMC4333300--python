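"""The four cross-validation / cross-target experiment strategies.

Each strategy is a seeded, reproducible runner over a
:class:`~rankscreen.core_data.RankingDataset`:

* Strategy I   : per-target 5-fold cross-validation (the classical
  "known ligands for this target" screening scenario), every algorithm
  compared against the SVR baseline.
* Strategy II  : leave-one-target-out -- train on all other targets,
  test on the held-out one, using the *same* per-target test partitions
  as Strategy I so the two are directly comparable.
* Strategy III : like II but training is restricted to the held-out
  target's protein-family members (tests whether phylogenetic relatedness
  helps cross-target screening); test partitions identical to II.
* Strategy IV  : heterogeneous-data integration -- targets measured on
  different affinity scales (pIC50 vs pKi) are harmonized per target,
  then leave-one-target-out models are trained and evaluated under both
  the concatenation and the cross-term (Kronecker) feature mappings.

Test partitions are derived from (seed, target index) only, so strategies
run at the same seed share them exactly.  No test (target, compound)
instance ever appears in its own training set; every runner asserts this.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_data import InvalidInputError, RankingDataset, harmonize_labels
from .evaluation import RankedList
from .featurization import FeatureScaler, compound_descriptors, ctd_features, map_pair
from .rankers import RankingGroup, fit_ranker

logger = logging.getLogger(__name__)


@dataclass
class StrategyConfig:
    """Configuration shared by the strategy runners."""

    strategy: str = "I"
    algorithms: Tuple[str, ...] = ("svmrank",)
    mapping: str = "concat"
    k: int = 10
    folds: int = 5
    seed: int = 0
    family_map: Optional[Dict[str, str]] = None
    standardize: bool = True
    algorithm_params: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy == "I" and self.folds < 2:
            raise InvalidInputError("Strategy I requires folds >= 2")


@dataclass
class StrategyReport:
    """Results of one strategy run.

    ``results[algorithm][target_id]`` holds the per-part NDCG@k values and
    their mean; Strategy IV uses algorithm keys suffixed with the mapping
    (e.g. ``svmrank_cross_term``).
    """

    strategy: str
    k: int
    seed: int
    results: Dict[str, Dict[str, dict]] = field(default_factory=dict)

    def mean(self, algorithm: str) -> float:
        per_target = self.results[algorithm]
        return float(np.mean([v["ndcg"] for v in per_target.values()]))

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "k": self.k,
            "seed": self.seed,
            "results": self.results,
            "mean_per_algorithm": {a: self.mean(a) for a in self.results},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["algorithm", "target_id", f"ndcg_at_{self.k}"])
            for alg in sorted(self.results):
                for tid in sorted(self.results[alg]):
                    writer.writerow(
                        [alg, tid, f"{self.results[alg][tid]['ndcg']:.6g}"]
                    )


# ---------------------------------------------------------------------------
# featurization plumbing

def build_groups(
    dataset: RankingDataset, mapping: str = "concat"
) -> Dict[str, RankingGroup]:
    """Featurize a dataset into one RankingGroup per target (sorted ids)."""
    tmap = dataset.target_map
    cmap = dataset.compound_map
    ctd_cache = {tid: ctd_features(t.sequence) for tid, t in tmap.items()}
    desc_cache = {cid: compound_descriptors(c) for cid, c in cmap.items()}
    groups: Dict[str, RankingGroup] = {}
    for tid, recs in sorted(dataset.affinities_by_target().items()):
        if not recs:
            continue
        recs = sorted(recs, key=lambda r: r.compound_id)
        t_vec = ctd_cache[tid]
        rows = [map_pair(t_vec, desc_cache[r.compound_id], mapping) for r in recs]
        groups[tid] = RankingGroup(
            target_id=tid,
            features=np.asarray(rows),
            grades=np.array([r.grade for r in recs], dtype=int),
            compound_ids=[r.compound_id for r in recs],
        )
    return groups


def stratified_folds(
    grades: Sequence[int], n_folds: int, rng: np.random.Generator
) -> List[np.ndarray]:
    """Grade-stratified fold assignment with seeded shuffling.

    Within every grade the indices are shuffled and dealt round-robin, so
    per-grade counts differ by at most 1 across folds.
    """
    grades = np.asarray(grades)
    folds: List[List[int]] = [[] for _ in range(n_folds)]
    start = 0
    for g in sorted(set(grades.tolist())):
        idx = np.flatnonzero(grades == g)
        idx = idx[rng.permutation(len(idx))]
        for offset, i in enumerate(idx):
            folds[(start + offset) % n_folds].append(int(i))
        start += len(idx)  # rotate the dealing start so folds stay balanced
    return [np.array(sorted(f), dtype=int) for f in folds]


def _target_rng(seed: int, target_index: int) -> np.random.Generator:
    # partitions depend only on (seed, target index): strategies at the same
    # seed share their test parts exactly
    return np.random.default_rng(np.random.SeedSequence([seed, target_index]))


def _fit_seed(seed: int, *parts: int) -> int:
    return int(
        np.random.SeedSequence([seed, *parts]).generate_state(1)[0] % (2**31 - 1)
    )


def _subgroup(group: RankingGroup, idx: np.ndarray) -> RankingGroup:
    return RankingGroup(
        target_id=group.target_id,
        features=group.features[idx],
        grades=group.grades[idx],
        compound_ids=[group.compound_ids[i] for i in idx],
    )


def _scaled(
    train_groups: List[RankingGroup],
    test_group: RankingGroup,
    standardize: bool,
) -> Tuple[List[RankingGroup], RankingGroup]:
    if not standardize:
        return train_groups, test_group
    X = np.vstack([g.features for g in train_groups])
    scaler = FeatureScaler().fit(X)
    train_s = [
        RankingGroup(g.target_id, scaler.transform(g.features), g.grades, g.compound_ids)
        for g in train_groups
    ]
    test_s = RankingGroup(
        test_group.target_id,
        scaler.transform(test_group.features),
        test_group.grades,
        test_group.compound_ids,
    )
    return train_s, test_s


def _assert_no_leakage(
    train_groups: Sequence[RankingGroup], test_group: RankingGroup
) -> None:
    test_pairs = {(test_group.target_id, c) for c in test_group.compound_ids}
    train_pairs = {
        (g.target_id, c) for g in train_groups for c in g.compound_ids
    }
    if test_pairs & train_pairs:
        raise RuntimeError(
            f"train/test leakage for target {test_group.target_id!r}"
        )


def _ndcg(model, group: RankingGroup, k: int) -> float:
    scores = model.score(group.features)
    return RankedList.from_scores(group.compound_ids, scores, group.grades).ndcg(k)


def _fit(algorithm: str, train_groups, config: StrategyConfig, fit_seed: int):
    params = dict(config.algorithm_params.get(algorithm, {}))
    if algorithm not in ("adarank", "svr_baseline"):
        params.setdefault("seed", fit_seed)
    if algorithm == "adarank":
        params.setdefault("k", config.k)
    return fit_ranker(algorithm, train_groups, **params)


# ---------------------------------------------------------------------------
# strategy runners

def run_strategy_one(
    dataset: RankingDataset, config: StrategyConfig
) -> StrategyReport:
    """Per-target k-fold cross-validation for each algorithm."""
    groups = build_groups(dataset, config.mapping)
    report = StrategyReport(strategy="I", k=config.k, seed=config.seed)
    target_ids = sorted(groups)
    for ai, alg in enumerate(config.algorithms):
        report.results[alg] = {}
        for ti, tid in enumerate(target_ids):
            group = groups[tid]
            if len(group) < config.folds:
                logger.warning(
                    "target %s has %d < %d compounds; skipped", tid, len(group), config.folds
                )
                continue
            folds = stratified_folds(group.grades, config.folds, _target_rng(config.seed, ti))
            per_fold = []
            for fi, test_idx in enumerate(folds):
                train_idx = np.array(
                    sorted(set(range(len(group))) - set(test_idx.tolist())), dtype=int
                )
                train_g = _subgroup(group, train_idx)
                test_g = _subgroup(group, test_idx)
                train_s, test_s = _scaled([train_g], test_g, config.standardize)
                model = _fit(alg, train_s, config, _fit_seed(config.seed, ai, ti, fi))
                per_fold.append(_ndcg(model, test_s, config.k))
            report.results[alg][tid] = {
                "per_fold": per_fold,
                "ndcg": float(np.mean(per_fold)),
            }
    return report


def _held_out_parts(
    group: RankingGroup, config: StrategyConfig, target_index: int
) -> List[np.ndarray]:
    return stratified_folds(
        group.grades, config.folds, _target_rng(config.seed, target_index)
    )


def _loto_eval(
    groups: Dict[str, RankingGroup],
    train_ids: List[str],
    test_id: str,
    target_index: int,
    config: StrategyConfig,
    alg: str,
    alg_index: int,
) -> dict:
    """Train on ``train_ids`` groups, evaluate on the held-out target's parts."""
    train_groups = [groups[t] for t in train_ids]
    test_group = groups[test_id]
    _assert_no_leakage(train_groups, test_group)
    train_s, test_s = _scaled(train_groups, test_group, config.standardize)
    model = _fit(alg, train_s, config, _fit_seed(config.seed, alg_index, target_index))
    parts = _held_out_parts(test_group, config, target_index)
    per_part = []
    for idx in parts:
        if len(idx) == 0:
            continue
        per_part.append(_ndcg(model, _subgroup(test_s, idx), config.k))
    return {"per_fold": per_part, "ndcg": float(np.mean(per_part))}


def run_strategy_two(
    dataset: RankingDataset, config: StrategyConfig
) -> StrategyReport:
    """Leave-one-target-out screening on novel targets.

    For each target, one model is trained on every other target's group and
    evaluated on the held-out target's compounds, split into the same seeded
    parts used by Strategy I, averaging NDCG@k over the parts.
    """
    groups = build_groups(dataset, config.mapping)
    target_ids = sorted(groups)
    if len(target_ids) < 2:
        raise InvalidInputError("leave-one-target-out requires >= 2 targets")
    report = StrategyReport(strategy="II", k=config.k, seed=config.seed)
    for ai, alg in enumerate(config.algorithms):
        report.results[alg] = {}
        for ti, tid in enumerate(target_ids):
            train_ids = [t for t in target_ids if t != tid]
            report.results[alg][tid] = _loto_eval(
                groups, train_ids, tid, ti, config, alg, ai
            )
    return report


def run_strategy_three(
    dataset: RankingDataset, config: StrategyConfig
) -> StrategyReport:
    """Family-restricted cross-target screening.

    Training uses only targets from the same protein family as the test
    target (test target excluded); test partitions are identical to
    Strategy II at the same seed.
    """
    if not config.family_map:
        raise InvalidInputError("Strategy III requires a family map")
    groups = build_groups(dataset, config.mapping)
    target_ids = sorted(groups)
    report = StrategyReport(strategy="III", k=config.k, seed=config.seed)
    families = config.family_map
    testable = []
    for tid in target_ids:
        fam = families.get(tid)
        if fam is None:
            raise InvalidInputError(f"family map missing target {tid!r}")
        members = [t for t in target_ids if families.get(t) == fam and t != tid]
        if members:
            testable.append((tid, members))
        else:
            logger.warning("target %s: no other family member; skipped", tid)
    if not testable:
        raise InvalidInputError("no target has another family member to train on")
    for ai, alg in enumerate(config.algorithms):
        report.results[alg] = {}
        for tid, members in testable:
            ti = target_ids.index(tid)
            report.results[alg][tid] = _loto_eval(
                groups, members, tid, ti, config, alg, ai
            )
    return report


def run_strategy_four(
    dataset: RankingDataset, config: StrategyConfig
) -> StrategyReport:
    """Heterogeneous-data integration with both feature mappings.

    Per-target measurement scales may differ (pIC50 vs pKi); labels are
    harmonized per target, then for each target a model (svmrank by default)
    is trained on all other targets' groups -- mixed scales included -- and
    evaluated on the full held-out group, once under the concatenation
    mapping and once under the cross-term mapping.
    """
    dataset = harmonize_labels(dataset)
    target_ids = sorted(t.target_id for t in dataset.targets)
    if len(target_ids) < 3:
        raise InvalidInputError("Strategy IV requires >= 3 targets")
    report = StrategyReport(strategy="IV", k=config.k, seed=config.seed)
    for mi, mapping in enumerate(("concat", "cross_term")):
        groups = build_groups(dataset, mapping)
        for ai, alg in enumerate(config.algorithms):
            key = f"{alg}_{mapping}"
            report.results[key] = {}
            for ti, tid in enumerate(target_ids):
                train_groups = [groups[t] for t in target_ids if t != tid]
                test_group = groups[tid]
                _assert_no_leakage(train_groups, test_group)
                train_s, test_s = _scaled(
                    train_groups, test_group, config.standardize
                )
                model = _fit(
                    alg, train_s, config, _fit_seed(config.seed, mi, ai, ti)
                )
                val = _ndcg(model, test_s, config.k)
                report.results[key][tid] = {"per_fold": [val], "ndcg": val}
    return report


RUNNERS = {
    "I": run_strategy_one,
    "II": run_strategy_two,
    "III": run_strategy_three,
    "IV": run_strategy_four,
}


def run_strategy(dataset: RankingDataset, config: StrategyConfig) -> StrategyReport:
    if config.strategy not in RUNNERS:
        raise InvalidInputError(f"unknown strategy {config.strategy!r}")
    return RUNNERS[config.strategy](dataset, config)
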