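"""Ranking quality metrics: DCG@k and NDCG@k.

For a ranked list whose item at position r (1-based) carries an integer
relevance grade y(r),

    DCG@k  = sum_{r=1..min(k, n)} (2^y(r) - 1) / log2(1 + r)
    NDCG@k = DCG@k(predicted order) / DCG@k(ideal order)

where the ideal order sorts grades descending.  NDCG@k is 1.0 exactly when
the predicted order's grade sequence matches an ideal one through position
min(k, n).  A query whose grades are all zero has ideal DCG 0 and is scored
0 by convention (it carries no ranking signal and must not inflate means).

Ties in predicted scores are broken deterministically: stable sort by
descending score, then by compound id lexicographically.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core_data import InvalidInputError


def dcg_at_k(grades_in_predicted_order: Sequence[int], k: int) -> float:
    """Discounted cumulative gain truncated at position k."""
    if k < 1:
        raise InvalidInputError(f"k must be >= 1, got {k}")
    total = 0.0
    for r, y in enumerate(grades_in_predicted_order[:k], start=1):
        if y < 0:
            raise InvalidInputError(f"grades must be non-negative, got {y}")
        total += (2.0 ** y - 1.0) / np.log2(1.0 + r)
    return total


def ndcg_at_k(grades_in_predicted_order: Sequence[int], k: int = 10) -> float:
    """Normalized DCG of a grade sequence given in predicted order."""
    grades = list(grades_in_predicted_order)
    if not grades:
        raise InvalidInputError("cannot compute NDCG of an empty list")
    ideal = dcg_at_k(sorted(grades, reverse=True), k)
    if ideal == 0.0:
        return 0.0
    return dcg_at_k(grades, k) / ideal


def rank_order(
    compound_ids: Sequence[str], scores: Sequence[float]
) -> List[int]:
    """Indices sorted by descending score; ties by compound id."""
    if len(compound_ids) != len(scores):
        raise InvalidInputError("compound_ids and scores length mismatch")
    return sorted(
        range(len(scores)), key=lambda i: (-float(scores[i]), compound_ids[i])
    )


@dataclass(frozen=True)
class RankedList:
    """One query's items ordered by descending predicted score."""

    items: Tuple[Tuple[str, float, int], ...]  # (compound_id, score, grade)

    @classmethod
    def from_scores(
        cls,
        compound_ids: Sequence[str],
        scores: Sequence[float],
        grades: Sequence[int],
    ) -> "RankedList":
        order = rank_order(compound_ids, scores)
        return cls(
            items=tuple(
                (compound_ids[i], float(scores[i]), int(grades[i])) for i in order
            )
        )

    def ndcg(self, k: int = 10) -> float:
        return ndcg_at_k([g for _, _, g in self.items], k)


@dataclass
class EvalReport:
    """Per-query NDCG@k values and their arithmetic mean."""

    k: int
    per_query: Dict[str, float] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        if not self.per_query:
            raise InvalidInputError("empty evaluation report")
        return float(np.mean(list(self.per_query.values())))

    def to_dict(self) -> dict:
        return {"k": self.k, "per_query": dict(self.per_query), "mean": self.mean}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["target_id", f"ndcg_at_{self.k}"])
            for tid in sorted(self.per_query):
                writer.writerow([tid, f"{self.per_query[tid]:.6g}"])


def evaluate_model(model, groups, k: int = 10) -> EvalReport:
    """Score each group with a fitted ranker and report per-query NDCG@k.

    ``groups`` is a sequence of :class:`rankscreen.rankers.RankingGroup`.
    Sorting is deterministic (descending score, ties by compound id).
    """
    if not getattr(model, "fitted", False):
        raise InvalidInputError("model is not fitted")
    report = EvalReport(k=k)
    for group in groups:
        if len(group.grades) == 0:
            raise InvalidInputError(f"empty group {group.target_id!r}")
        scores = model.score(group.features)
        ranked = RankedList.from_scores(group.compound_ids, scores, group.grades)
        report.per_query[group.target_id] = ranked.ndcg(k)
    return report
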