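"""Data model, affinity grading, and dataset curation.

Affinity values are on the -log10 molar scale (pIC50 / pKi / pKd; higher
means stronger binding).  Affinities are discretized into five relevance
grades used as ranking labels:

    grade 0 : value <  6        (inactive)
    grade 1 : 6 <= value < 7
    grade 2 : 7 <= value < 8
    grade 3 : 8 <= value < 9
    grade 4 : value >= 9

A compound is called *active* when its value is at least 6, i.e. exactly
when its grade is at least 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

logger = logging.getLogger(__name__)

#: the 20 canonical amino-acid one-letter codes
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: accepted affinity measurement types (all on the -log10 molar scale)
MEASUREMENT_TYPES = ("pIC50", "pKi", "pKd")

#: grade boundaries; intervals are half-open [a, b), boundary -> higher grade
GRADE_BOUNDARIES = (6.0, 7.0, 8.0, 9.0)

#: activity threshold on the -log10 molar scale
ACTIVITY_THRESHOLD = 6.0


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


def validate_sequence(sequence: str, *, surrogate: Optional[str] = None) -> str:
    """Validate (and optionally repair) an amino-acid sequence.

    Non-canonical letters (B, Z, X, U, O, ...) are rejected unless a
    one-letter ``surrogate`` is supplied, in which case they are replaced
    by it.  The sequence groups used by the protein features are defined
    only for the 20 canonical residues.
    """
    if not sequence:
        raise InvalidInputError("sequence must be non-empty")
    seq = sequence.upper()
    bad = set(seq) - CANONICAL_RESIDUES
    if bad:
        if surrogate is None:
            raise InvalidInputError(
                f"non-canonical residues {sorted(bad)}; supply a surrogate "
                "residue to map them"
            )
        if surrogate not in CANONICAL_RESIDUES:
            raise InvalidInputError(f"surrogate {surrogate!r} is not canonical")
        seq = "".join(surrogate if c in bad else c for c in seq)
    return seq


@dataclass(frozen=True)
class TargetRecord:
    """A protein target: identifier, sequence, optional family label."""

    target_id: str
    sequence: str
    family: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))


@dataclass(frozen=True)
class CompoundRecord:
    """A compound: identifier, optional SMILES, fixed-length descriptor."""

    compound_id: str
    descriptor: tuple
    smiles: Optional[str] = None

    def __post_init__(self) -> None:
        desc = tuple(float(v) for v in self.descriptor)
        if not all(math.isfinite(v) for v in desc):
            raise InvalidInputError(
                f"compound {self.compound_id}: descriptor entries must be finite"
            )
        object.__setattr__(self, "descriptor", desc)


def grade_affinity(value: float) -> int:
    """Discretize a -log10 molar affinity into a relevance grade 0-4."""
    if not math.isfinite(value):
        raise InvalidInputError(f"affinity value must be finite, got {value!r}")
    grade = 0
    for boundary in GRADE_BOUNDARIES:
        if value >= boundary:
            grade += 1
    return grade


def label_active(value: float) -> bool:
    """True iff the compound counts as active (value >= 6)."""
    if not math.isfinite(value):
        raise InvalidInputError(f"affinity value must be finite, got {value!r}")
    return value >= ACTIVITY_THRESHOLD


@dataclass(frozen=True)
class AffinityRecord:
    """One measured target-compound affinity with its derived grade."""

    target_id: str
    compound_id: str
    measurement: str
    value: float
    grade: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.measurement not in MEASUREMENT_TYPES:
            raise InvalidInputError(
                f"measurement must be one of {MEASUREMENT_TYPES}, "
                f"got {self.measurement!r}"
            )
        if self.grade == -1:
            object.__setattr__(self, "grade", grade_affinity(self.value))
        elif self.grade not in (0, 1, 2, 3, 4):
            raise InvalidInputError(f"grade must be in 0..4, got {self.grade}")


@dataclass
class RankingDataset:
    """Targets, compounds, and the affinity records linking them."""

    targets: List[TargetRecord]
    compounds: List[CompoundRecord]
    affinities: List[AffinityRecord]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        target_ids = {t.target_id for t in self.targets}
        compound_ids = {c.compound_id for c in self.compounds}
        if len(target_ids) != len(self.targets):
            raise InvalidInputError("duplicate target ids")
        if len(compound_ids) != len(self.compounds):
            raise InvalidInputError("duplicate compound ids")
        seen = set()
        for rec in self.affinities:
            if rec.target_id not in target_ids:
                raise InvalidInputError(f"unknown target {rec.target_id!r}")
            if rec.compound_id not in compound_ids:
                raise InvalidInputError(f"unknown compound {rec.compound_id!r}")
            key = (rec.target_id, rec.compound_id)
            if key in seen:
                raise InvalidInputError(f"duplicate affinity record {key}")
            seen.add(key)

    @property
    def target_map(self) -> Dict[str, TargetRecord]:
        return {t.target_id: t for t in self.targets}

    @property
    def compound_map(self) -> Dict[str, CompoundRecord]:
        return {c.compound_id: c for c in self.compounds}

    def affinities_by_target(self) -> Dict[str, List[AffinityRecord]]:
        out: Dict[str, List[AffinityRecord]] = {t.target_id: [] for t in self.targets}
        for rec in self.affinities:
            out[rec.target_id].append(rec)
        return out


def dedupe_affinities(records: Sequence[AffinityRecord]) -> List[AffinityRecord]:
    """Collapse duplicate (target, compound) rows, keeping the first seen."""
    seen = set()
    out = []
    dropped = 0
    for rec in records:
        key = (rec.target_id, rec.compound_id)
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        out.append(rec)
    if dropped:
        logger.warning("dropped %d duplicate target-compound affinity rows", dropped)
    return out


@dataclass(frozen=True)
class CurationConfig:
    """Rules for benchmark-style target selection.

    ``min_ligands``/``max_ligands`` bound the non-redundant ligand count per
    target (both None by default: no window is enforced).
    ``drop_low_grades_only`` removes targets whose compounds cover only
    grades {0, 1}.  ``min_top_grade_fraction`` removes targets where the
    highest observed grade accounts for less than that fraction of records.
    """

    min_ligands: Optional[int] = None
    max_ligands: Optional[int] = None
    drop_low_grades_only: bool = True
    min_top_grade_fraction: float = 0.05


def apply_curation_filters(
    dataset: RankingDataset, rules: CurationConfig = CurationConfig()
) -> RankingDataset:
    """Retain only targets passing all configured curation rules.

    Duplicate (target, compound) rows are collapsed first (keep-first).
    Idempotent: filtering a filtered dataset is a no-op.
    """
    if not dataset.targets and not dataset.affinities:
        logger.warning("apply_curation_filters called on an empty dataset")
        return RankingDataset(targets=[], compounds=[], affinities=[])

    records = dedupe_affinities(dataset.affinities)
    by_target: Dict[str, List[AffinityRecord]] = {}
    for rec in records:
        by_target.setdefault(rec.target_id, []).append(rec)

    kept_targets = []
    for target in dataset.targets:
        recs = by_target.get(target.target_id, [])
        n = len(recs)
        if rules.min_ligands is not None and n < rules.min_ligands:
            continue
        if rules.max_ligands is not None and n > rules.max_ligands:
            continue
        if not recs:
            continue
        grades = [r.grade for r in recs]
        if rules.drop_low_grades_only and set(grades) <= {0, 1}:
            continue
        top = max(grades)
        frac = grades.count(top) / n
        if frac < rules.min_top_grade_fraction:
            continue
        kept_targets.append(target)

    kept_ids = {t.target_id for t in kept_targets}
    kept_records = [r for r in records if r.target_id in kept_ids]
    kept_compound_ids = {r.compound_id for r in kept_records}
    kept_compounds = [c for c in dataset.compounds if c.compound_id in kept_compound_ids]
    return RankingDataset(
        targets=kept_targets, compounds=kept_compounds, affinities=kept_records
    )


def harmonize_labels(dataset: RankingDataset) -> RankingDataset:
    """Grade each target on its own measurement scale.

    Different targets may be measured on different platforms (pIC50 vs pKi
    vs pKd); grading is applied per target to its own values, so records are
    comparable within a target while no cross-target value comparison is
    made.  A target mixing measurement types has no unambiguous internal
    ordering and is rejected.
    """
    by_target: Dict[str, set] = {}
    for rec in dataset.affinities:
        by_target.setdefault(rec.target_id, set()).add(rec.measurement)
    mixed = sorted(t for t, kinds in by_target.items() if len(kinds) > 1)
    if mixed:
        raise InvalidInputError(
            f"targets with mixed measurement types: {mixed}; grade ordering "
            "would be ambiguous"
        )
    regraded = [
        replace(rec, grade=grade_affinity(rec.value)) for rec in dataset.affinities
    ]
    return RankingDataset(
        targets=list(dataset.targets),
        compounds=list(dataset.compounds),
        affinities=regraded,
    )
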