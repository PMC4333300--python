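"""Target and compound feature vectors and the pair feature mappings.

Proteins are represented by composition/transition/distribution (CTD)
sequence features: 7 physicochemical properties x (3 composition + 3
transition + 15 distribution) = 147 values.  Compounds are represented by a
fixed 32-dimensional descriptor vector, either supplied precomputed or
computed from SMILES with RDKit.

A target-compound pair (T, C) is mapped to a single feature vector x by one
of two feature functions:

* ``concat``     : x = [T ; C], length 147 + 32 = 179
* ``cross_term`` : x = T (x) C, the Kronecker product, length 147 x 32 = 4704
  (target-major: entry i*32 + j equals T[i] * C[j])

The cross-term mapping encodes multiplicative target-compound interactions,
which is what lets a linear ranker express target-specific compound
preferences.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .core_data import CANONICAL_RESIDUES, CompoundRecord, InvalidInputError

logger = logging.getLogger(__name__)

CTD_DIM = 147
COMPOUND_DIM = 32
CONCAT_DIM = CTD_DIM + COMPOUND_DIM      # 179
CROSS_TERM_DIM = CTD_DIM * COMPOUND_DIM  # 4704

MAPPINGS = ("concat", "cross_term")

#: unordered group pairs, in transition-feature order
_TRANSITION_PAIRS = ((1, 2), (1, 3), (2, 3))

#: distribution percentiles; "first occurrence" then quartiles of occupancy
_DISTRIBUTION_FRACTIONS = (0.0, 0.25, 0.50, 0.75, 1.0)


def _load_ctd_tables() -> List[Tuple[str, Tuple[str, str, str]]]:
    raw = json.loads(
        resources.files("rankscreen").joinpath("data/ctd_groups.json").read_text()
    )
    tables = []
    for prop in raw["properties"]:
        groups = tuple(prop["groups"])
        covered = set("".join(groups))
        if covered != CANONICAL_RESIDUES or len(groups) != 3:
            raise RuntimeError(f"bad CTD group table for {prop['name']}")
        tables.append((prop["name"], groups))
    return tables


CTD_PROPERTIES = _load_ctd_tables()

#: residue -> group index (1..3) lookup per property
_GROUP_OF = [
    {res: g + 1 for g, members in enumerate(groups) for res in members}
    for _, groups in CTD_PROPERTIES
]


def ctd_feature_names() -> List[str]:
    """Feature names in the exact output order of :func:`ctd_features`."""
    names = []
    for prop_name, _ in CTD_PROPERTIES:
        names += [f"{prop_name}.C{g}" for g in (1, 2, 3)]
        names += [f"{prop_name}.T{a}{b}" for a, b in _TRANSITION_PAIRS]
        for g in (1, 2, 3):
            names += [
                f"{prop_name}.D{g}.{p}"
                for p in ("first", "25pct", "50pct", "75pct", "100pct")
            ]
    return names


def ctd_features(sequence: str) -> np.ndarray:
    """Compute the 147-dimensional CTD feature vector of a protein sequence.

    Per property the residues are mapped into 3 groups and the vector holds,
    in order: 3 composition values (group fraction of length L), 3 transition
    frequencies (adjacent-pair group changes for the unordered pairs (1,2),
    (1,3), (2,3), divided by L-1), and 15 distribution values (per group, the
    1-based positions of the first, 25%, 50%, 75% and 100% occurrences, each
    divided by L and expressed as a percentage; 0 for absent groups).
    """
    seq = sequence.upper()
    L = len(seq)
    if L < 2:
        raise InvalidInputError("sequence must have length >= 2")
    bad = set(seq) - CANONICAL_RESIDUES
    if bad:
        raise InvalidInputError(f"non-canonical residues {sorted(bad)}")

    out = np.empty(CTD_DIM, dtype=float)
    pos = 0
    for group_of in _GROUP_OF:
        codes = [group_of[c] for c in seq]
        # composition
        counts = [0, 0, 0]
        for g in codes:
            counts[g - 1] += 1
        for g in range(3):
            out[pos] = counts[g] / L
            pos += 1
        # transition
        trans = {pair: 0 for pair in _TRANSITION_PAIRS}
        for a, b in zip(codes, codes[1:]):
            if a != b:
                trans[(min(a, b), max(a, b))] += 1
        for pair in _TRANSITION_PAIRS:
            out[pos] = trans[pair] / (L - 1)
            pos += 1
        # distribution
        positions = {1: [], 2: [], 3: []}
        for i, g in enumerate(codes, start=1):
            positions[g].append(i)
        for g in (1, 2, 3):
            occ = positions[g]
            n_g = len(occ)
            if n_g == 0:
                out[pos : pos + 5] = 0.0
                pos += 5
                continue
            for frac in _DISTRIBUTION_FRACTIONS:
                idx = 1 if frac == 0.0 else math.ceil(frac * n_g)
                out[pos] = occ[idx - 1] / L * 100.0
                pos += 1
    return out


# ---------------------------------------------------------------------------
# compound descriptors

#: the built-in open 32-descriptor set computed from SMILES.  It covers the
#: four aspects of the classic "general descriptor" block -- surface area,
#: logP, molar refractivity and partial charge -- padded with standard
#: constitutional and topological descriptors to 32.
DESCRIPTOR_NAMES_32 = (
    "TPSA", "LabuteASA",
    "MolLogP", "MolMR",
    "MaxPartialCharge", "MinPartialCharge",
    "MaxAbsPartialCharge", "MinAbsPartialCharge",
    "MolWt", "ExactMolWt", "HeavyAtomCount", "NumHeteroatoms",
    "NumValenceElectrons", "NumHAcceptors", "NumHDonors",
    "NumRotatableBonds", "RingCount", "NumAromaticRings",
    "NumSaturatedRings", "NumAliphaticRings", "FractionCSP3",
    "NOCount", "NHOHCount",
    "BertzCT", "BalabanJ", "Chi0", "Chi1", "Chi0v", "Chi1v",
    "Kappa1", "Kappa2", "HallKierAlpha",
)


def descriptors_from_smiles(smiles: str) -> np.ndarray:
    """Compute the built-in 32-descriptor vector from a SMILES string."""
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidInputError(f"unparseable SMILES: {smiles!r}")
    values = np.empty(COMPOUND_DIM, dtype=float)
    for i, name in enumerate(DESCRIPTOR_NAMES_32):
        v = getattr(Descriptors, name)(mol)
        if not math.isfinite(v):
            # single-atom or chargeless edge cases; keep the vector finite
            logger.warning("descriptor %s non-finite for %r; set to 0", name, smiles)
            v = 0.0
        values[i] = v
    return values


def compound_descriptors(
    record: Union[CompoundRecord, str, Sequence[float]]
) -> np.ndarray:
    """Return a compound's 32-dim descriptor vector.

    Accepts a :class:`CompoundRecord` (precomputed descriptor passes through,
    else its SMILES is used), a SMILES string, or a precomputed vector.
    """
    if isinstance(record, CompoundRecord):
        if record.descriptor:
            vec = np.asarray(record.descriptor, dtype=float)
        elif record.smiles:
            return descriptors_from_smiles(record.smiles)
        else:
            raise InvalidInputError(
                f"compound {record.compound_id}: no descriptor and no SMILES"
            )
    elif isinstance(record, str):
        return descriptors_from_smiles(record)
    else:
        vec = np.asarray(record, dtype=float)
    if vec.shape != (COMPOUND_DIM,):
        raise InvalidInputError(
            f"descriptor must have length {COMPOUND_DIM}, got shape {vec.shape}"
        )
    if not np.all(np.isfinite(vec)):
        raise InvalidInputError("descriptor entries must be finite")
    return vec


# ---------------------------------------------------------------------------
# pair feature mappings

@dataclass(frozen=True)
class PairFeature:
    """One featurized target-compound pair."""

    target_id: str
    compound_id: str
    vector: np.ndarray
    mapping: str

    def __post_init__(self) -> None:
        if self.mapping not in MAPPINGS:
            raise InvalidInputError(f"unknown mapping {self.mapping!r}")
        if not np.all(np.isfinite(self.vector)):
            raise InvalidInputError("pair feature entries must be finite")


def map_concat(t_vec: np.ndarray, c_vec: np.ndarray) -> np.ndarray:
    """Concatenate target and compound vectors: [T ; C]."""
    t = np.asarray(t_vec, dtype=float)
    c = np.asarray(c_vec, dtype=float)
    if t.ndim != 1 or c.ndim != 1:
        raise InvalidInputError("inputs must be 1-D vectors")
    return np.concatenate([t, c])


def map_cross_term(t_vec: np.ndarray, c_vec: np.ndarray) -> np.ndarray:
    """Kronecker product T (x) C, target-major.

    Entry i*len(C) + j equals T[i] * C[j].  For the full-size 147- and
    32-dim inputs the result has length 4704.
    """
    t = np.asarray(t_vec, dtype=float)
    c = np.asarray(c_vec, dtype=float)
    if t.ndim != 1 or c.ndim != 1:
        raise InvalidInputError("inputs must be 1-D vectors")
    return np.kron(t, c)


def map_pair(t_vec: np.ndarray, c_vec: np.ndarray, mapping: str) -> np.ndarray:
    if mapping == "concat":
        return map_concat(t_vec, c_vec)
    if mapping == "cross_term":
        return map_cross_term(t_vec, c_vec)
    raise InvalidInputError(f"unknown mapping {mapping!r}")


class FeatureScaler:
    """Column-wise standardization fitted on training data only.

    Each column is centered to mean 0 and scaled to unit standard deviation;
    constant columns are mapped to 0.  The fitted transform is re-applied
    verbatim to test data.
    """

    def __init__(self) -> None:
        self.mean_: Optional[np.ndarray] = None
        self.scale_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise InvalidInputError("standardization requires at least 2 rows")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0.0] = 1.0  # constant columns -> centered to exactly 0
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise InvalidInputError("scaler is not fitted")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def standardize_features(X: np.ndarray) -> Tuple[np.ndarray, FeatureScaler]:
    """Standardize a pair-feature matrix; returns (scaled, fitted scaler)."""
    scaler = FeatureScaler()
    return scaler.fit_transform(X), scaler
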