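# Methods

This note documents the model, the default parameters and their rationale,
the synthetic study conditions, numerical conventions, and known limitations
of `rankscreen`.

## Problem formulation

A *query* is one protein target together with its associated compounds.
Within a query, each compound carries an affinity value on a -log10 molar
scale (pIC50, pKi, or pKd) that is discretized into an integer *grade*:

| grade | value range  |            |
|-------|--------------|------------|
| 0     | value < 6    | inactive   |
| 1     | [6, 7)       | active     |
| 2     | [7, 8)       | active     |
| 3     | [8, 9)       | active     |
| 4     | value >= 9   | active     |

Boundaries are left-closed; a compound is *active* exactly when its grade is
at least 1 (value >= 6).  The learning task is to score compounds so that,
within each query, higher-graded compounds rank above lower-graded ones.

Ranking quality is measured by NDCG@k.  For a ranked list whose item at
1-based position r has grade y(r):

    DCG@k  = sum_{r=1..min(k,n)} (2^y(r) - 1) / log2(1 + r)
    NDCG@k = DCG@k(predicted order) / DCG@k(ideal order)

where the ideal order sorts grades descending.  NDCG@k is exactly 1.0 when
the predicted ordering matches an ideal one through position min(k, n).  A
query whose grades are all zero has ideal DCG 0 and is scored 0 by
convention, so it cannot inflate averages.  The default cutoff is k = 10
(the "how good are the first ten picks" question an experimentalist asks).

## Features

**Targets — CTD (147-dim).**  Seven physicochemical properties
(hydrophobicity, normalized van der Waals volume, polarity, polarizability,
charge, secondary structure, solvent accessibility) each partition the 20
canonical residues into 3 groups.  Per property the feature block is:
3 Composition values (group fraction of sequence length), 3 Transition
frequencies (adjacent-residue group changes for the unordered group pairs
(1,2), (1,3), (2,3), divided by L-1), and 15 Distribution values (for each
group, the 1-based positions of its first, 25%, 50%, 75%, and 100%
occurrences — occurrence index computed as ceil(p * N_g) — divided by L and
expressed as percentages; 0 for absent groups).  7 x (3 + 3 + 15) = 147.
The group tables ship with the package (`data/ctd_groups.json`).

**Compounds — 32-dim descriptors.**  The contract is any fixed, documented
32-vector per compound.  Tables with columns `d01..d32` are used as-is; when
only SMILES are available, a built-in open descriptor set is computed with
RDKit (TPSA, LabuteASA, MolLogP, MolMR, partial-charge statistics, and
constitutional/topological counts — see
`featurization.DESCRIPTOR_NAMES_32`).  Descriptors that RDKit cannot compute
become 0 with a warning.

**Pair mappings.**  A (target, compound) pair becomes one feature vector by

- `concat`: [T ; C], 147 + 32 = 179 dimensions — target and compound enter
  additively, so within one target every compound shift is shared across
  targets;
- `cross_term`: the Kronecker product T (x) C (target-major: entry
  i*32 + j = T[i]*C[j]), 147 x 32 = 4704 dimensions — a linear scorer over
  this space expresses any bilinear interaction T' G C.

Feature standardization (zero mean, unit variance per column; constant
columns map to 0) is fitted on training items only and applied to test
items.

## Ranking algorithms and defaults

All fitters consume `RankingGroup`s (one per query) and emit JSON-serializable
models.  Pair-based methods reduce each query to its *ordered pairs*
(i, j with grade_i > grade_j, enumerated i-ascending then j-ascending; never
across queries).  Defaults were chosen as conventional, stable settings and
are deliberately unexciting; none were tuned to any benchmark outcome.

- **PRank** (point-wise ordinal perceptron): grades 0..K-1 become ranks
  1..K; weight vector plus non-decreasing thresholds, classic additive
  update.  Default 50 epochs (training-error plateau on the synthetic
  benchmark is reached well before that).
- **RankNet** (pair-wise, logistic): minimizes binary cross-entropy of
  sigmoid(f_i - f_j) by gradient descent; linear scorer by default
  (`hidden_units=0`), learning rate 0.01, 200 epochs, seeded shuffling.
- **RankBoost** (pair-wise boosting): threshold weak rankers on single
  features, pair distribution D updated multiplicatively; round weight
  alpha = 0.5 ln((1+r)/(1-r)) with r the weighted ranking correlation,
  capped at +/-(1 - 1e-10).  The per-round search uses the potential
  decomposition pi(i) = sum_j D(i,j) - sum_j D(j,i) and cumulative sums over
  sorted feature values, so a round costs O(d n log n).  Default 100 rounds.
- **SVMRank** (pair-wise max margin): L2-regularized squared-hinge primal
  on pair differences, 0.5||w||^2 + C sum max(0, 1 - w.(x_i - x_j))^2,
  minimized with L-BFGS.  Margins and gradients are evaluated through the
  per-item score vector X w (the pair-difference matrix is never formed), so
  cross-term-dimension fits take seconds.  The objective is convex and the
  start fixed: fits are deterministic.  Defaults C = 1, max 1000 iterations,
  ftol 1e-10.
- **AdaRank** (list-wise boosting): weak rankers are single raw features
  scored by NDCG@k per query; round weight
  alpha = 0.5 ln(sum P(1+E) / sum P(1-E)); query weights re-weighted
  proportional to exp(-ensemble NDCG).  Default 100 rounds, k = 10.
- **ListNet** (list-wise): top-one softmax cross-entropy between score
  softmax and grade softmax, linear scorer, learning rate 0.01, 200 epochs.
- **SVR baseline** (point-wise regression): scikit-learn RBF SVR on
  (feature, value) pairs; serialized as an explicit support-vector expansion
  so JSON round-trips are bit-faithful.

Pair-wise fitters are invariant to strictly increasing per-query label
transformations: the ordered-pair sets, and therefore the fitted models at a
fixed seed, are unchanged.  This is the theoretical basis of Strategy IV.

## Experiment strategies

All strategies share these conventions: per-target fold assignments are
stratified by grade and drawn from `SeedSequence([seed, target_index])`, so
at equal seed Strategies I-III hold out identical parts; fit seeds derive
from the strategy seed; training features never include the evaluated
(target, compound) instances, enforced by a runtime leakage assertion; and
reports are byte-identical across runs at a fixed seed.

- **I — per-target cross-validation** (default 5-fold): within each target,
  train on 4/5 of its compounds, evaluate NDCG@10 on the held-out fifth.
  Targets with fewer compounds than folds are skipped with a warning.
- **II — leave-one-target-out**: train on all other targets' compounds,
  evaluate on the held-out target — the cross-target screening scenario.
- **III — family-restricted**: leave-one-target-out within each protein
  family (requires a family map; families need >= 2 members).
- **IV — heterogeneous integration**: targets may carry different
  measurement types (pIC50/pKi/pKd); labels are harmonized per target
  (mixing types within one target is an error) and leave-one-target-out is
  run under *both* pair mappings, reported as `<algorithm>_concat` and
  `<algorithm>_cross_term`.

## Synthetic benchmark generator

The generator emulates the statistical structure the framework assumes, so
all experiments run without external data.  All randomness flows from one
master seed through named `SeedSequence` streams (targets / compounds /
affinities).

Ground truth is bilinear: target t with latent vector v_t scores compound c
as a = v_t' M_t c + eps, with M_t = f M_shared + (1-f) M_own
(f = `shared_model_fraction`) and eps ~ Normal(0, `noise_sd`).  Raw scores
are rescaled per target onto [4, 11] (affine min-max; a rank-based even
spread is the fallback when affine rescaling leaves one of the 5 grades
unpopulated) and graded.  Per-target rescaling is monotone, so it never
changes within-target order.

Default study conditions (`SyntheticConfig`): 24 targets in 6 families, 40
compounds per target, latent dimension 8, noise 0.5 log units (a typical
inter-assay spread for reported potencies), fully shared interaction model,
sequence lengths 120-400, family jitter 0.3.  Family centers are drawn as a
random orthogonal frame scaled to a common norm sqrt(latent_dim), so every
family carries equal signal strength; members add jitter.

Two sequence regimes:

- **Default** (`latents_from_ctd=False`): sequences are uniform random over
  the 20 canonical residues and carry no information about the latents.
  Cross-target recovery from sequence alone is impossible by construction
  (any linear model's weights lie in the span of its training features, and
  unrelated sequences give that span no purchase on a held-out target) —
  the regime where target-level generalization must fail.
- **Recovery regime** (`latents_from_ctd=True`): each target's residue
  profile is softmax(1.5 B v) of its family latent; the sequence is built
  *deterministically* from the profile (largest-remainder rounding of
  expected counts, canonical-order layout), so the whole CTD vector is a
  deterministic function of the profile; and the operative latent is a fixed
  linear read-out of the realized sequence's 21 composition features,
  centered on the cohort mean.  Consequences, in order: affinities are an
  exact function of the observable features (truly noise-free labels, and —
  because each property's three composition fractions sum to exactly 1 —
  exactly representable by a linear scorer over the cross-term mapping);
  there is no sequence-sampling noise separating a target from its family;
  and centering removes the CTD component shared by all targets, so
  per-target rankings differ across families and a concatenation scorer,
  which can only express one global compound ordering plus per-target
  offsets, is strictly handicapped.  This is the designed condition for the
  ranking-recovery experiments: leave-one-target-out NDCG@10 with
  svmrank/cross_term averages ~0.98 at 24 targets x 40 compounds (seeds 1-3),
  and cross-term beats concat in 20/20 paired seeds at the scaled size.

## Test-suite problem sizes

The acceptance suite runs at sizes chosen to fit a desk-scale runtime budget
while preserving every asserted direction and threshold:

- ranking recovery: the full 24 targets x 40 compounds (noise-free, zero
  jitter, recovery regime), one leave-one-target-out pass (~3 minutes);
- the paired concat-vs-cross-term comparison: 6 targets x 20 compounds over
  20 seeds (~4 minutes);
- invariance and determinism suites: 100 random queries / 6 targets x 20
  compounds respectively (seconds to ~1 minute).

## Numerical conventions

- Ties in predicted scores are broken deterministically: stable sort by
  descending score, then compound id lexicographically.
- CSV reports round to 6 significant digits; JSON reports keep full
  precision.  Data writers emit floats via `repr` and readers parse with
  pandas `float_precision="round_trip"`, so dataset round-trips are
  bit-exact.
- Every CLI run writes a manifest (command, master seed, config digest,
  SHA-256 of each input file).
- Duplicate (target, compound, measurement) affinity rows keep the first
  occurrence, with a warning.

## Limitations

- The six rankers use simple fixed-budget optimizers (perceptron epochs,
  gradient descent, boosting rounds); they are faithful and deterministic,
  not speed-competitive with production LOR libraries.
- The built-in 32-descriptor set is one documented choice, not a canonical
  standard; results depend on the descriptor contract only through the fixed
  dimension.
- The synthetic generator is a study instrument: its bilinear ground truth
  and deterministic recovery regime are designed to make specific
  phenomena observable, not to imitate real binding data.  Conclusions
  about real screening campaigns require real affinity datasets.
- CTD distribution features are nearly uninformative for i.i.d.-generated
  sequences (their sampling noise dominates); on real sequences they carry
  structure.  This is a property of the synthetic data, not of the
  featurizer.
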