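# rankscreen

Learning-to-rank (LOR) for ligand-based virtual screening.

Virtual screening asks: given a protein target and a library of candidate
compounds, which compounds should be tested first?  Classification ("is it
active?") and regression ("what is its pIC50?") both optimize the wrong
objective — what an experimentalist consumes is an *ordering* of the library.
`rankscreen` treats each target together with its compounds as one ranking
query and trains scoring functions that directly optimize ranking quality,
measured by NDCG@k over 5-level affinity grades.

## What is in the box

- **Data model** (`core_data`): targets (protein sequences), compounds
  (32-dim descriptor vectors), and affinity records (pIC50/pKi/pKd).
  Affinities are discretized into 5 grades: 0 (< 6), 1 [6, 7), 2 [7, 8),
  3 [8, 9), 4 (>= 9); a compound is *active* iff its value is >= 6
  (equivalently, grade >= 1).
- **Featurization** (`featurization`): 147-dim CTD
  (Composition/Transition/Distribution) protein sequence features; 32-dim
  compound descriptors (from a descriptor table, or computed from SMILES via
  RDKit); two target-compound pair mappings — concatenation (179-dim) and
  the Kronecker cross-term product (147 x 32 = 4704-dim), which lets a
  linear scorer express multiplicative target-compound interactions.
- **Rankers** (`rankers`): six LOR algorithms spanning the three families —
  point-wise PRank, pair-wise RankNet / RankBoost / SVMRank, list-wise
  AdaRank / ListNet — plus an SVR regression baseline.  All models
  round-trip through JSON.
- **Evaluation** (`evaluation`): DCG@k / NDCG@k with deterministic
  tie-breaking.
- **Experiment strategies** (`strategies`): I per-target 5-fold CV;
  II leave-one-target-out (cross-target screening); III family-restricted
  leave-one-out; IV heterogeneous-measurement integration under both pair
  mappings.
- **Synthetic benchmark generator** (`synthetic_data`): a seeded bilinear
  ground-truth generator so every experiment runs without external data.
- **I/O + CLI** (`cli_io`, `cli`): FASTA/CSV/TSV readers and writers, run
  manifests with SHA-256 input digests, and a `rankscreen` console command.

## Worked example

Command line — simulate a benchmark, then run per-target cross-validation:

```bash
$ rankscreen simulate --seed 7 --targets 6 --compounds 20 --families 3 --out demo_data
wrote 6 targets x 20 compounds to demo_data
$ rankscreen run-strategy I --data demo_data --algorithm prank --algorithm listnet --seed 7 --out demo_run
strategy I listnet: mean NDCG@10 = 0.8529
strategy I prank: mean NDCG@10 = 0.8609
```

`demo_run/strategy_I_report.json` holds per-target, per-fold NDCG@10 values
(full precision), `strategy_I_report.csv` the same at 6 significant digits,
and `manifest.json` the command, master seed, and SHA-256 digests of every
input file.  Re-running with the same seed reproduces the reports
byte-for-byte.

The same from Python:

```python
>>> from rankscreen import ndcg_at_k, grade_affinity, ctd_features
>>> ndcg_at_k([4, 3, 2, 1, 0], 10)   # prediction matches the ideal ordering
1.0
>>> round(ndcg_at_k([0, 1, 2, 3, 4], 10), 4)   # fully reversed
0.5129
>>> grade_affinity(6.5)
1
>>> ctd_features("ACDEFGHIKLMNPQRSTVWY" * 5).shape
(147,)
```

## Documentation

`docs/methods.md` describes the model, all default parameters and their
rationale, the synthetic study conditions, numerical choices, and known
limitations.
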