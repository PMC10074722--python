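# wavehot

Prediction pipeline for hot-spot residues in protein–DNA binding interfaces.
Per-residue structural descriptors (43 "traditional" features: solvent
accessibility, secondary structure, depth/protrusion indices, hydrogen-bond
count) are treated as four short digital signals and expanded with wavelet
energy and entropy descriptors (3-level Haar DWT + level-3 wavelet packet
transform, +132 columns, 175 total). The imbalanced classes are equalized
with SMOTE, features are selected by mRMR ranking followed by sequential
forward selection under cross-validated AUC, and a histogram gradient-boosted
tree classifier (max_depth=15, num_leaves=50, n_estimators=1000) is evaluated
by SEN/SPE/PRE/F1/ACC/MCC/AUC with stratified tenfold cross-validation and
leakage-safe in-fold balancing.

## Layout

| module | contents |
|---|---|
| `wavehot.schema` | canonical 43-column schema, `FeatureTable`, CSV/TSV I/O, ΔΔG ≥ 1.0 kcal/mol labeling rule, split bookkeeping |
| `wavehot.wavelet` | Haar analysis step, multilevel DWT, level-3 WPT, energy percentages, five wavelet entropies |
| `wavehot.featurize` | signal-group construction (ASA/uASA/dASA/DSSP) and the 43 → 175 column featurizer |
| `wavehot.balance` | SMOTE (k-NN interpolation, default seed 114) and random-repeat oversampling |
| `wavehot.selection` | mRMR (MID scheme, 3-bin MI) ranking + SFS wrapper under CV AUC |
| `wavehot.modeling` | GBDT training, confusion/metrics/rank-AUC, repeated stratified CV |
| `wavehot.simulate` | synthetic labeled residue tables and wavelet test signals |
| `wavehot.cli` | `wavehot` command-line app and the end-to-end pipeline |

## CLI

```sh
wavehot schema --out schema.json                 # canonical 43-column schema
wavehot simulate --n-pos 101 --n-neg 170 --effect 2.0 --seed 1 --out table.csv
wavehot featurize --input table.csv --out full.csv
wavehot balance  --input full.csv --method smote --seed 114 --k 5 --out balanced.csv
wavehot select   --input full.csv --folds 10 --seed 1 --out selection.json
wavehot cv       --input full.csv --features-json selection.json --folds 10 --seed 1 --out metrics.json
wavehot evaluate --train train.csv --test test.csv --features-json selection.json --out eval.json
wavehot run      --config config.yaml            # all stages into a run directory
```

`wavehot run` writes `features_full175.csv`, `features_balanced.csv`,
`selection.json`, `metrics.json`, `model_meta.json`, a `manifest.json`
recording every parameter and seed, and a log. Reruns with the same config
are bit-identical.

Input tables are CSV or TSV (auto-detected) with a header; feature columns
must match the canonical schema (see `wavehot schema`). Optional columns:
`pdb_id`, `chain`, `position`, `wt_residue`, `ddg`, `label`.

## Notes

- SFS candidate subsets are scored with a smaller booster (configurable via
  `select_*` settings / `--n-estimators` on `wavehot select`) and the walk is
  capped at the top-ranked features (`select_max_features`, default 30); the
  final cross-validation and model always use the full 15/50/1000
  configuration.
- Balancing happens inside training folds by default; `--balance-before-cv`
  balances the whole table once before splitting instead.
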