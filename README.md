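# pfnorm

Normalization, correlation and trend analysis for multivariate
platelet-function time series (ROTEM / aggregometry / blood-count style
perioperative panels).

The package demonstrates — and makes testable without patient data — a
simple but consequential fact about visualizing multivariate clinical
time series: Spearman rank correlation between two assays, pooled over
patients and timepoints, is **exactly preserved** when each assay is
normalized on its own (per-attribute scope, any strictly monotone
transform), but is **scrambled** when normalization pools all assays
within each timepoint.

## Components

| module | what it does |
| --- | --- |
| `pfnorm.data_model` | tidy long table (patient, timepoint, attribute, value), CSV I/O, wide pivot, derived PLTEM channel (`X PLTEM = X EXTEM − X FIBTEM`) |
| `pfnorm.normalization` | four transforms (z, range, proportion, robust IQR scaling) × three grouping scopes (all / per-attribute / per-timepoint), with per-group statistics reports and degenerate-group policies |
| `pfnorm.correlation` | Spearman rho, t-approximation and exact-permutation p-values, strength bands (strong > 0.40, moderate 0.30–0.40, else weak) |
| `pfnorm.trend` | pooled polynomial trend fits over the ordered time index (model df = degree + 1) |
| `pfnorm.synthetic` | Gaussian-copula study generator: truncated-normal marginals from printed normal ranges, target rank correlations, per-timepoint multiplicative time effects, seeded and reproducible |
| `pfnorm.cli` | `pfnorm` command with `simulate`, `normalize`, `correlate`, `trend`, `plot`, and the composite `run` |

## CLI quick start

```sh
# full demo pipeline: synthetic 20-patient study -> PLTEM derivation ->
# 4 methods x 3 scopes normalized tables -> correlations, trends, figures
pfnorm run --demo --seed 42 -o out/

# individual stages
pfnorm simulate --seed 42 -o study.csv --report gen.json
pfnorm normalize --method z --scope per-attribute -i study.csv -o z.csv --report z.json
pfnorm correlate -i study.csv --targets "MCF EXTEM" --references PlatCt
pfnorm trend -i study.csv --attributes "PlatCt,MCF EXTEM" --degree 2
pfnorm plot -i study.csv --scope per-timepoint -o fig.svg
```

`run` writes 12 normalized tables (`normalized_<method>_<scope>.csv` plus
JSON group-statistics reports), `correlations.csv`, `trends.csv`, one
faceted SVG per scope (panels A: InterQ, B: range, C: prop, D: Z), and a
`manifest.json`; re-running with the same seed reproduces every CSV byte
for byte.

Input CSVs are long format with header
`patient,timepoint,attribute,value,unit` (column names remappable via
`pfnorm.data_model.ColumnMap`); timepoints default to S1 < S2 < S3 order.

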