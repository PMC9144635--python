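# metimpute

Benchmarking framework for **missing-value imputation in untargeted GC–MS
metabolomics peak tables**: simulate realistic abundance tables, inject
missing values under controlled mechanisms, impute with ten standard
single-imputation methods, and measure both imputation accuracy and the
bias imputation induces in downstream statistics.

It is aimed at metabolomics data analysts deciding how to handle missing
peaks before statistical modelling, and at methodologists who want a
reproducible harness for comparing imputation strategies.

## The problem

Untargeted GC–MS peak tables (samples × metabolites, log10-transformed
abundances) routinely contain missing cells, arising as

* **MCAR** — missing completely at random (acquisition artifacts),
* **MAR** — missing at random, driven by an observed variable (e.g. an
  abundant co-eluting metabolite suppressing another's detection),
* **MNAR** — missing not at random, driven by the value itself (below the
  detection limit),

or any mixture of the three. Imputation fills the gaps, but every single
imputation method alters the data's correlation structure and biases
downstream estimates. This package quantifies that trade-off:

* **Accuracy** — RMSE and percent bias `PB = mean 100·|ŷ − y|/|y|` over the
  injected-missing cells only.
* **Internal consistency** — Cronbach's alpha
  `α = k/(k−1)·(1 − Σ var(itemᵢ) / var(Σ items))` and mean pairwise
  Pearson correlation, imputed vs truth.
* **Regression bias** — per-metabolite OLS of log10 abundance on age:
  differences in slopes `β̂` and p-values between truth and imputed data
  (`Δp > 0` means the association weakened).

Ten imputers sit behind one interface: zero, half-minimum, mean, kNN,
iterative SVD completion, Bayesian PCA (variational, with automatic
relevance determination), local least squares, missForest-style random
forest, cross-validated ridge (GRR), and quantile regression. All preserve
observed cells bit-exactly and act as the identity on complete tables.

## Worked example

```python
from metimpute import (
    ReplicateSimConfig, generate_replicate_dataset, log10_transform,
    inject_mixture, impute, rmse, percent_bias,
)

# 150 technical replicates x 60 metabolites, analytical CVs 5-60%
table = log10_transform(generate_replicate_dataset(ReplicateSimConfig(seed=1)))

# remove 10% of cells: equal parts MCAR, MAR and MNAR
mask = inject_mixture(table, rate=0.10, seed=2)
masked = mask.apply(table)
print(f"masked {mask.n_masked} cells {mask.label_counts()}")

for method in ("rf", "mean", "hm", "zero"):
    result = impute(masked, method, seed=3)
    print(f"{method:>5}: RMSE={rmse(table, result.imputed, mask.mask):.3f}  "
          f"PB={percent_bias(table, result.imputed, mask.mask):.1f}%")
```

```
masked 900 cells {'MAR': 300, 'MCAR': 300, 'MNAR': 300}
   rf: RMSE=0.216  PB=3.0%
 mean: RMSE=0.211  PB=3.0%
   hm: RMSE=0.465  PB=7.8%
 zero: RMSE=5.629  PB=100.0%
```

Model-based and mean imputation recover the removed log10 abundances to
~0.2 log units (a few percent of a typical value of ~5), while
detection-limit surrogates (half-minimum) and zero-filling are far off —
zero-filling is 100% biased by construction on this scale. On technical
replicates the column mean is near-optimal because every sample repeats the
same material; on biological tables with shared covariance the model-based
methods (RF, GRR, BPCA) pull ahead.

The same pipeline is scriptable from the shell:

```bash
metimpute simulate replicates --seed 1 --out table.csv
metimpute inject --mechanism mix --rate 0.1 --seed 2 --in table.csv \
    --out masked.csv --mask mask.csv
metimpute impute --method rf --in masked.csv --out imputed.csv --scale raw
metimpute benchmark accuracy --config bench.yaml --out report/
```

`benchmark` runs any of the four experiments (`accuracy`, `consistency`,
`regression`, `indepth`) from a YAML config and writes tidy CSVs plus a
provenance block from which the run can be replayed exactly.

## Layout

```
src/metimpute/
  data_model.py   # AbundanceTable, readers/writers, log10, summaries
  synthetic.py    # replicate & biological table generators
  missingness.py  # MCAR/MAR/MNAR/mixture injectors, single-value insertion
  imputation.py   # the ten imputers + dispatcher
  evaluation.py   # RMSE, percent bias, alpha, regressions, tests, FDR
  benchmark.py    # the four experiments, reporting, replay
  presets.py      # canonical study conditions
  cli.py          # `metimpute` command group
docs/methods.md   # models, assumptions, parameter choices, limitations
```
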