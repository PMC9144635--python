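# Methods

## Scope and model of the data

`metimpute` benchmarks single-imputation methods for wide-format GC–MS
metabolomics peak tables: samples × metabolites matrices of peak abundances
that are log10-transformed before any model-based analysis. The package
covers the full loop the benchmark needs — simulate a table, inject missing
values under a controlled mechanism, impute, and score both the imputation
error itself and the bias imputation induces in downstream statistics.

Missingness mechanisms follow the standard taxonomy:

* **MCAR** — removal independent of all values (acquisition artifacts such
  as incomplete derivatization or ionization).
* **MAR** — removal driven by another *observed* variable (an abundant
  co-eluting metabolite suppressing detection of a second one).
* **MNAR** — removal driven by the missing value itself (abundance below
  the detection limit).
* **mixture** — the three applied sequentially at equal proportions, the
  default for headline comparisons because real tables plausibly contain
  all three.

## Synthetic data generators

The deposited raw datasets behind the original study are not required:
two generators emulate their statistical structure. Both are log-normal on
the raw scale (so raw abundances are strictly positive) and impose the
analytical coefficient of variation exactly through
`sigma_ln = sqrt(ln(1 + CV²))`. All randomness flows from one integer seed
through `numpy.random.SeedSequence` spawning, so every sub-stream
(medians, CVs, ages, effects, noise, dropout) is independently
reproducible.

**Technical replicates** (`ReplicateSimConfig`, defaults 150 samples × 60
metabolites): repeated injections of one pooled plasma sample. Metabolite
`j` has median `10^mu_j` with `mu_j ~ U(3.5, 7.0)` (log10 span typical of
untargeted peak heights) and per-metabolite CV `~ U(0.05, 0.6)`. Samples
share medians; an optional per-sample scaling factor (off by default) can
emulate injection-volume drift.

**Biological cohorts** (`BioSimConfig`, defaults 45 samples × 100
metabolites, ages `U(6, 23)` years): log10 abundance of metabolite `j` in
sample `i` is

```
log10 y_ij = intercept_j + beta_j * (age_i - age_mid) + loadings_j · f_i + eps_ij
```

with `beta_j ~ N(0, effect_sd)` for a `frac_affected` fraction (default
0.3, `effect_sd` 0.02 log10 units/year) and `beta_j = 0` otherwise; true
slopes are recorded and retrievable for parameter-recovery tests. The
latent factors `f_i` give metabolites the shared covariance real peak
tables show; the first factor loads positively on every metabolite
(sample-level total-abundance variation: extraction yield, injection
volume), the rest have signed loadings (co-regulated pathway structure).
Without this shared variance, internal-consistency statistics such as
Cronbach's alpha would be undefined noise on independent columns. An
optional block structure (`block_size` > 1) adds near-duplicate feature
groups, emulating the multiple fragments/adducts per compound that GC–MS
peak tables carry.

**Natural ("full"-table) missingness** is stochastic detection-limit
censoring: per-metabolite censoring fractions are drawn from a chi-squared
shape (right-skewed, so missingness spans gap-free to heavily censored
metabolites), and within a metabolite cells drop out with probability
increasing as abundance decreases (softmax over `-sharpness * z`), not by
a deterministic quantile cut — real dropout is noisy and censored
metabolites retain some low observed values. With
`cv_missing_coupling > 0` the larger censoring fractions are
preferentially assigned to the noisier metabolites, reproducing the
empirical correlation between peak quality, CV and missingness.

What the generators do **not** emulate: chromatographic drift, batch
effects, instrument noise models, non-log-normal marginals, and
metabolite annotation ambiguity. Passing tests therefore show that the
pipeline recovers the expected patterns *under the stated generative
assumptions*, not that any particular imputation method is best for a
given real dataset.

## Missingness injection

All injectors take a complete (or partially observed) table, a global
target rate and a seed, and return a mask with per-cell mechanism labels
and the removed true values (so masking is exactly invertible). Counts
use round-half-away-from-zero on `rate × n_observed`; realized vs target
rate is always reported and agrees to within one cell for MCAR and the
mixture. Supported rates span 2–70%.

Protocol details the underlying description leaves open, fixed here as
configurable defaults:

* MNAR per-metabolite percentages are chi-squared with `df = 6`
  (right-skewed, mean 6%), capped at 80% of a metabolite's observed
  cells; ties among equal lowest values break by sample index.
* MAR per-pair removal percentages are `U(5%, 50%)`; the driver ranking
  uses a stable descending sort so ties are deterministic.
* Mixture remainders are assigned in the fixed order MCAR → MAR → MNAR,
  and later mechanisms only see still-observed cells (sub-masks are
  disjoint).
* Every injector leaves at least two observed cells per metabolite, so
  per-metabolite means/SDs — and with them every imputer — remain
  defined. At the benchmark's rates this floor essentially never binds.

The single-value protocol masks exactly one observed cell at a time
(uniform over cells not yet used), re-imputes the whole table, and
records the error at that one cell together with the host metabolite's
natural missingness and CV.

## Imputation methods

Ten single-imputation methods sit behind one dispatcher with a central
parameter registry. Two contracts are enforced for all of them and
checked bit-exactly in the tests: observed cells are never altered, and a
complete table is returned unchanged. Model-based imputers treat
metabolites as variables and samples as observations, run on the log10
scale, and start from the metabolite-mean fill so runs are reproducible.

* **zero / half-minimum / mean** — closed-form substitution. HM uses half
  the metabolite's minimum observed value (equivalently
  `min − log10 2` on the log scale), a detection-limit surrogate.
* **kNN** (k=10, distance-weighted) — co-observation-normalized Euclidean
  distances between metabolites; missing cells are weighted averages of
  neighbour values in the same sample, with a recorded mean fallback when
  no neighbour is observed there.
* **SVD** (rank 5) — iterative truncated-SVD completion with observed
  values re-imposed each pass; stops when the largest relative change of
  an imputed cell is below `1e-6`.
* **BPCA** — variational Bayes PCA with automatic relevance
  determination: `y_i = W x_i + mu + eps`, ARD prior
  `W[:, q] ~ N(0, I/alpha_q)`, per-sample E-step over each sample's
  observed coordinates, missing cells filled with the posterior-mean
  reconstruction. Initialisation is the SVD of the mean-filled matrix,
  making the method fully deterministic. The default component count is
  `max(3, min(dims)//3)`: at `q ≈ rank` the latent model can interpolate
  the filled matrix and EM stalls at its starting point, while ARD prunes
  any surplus from a moderate `q` (results are insensitive to `q`
  between ~5 and `min(dims)//2` on the synthetic tables). A minimum of
  five EM sweeps runs before the convergence test so ARD has shaped the
  loadings.
* **LLS** (k=10) — ordinary least squares of each gap metabolite on its
  `k` most `|r|`-correlated neighbours over fully co-observed rows, with
  recorded mean fallbacks for rank-deficient designs, short fits, or
  neighbours missing in the prediction row.
* **RF** — missForest-style iteration with scikit-learn random forests
  (100 trees by default, `mtry = sqrt(p)` as in missForest): visit
  metabolites in increasing order of missingness, regress each on all
  others, re-predict its missing cells; stop at the first increase of the
  normalized squared change of imputed values and return the previous
  sweep.
* **GRR** — the same chained iteration with L2-penalized regression; the
  penalty is chosen per metabolite over `logspace(1e-4, 1e2, 25)` by
  efficient leave-one-out (generalized) cross-validation, with the grid
  floored at `1e-2` for under-determined designs where near-zero
  penalties interpolate.
* **QR** (quantile 0.5) — chained per-metabolite quantile regression
  (pinball loss). The design is restricted to the 10 most correlated
  peers: with as many metabolites as samples the full-design fit is
  rank-deficient and unstable. Degenerate fits fall back to the mean and
  are recorded.

## Evaluation

RMSE and percent bias (`mean 100·|imputed − truth|/|truth|`) are computed
only over injected-missing cells, RMSE on the log10 analysis scale (the
scale imputation runs on; the single-value protocol also reports raw-scale
percent bias, where the published figures are quoted). Cronbach's alpha
uses the classical variance decomposition with an explicit items axis:
samples are the items for technical-replicate consistency, metabolites for
the biological and in-depth analyses. Regression bias fits per-metabolite
OLS of log10 abundance on age in the truth and the imputed table and
records slope and p-value differences; `p_diff = p_imputed − p_true`, so
positive means the association weakened. Hypothesis-testing helpers wrap
scipy's one-sample t-test and Wilcoxon rank-sum (exact for small tie-free
samples) and statsmodels' Benjamini–Hochberg adjustment.

## Benchmark experiments and desk-scale sizes

Every experiment is a pure function of (config, seed); per-cell seeds are
derived with `SeedSequence` so all methods inside one design cell see the
same mask, and any failing cell can be replayed in isolation from the
provenance block. A truth-passthrough `"oracle"` pseudo-method runs
through every experiment as a plumbing control that must score exactly
zero.

The canonical study conditions live in `metimpute.presets` and are sized
to finish in minutes on one CPU:

* **Accuracy ranking** — 150 × 60 replicates, 10% mixture, 20 repeats,
  methods {rf, grr, bpca, mean, zero, hm}; RF uses 30 trees and at most 5
  sweeps for repeated cells (the registry default of 100 trees is for
  one-off imputations; the ranking is insensitive to the difference).
  Per-metabolite records stratify RMSE by CV bins
  {<0.1, 0.1–0.2, 0.2–0.3, >0.3} and injected-missingness bins, and feed
  OLS of RMSE on CV and on missingness with method as a covariate.
* **Regression bias** — the 45-sample biological cohort, mixture at 10%
  and 20%, 3 repeats, methods {rf, grr, bpca}; one-sample t-tests of the
  slope differences (raw and magnitude) and p-value shifts, BH-FDR across
  methods, pairwise Wilcoxon on |slope differences|.
* **Consistency** — a biological cohort with pronounced shared covariance
  (3 factors, sd 0.3), mixture at 10% and 20%, 10 repeats; alpha over
  metabolite items, pairwise Wilcoxon across methods.
* **In-depth single-value** — a 45 × 40 "full" table with ~30% natural
  missingness, noise CVs 5–35% rank-coupled (0.7) to dropout, one
  dominant sample-level latent; metabolites >75% missing are removed,
  then 300 single-value insertions with RF (20 trees, ≤3 sweeps), plus a
  10–70% overall-missingness sweep of alpha and regression differences.
  This is a deliberate scale-down of the published protocol
  (10,000 insertions on a ~47 × 330 table); the qualitative
  accuracy-vs-missingness pattern is what the conditions are designed to
  expose, and the insertion count bounds the resolution of the binned
  medians.

## Numerical choices and degenerate inputs

* Missing sentinels when reading tables default to {"", "NA", "NaN"};
  zeros are *not* missing (a zero in a raw table is a scale error and is
  rejected).
* CV is always the raw-scale analytical CV; log10 tables are
  back-transformed first. CV is flagged as undefined (never silently
  zero) for non-positive means or fewer than two observations.
* Sample (n−1) standard deviations throughout.
* All-missing metabolites are an error for every imputer that needs an
  observed value; kNN/LLS/QR record every fallback rather than failing
  silently.
* Iterative imputers report `n_iterations` and `converged`;
  non-convergence is a flagged result, not an exception.
* Wilcoxon tests on identical groups return p = 1 exactly rather than
  relying on the tie-corrected approximation.

## Known limitations

* Multiple imputation (pooled inference) is out of scope by design; all
  ten methods are single-imputation.
* The QR imputer's restricted design (top-10 peers) is a pragmatic
  stabilisation, not the textbook full-design quantile regression.
* BPCA's ARD is an EM approximation on the completed matrix; its
  posterior variances are not propagated into downstream statistics.
* Generator realism bounds what the acceptance patterns mean: the
  direction results (method ranking, bias signs, degradation with
  missingness) reproduce on the stated synthetic conditions and should
  transfer qualitatively, but absolute RMSE/alpha values are not
  comparable to any particular instrument's data.
* The sign of the mean regression *p-value* shift after imputation is not
  a robust property of these synthetic cohorts. Two effects compete:
  slope attenuation (imputed cells carry less of the age signal, pushing
  p up) and variance deflation (conditional-mean fills shrink residual
  variance and standard errors, pushing p down). With 70% of metabolites
  null and model-based imputers that partially recover the age signal
  from co-affected peers, the benchmark measures a small *negative* mean
  p-shift for RF/GRR/BPCA — deflation wins — while the |slope|-shrinkage
  itself is consistently negative and significant. On real cohorts where
  cross-metabolite prediction of the outcome signal is poorer, the
  attenuation side can dominate and shift p-values upward instead.
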