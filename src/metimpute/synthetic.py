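"""Synthetic abundance tables with the structure the benchmark assumes.

Two generators:

* :func:`generate_replicate_dataset` — technical-replicate peak tables
  (repeated injections of one pooled plasma sample): every sample shares a
  metabolite's median abundance, and sample-to-sample scatter is pure
  analytical noise controlled by a per-metabolite coefficient of variation.
* :func:`generate_biological_dataset` — biological cohorts with an age
  covariate and per-metabolite age effects on the log10 abundance scale,
  with retrievable true slopes for parameter-recovery tests.

Both are log-normal on the raw scale, so raw abundances are strictly
positive and the analytical CV can be imposed exactly through
``sigma_log = sqrt(ln(1 + CV^2))`` (natural-log sd of a log-normal with the
target CV).  All randomness flows from a single seed through
``numpy.random.SeedSequence`` spawning, so the sub-streams (medians, CVs,
noise, ages, effects, baseline missingness) are independent and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import AbundanceTable

__all__ = [
    "ReplicateSimConfig",
    "BioSimConfig",
    "generate_replicate_dataset",
    "generate_biological_dataset",
]

LN10 = np.log(10.0)


def cv_to_sigma_log(cv: np.ndarray | float) -> np.ndarray | float:
    """Natural-log sd of a log-normal variable with coefficient of variation cv."""
    return np.sqrt(np.log1p(np.square(cv)))


@dataclass(frozen=True)
class ReplicateSimConfig:
    """Technical-replicate generator settings.

    Defaults emulate a pooled-plasma replicate table: 150 injections of 60
    gap-free metabolites, median log10 abundances spanning 3.5-7.0 and
    per-metabolite analytical CVs drawn uniformly from 5-60%.
    """

    n_samples: int = 150
    n_metabolites: int = 60
    log_mean_range: tuple[float, float] = (3.5, 7.0)
    cv_range: tuple[float, float] = (0.05, 0.6)
    sample_scale_sd: float = 0.0  # log10 sd of per-sample injection scaling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_metabolites < 2:
            raise ValueError("need at least 2 samples and 2 metabolites")
        lo, hi = self.cv_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("cv_range must satisfy 0 < low <= high <= 1")
        if self.log_mean_range[0] > self.log_mean_range[1]:
            raise ValueError("log_mean_range must be (low, high)")
        if self.sample_scale_sd < 0:
            raise ValueError("sample_scale_sd must be >= 0")


@dataclass(frozen=True)
class BioSimConfig:
    """Biological-cohort generator settings.

    ``effect_sd`` is the sd of the nonzero per-metabolite age slopes in
    log10 abundance units per year; ``frac_affected`` is the fraction of
    metabolites given a nonzero slope.  ``baseline_missing_rate`` > 0
    produces a "full" table with low-abundance-driven (detection-limit
    style) natural missingness.
    """

    n_samples: int = 45
    n_metabolites: int = 100
    age_range: tuple[float, float] = (6.0, 23.0)
    effect_sd: float = 0.02
    frac_affected: float = 0.3
    log_mean_range: tuple[float, float] = (3.5, 7.0)
    noise_cv_range: tuple[float, float] = (0.1, 0.4)
    n_factors: int = 2
    factor_sd: float = 0.15
    block_size: int = 1  # metabolites per correlated feature block (1 = off)
    block_sd: float = 0.25
    baseline_missing_rate: float = 0.0
    censor_sharpness: float = 1.5  # abundance-dependence of natural dropout
    cv_missing_coupling: float = 0.7  # rank coupling of noise CV and dropout
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3 or self.n_metabolites < 2:
            raise ValueError("need at least 3 samples and 2 metabolites")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low < high")
        if not 0 <= self.frac_affected <= 1:
            raise ValueError("frac_affected must be in [0, 1]")
        if not 0 <= self.baseline_missing_rate < 1:
            raise ValueError("baseline_missing_rate must be in [0, 1)")
        lo, hi = self.noise_cv_range
        if not (0 < lo <= hi):
            raise ValueError("noise_cv_range must satisfy 0 < low <= high")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be >= 0")
        if self.n_factors < 0 or self.factor_sd < 0:
            raise ValueError("n_factors and factor_sd must be >= 0")
        if self.block_size < 1 or self.block_sd < 0:
            raise ValueError("block_size must be >= 1 and block_sd >= 0")
        if not 0 <= self.cv_missing_coupling <= 1:
            raise ValueError("cv_missing_coupling must be in [0, 1]")


def _metabolite_ids(n: int) -> list[str]:
    return [f"m{j + 1:03d}" for j in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"s{i + 1:03d}" for i in range(n)]


def generate_replicate_dataset(config: ReplicateSimConfig) -> AbundanceTable:
    """Simulate a complete technical-replicate table on the raw scale.

    Metabolite j is log-normal with median ``10**mu_j`` (mu_j uniform over
    ``log_mean_range``) and CV uniform over ``cv_range``.  The table has no
    missing entries.  Target CVs are stored in ``table.truth`` (a DataFrame
    with columns ``log10_median`` and ``target_cv``).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_params, rng_noise, rng_scale = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )
    n, p = config.n_samples, config.n_metabolites
    mu = rng_params.uniform(*config.log_mean_range, size=p)  # log10 medians
    cv = rng_params.uniform(*config.cv_range, size=p)
    sigma_ln = cv_to_sigma_log(cv)  # natural-log sd

    noise_ln = rng_noise.standard_normal((n, p)) * sigma_ln
    log10_vals = mu + noise_ln / LN10
    if config.sample_scale_sd > 0:
        log10_vals = log10_vals + rng_scale.normal(
            0.0, config.sample_scale_sd, size=(n, 1)
        )
    df = pd.DataFrame(
        np.power(10.0, log10_vals),
        index=_sample_ids(n),
        columns=_metabolite_ids(p),
    )
    df.index.name = "sample_id"
    table = AbundanceTable(df, scale="raw")
    table.truth = pd.DataFrame(  # type: ignore[attr-defined]
        {"log10_median": mu, "target_cv": cv}, index=df.columns
    )
    return table


def generate_biological_dataset(config: BioSimConfig) -> AbundanceTable:
    """Simulate a biological cohort with per-metabolite age effects.

    log10 abundance of metabolite j in sample i is
    ``intercept_j + beta_j * age_i + loadings_j . f_i + noise_ij`` with
    noise sd set by a per-metabolite CV drawn from ``noise_cv_range``.
    The ``n_factors`` latent factors (scores ``f_i ~ N(0, I)``, loadings
    ``~ N(0, factor_sd)``) give metabolites the shared covariance real
    peak tables show (co-regulated pathways, sample-level metabolic
    state); set ``n_factors=0`` for independent metabolites.  A
    ``frac_affected`` fraction of metabolites receives
    ``beta_j ~ Normal(0, effect_sd)``; the rest have beta_j = 0.  True
    slopes are retrievable from ``table.truth`` (columns ``intercept``,
    ``beta``, ``noise_cv``).

    With ``baseline_missing_rate`` > 0 the lowest values are censored
    detection-limit style: cells are removed bottom-up within metabolites
    picked at random, emulating the natural missingness of a "full" table.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_ages, rng_params, rng_effects, rng_noise, rng_missing, rng_factors = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )
    n, p = config.n_samples, config.n_metabolites

    ages = rng_ages.uniform(*config.age_range, size=n)
    intercepts = rng_params.uniform(*config.log_mean_range, size=p)
    noise_cv = rng_params.uniform(*config.noise_cv_range, size=p)
    sigma10 = cv_to_sigma_log(noise_cv) / LN10  # log10-scale noise sd

    n_affected = int(round(config.frac_affected * p))
    affected = rng_effects.choice(p, size=n_affected, replace=False)
    beta = np.zeros(p)
    beta[affected] = rng_effects.normal(0.0, config.effect_sd, size=n_affected)

    # centre the age term so intercepts stay the mid-cohort log10 level
    age_mid = np.mean(config.age_range)
    log10_vals = (
        intercepts
        + np.outer(ages - age_mid, beta)
        + rng_noise.standard_normal((n, p)) * sigma10
    )
    if config.n_factors > 0 and config.factor_sd > 0:
        loadings = rng_factors.normal(0.0, config.factor_sd, size=(p, config.n_factors))
        # the first factor loads positively on every metabolite: a sample-level
        # total-abundance factor (extraction yield, injection volume), which is
        # what gives real peak tables their predominantly positive covariance
        loadings[:, 0] = np.abs(loadings[:, 0])
        scores = rng_factors.standard_normal((n, config.n_factors))
        log10_vals = log10_vals + scores @ loadings.T
    if config.block_size > 1 and config.block_sd > 0:
        # correlated feature blocks: GC-MS peak tables carry several features
        # per compound (fragments, adducts, derivatization products), which
        # are near-duplicate columns sharing a compound-level signal
        n_blocks = int(np.ceil(p / config.block_size))
        block_of = np.arange(p) // config.block_size
        block_scores = rng_factors.standard_normal((n, n_blocks)) * config.block_sd
        log10_vals = log10_vals + block_scores[:, block_of]

    df = pd.DataFrame(
        np.power(10.0, log10_vals),
        index=_sample_ids(n),
        columns=_metabolite_ids(p),
    )
    df.index.name = "sample_id"

    if config.baseline_missing_rate > 0:
        _censor_lowest(
            df,
            config.baseline_missing_rate,
            rng_missing,
            config.censor_sharpness,
            noise_cv=noise_cv,
            coupling=config.cv_missing_coupling,
        )

    covariates = pd.DataFrame({"age": ages}, index=df.index)
    table = AbundanceTable(df, scale="raw", covariates=covariates)
    table.truth = pd.DataFrame(  # type: ignore[attr-defined]
        {"intercept": intercepts, "beta": beta, "noise_cv": noise_cv},
        index=df.columns,
    )
    return table


def _censor_lowest(
    df: pd.DataFrame,
    rate: float,
    rng: np.random.Generator,
    sharpness: float = 1.5,
    noise_cv: np.ndarray | None = None,
    coupling: float = 0.0,
) -> None:
    """Remove ~rate of all cells by stochastic detection-limit censoring.

    Per-metabolite censoring fractions are drawn from a right-skewed
    distribution so metabolite missingness spans a wide range (some gap-free
    columns, some heavily censored), as in real full peak tables.  With
    ``coupling`` > 0 the larger censoring fractions are preferentially
    assigned to the noisier metabolites (rank coupling with ``noise_cv``),
    emulating how poor peak quality drives both imprecision and dropout.
    Within a metabolite, cells drop out with probability increasing as
    abundance decreases (softmax over -sharpness * standardized log
    abundance) rather than by a deterministic quantile cut: real
    detection-limit dropout is noisy, so censored metabolites still retain
    some low observed values.
    """
    n, p = df.shape
    quota = int(round(rate * n * p))
    fracs = np.minimum(rng.chisquare(4, size=p) / 10.0, 0.85)
    fracs[::-1].sort()  # descending: largest censoring fractions first
    if noise_cv is not None and coupling > 0:
        # noisy rank coupling: key = coupled cv rank + independent noise
        z = (np.argsort(np.argsort(noise_cv)) - (p - 1) / 2) / max(p / 4, 1)
        key = coupling * z + np.sqrt(1 - coupling**2) * rng.standard_normal(p)
        order = np.argsort(-key)
    else:
        order = rng.permutation(p)
    removed = 0
    for frac, j in zip(fracs, order):
        if removed >= quota:
            break
        k = min(int(round(frac * n)), n - 2, quota - removed)
        if k <= 0:
            continue
        col = df.iloc[:, j].to_numpy()
        z = np.log10(col)
        z = (z - z.mean()) / max(z.std(), 1e-12)
        w = np.exp(-sharpness * z)
        w /= w.sum()
        drop = rng.choice(n, size=k, replace=False, p=w)
        col[drop] = np.nan
        df.iloc[:, j] = col
        removed += k
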