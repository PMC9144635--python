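"""Accuracy metrics and downstream-bias statistics.

Imputation accuracy is scored only over the injected-missing cells: RMSE on
the log10 analysis scale and percent bias (mean absolute relative deviation,
in percent).  Downstream bias is quantified by comparing, between the true
and the imputed table, per-metabolite age-regression slopes and p-values,
Cronbach's alpha (internal consistency) and the mean pairwise Pearson
correlation.  Hypothesis-testing helpers wrap the classical one-sample
t-test, the two-sided Wilcoxon rank-sum test, and Benjamini-Hochberg FDR
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AbundanceTable

__all__ = [
    "EvaluationRecord",
    "RegressionBiasRecord",
    "ConsistencyRecord",
    "rmse",
    "percent_bias",
    "cronbach_alpha",
    "mean_pairwise_correlation",
    "regression_bias",
    "one_sample_t",
    "pairwise_wilcoxon",
    "fdr_adjust",
]


@dataclass(frozen=True)
class EvaluationRecord:
    """One iteration's accuracy metrics for one benchmark design cell."""

    method: str
    mechanism: str
    target_rate: float
    rmse: float
    percent_bias: float
    cv_bin: str = "all"
    missingness_bin: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.percent_bias < 0:
            raise ValueError("rmse and percent_bias must be non-negative")


@dataclass(frozen=True)
class RegressionBiasRecord:
    """Per-metabolite slope/p-value comparison: imputed vs complete data.

    ``p_diff = p_imputed - p_true``: positive means the association became
    less significant after imputation.
    """

    metabolite_id: str
    beta_true: float
    beta_imputed: float
    beta_diff: float
    p_true: float
    p_imputed: float
    p_diff: float

    def __post_init__(self) -> None:
        for p in (self.p_true, self.p_imputed):
            if not 0.0 <= p <= 1.0:
                raise ValueError("p-values must lie in [0, 1]")


@dataclass(frozen=True)
class ConsistencyRecord:
    """Internal-consistency comparison: imputed vs true table."""

    alpha_true: float
    alpha_imputed: float
    alpha_diff: float
    mean_pairwise_corr: float
    items_axis: str  # "samples" or "metabolites"


def _masked_pairs(
    truth: AbundanceTable | np.ndarray,
    imputed: AbundanceTable | np.ndarray,
    mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    t = truth.values if isinstance(truth, AbundanceTable) else np.asarray(truth, float)
    m = (
        imputed.values
        if isinstance(imputed, AbundanceTable)
        else np.asarray(imputed, float)
    )
    if t.shape != m.shape or t.shape != mask.shape:
        raise ValueError("truth, imputed and mask shapes must align")
    if not mask.any():
        raise ValueError("mask selects no cells")
    return t[mask], m[mask]


def rmse(
    truth: AbundanceTable | np.ndarray,
    imputed: AbundanceTable | np.ndarray,
    mask: np.ndarray,
) -> float:
    """Root mean squared error over masked cells only."""
    t, m = _masked_pairs(truth, imputed, mask)
    return float(np.sqrt(np.mean((m - t) ** 2)))


def percent_bias(
    truth: AbundanceTable | np.ndarray,
    imputed: AbundanceTable | np.ndarray,
    mask: np.ndarray,
    skip_zero_truth: bool = False,
) -> float:
    """Mean of 100 * |imputed - truth| / |truth| over masked cells."""
    t, m = _masked_pairs(truth, imputed, mask)
    zero = t == 0
    if zero.any():
        if not skip_zero_truth:
            raise ValueError(
                "zero truth on a masked cell; pass skip_zero_truth=True to exclude"
            )
        t, m = t[~zero], m[~zero]
        if t.size == 0:
            raise ValueError("all masked cells had zero truth")
    return float(np.mean(100.0 * np.abs(m - t) / np.abs(t)))


def cronbach_alpha(table: AbundanceTable | np.ndarray, items_axis: str) -> float:
    """Cronbach's alpha, items along ``items_axis`` ("samples"|"metabolites").

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums).
    For technical-replicate consistency the items are the samples; for
    metabolite-correlation analyses the items are the metabolites.
    """
    vals = table.values if isinstance(table, AbundanceTable) else np.asarray(table, float)
    if items_axis not in ("samples", "metabolites"):
        raise ValueError("items_axis must be 'samples' or 'metabolites'")
    if np.isnan(vals).any():
        raise ValueError("Cronbach's alpha requires a complete table")
    # items become columns: observations x items
    items = vals.T if items_axis == "samples" else vals
    k = items.shape[1]
    if k < 2:
        raise ValueError("need at least 2 items")
    item_vars = np.var(items, axis=0, ddof=1)
    total_var = float(np.var(items.sum(axis=1), ddof=1))
    if total_var == 0:
        raise ValueError("zero total variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def mean_pairwise_correlation(
    table: AbundanceTable | np.ndarray, axis: str = "samples"
) -> float:
    """Mean Pearson r over all unordered vector pairs along ``axis``.

    Pairs involving a constant vector are excluded with a warning.
    """
    vals = table.values if isinstance(table, AbundanceTable) else np.asarray(table, float)
    if axis not in ("samples", "metabolites"):
        raise ValueError("axis must be 'samples' or 'metabolites'")
    if np.isnan(vals).any():
        raise ValueError("mean pairwise correlation requires a complete table")
    vectors = vals if axis == "samples" else vals.T
    n = vectors.shape[0]
    if n < 2:
        raise ValueError("need at least 2 vectors")
    sds = np.std(vectors, axis=1)
    keep = np.flatnonzero(sds > 0)
    if keep.size < n:
        warnings.warn(
            f"excluding {n - keep.size} constant vector(s) from correlation pairs",
            stacklevel=2,
        )
    if keep.size < 2:
        raise ValueError("fewer than 2 non-constant vectors")
    corr = np.corrcoef(vectors[keep])
    iu = np.triu_indices(keep.size, k=1)
    return float(np.mean(corr[iu]))


def regression_bias(
    truth_table: AbundanceTable,
    imputed_table: AbundanceTable,
    covariate: str | Sequence[float] = "age",
) -> list[RegressionBiasRecord]:
    """Per-metabolite OLS of abundance on a covariate, truth vs imputed.

    Both tables must be complete and share sample/metabolite ids.  The
    covariate is either a column name of ``truth_table.covariates`` or an
    explicit per-sample vector.
    """
    if truth_table.n_samples < 3:
        raise ValueError("regression needs at least 3 samples")
    if isinstance(covariate, str):
        if truth_table.covariates is None or covariate not in truth_table.covariates:
            raise ValueError(f"covariate {covariate!r} not present on the table")
        x = truth_table.covariates[covariate].to_numpy(dtype=float)
    else:
        x = np.asarray(covariate, dtype=float)
        if x.size != truth_table.n_samples:
            raise ValueError("covariate length must equal the number of samples")
    tv, iv = truth_table.values, imputed_table.values
    if tv.shape != iv.shape:
        raise ValueError("tables must share dimensions")
    if np.isnan(tv).any() or np.isnan(iv).any():
        raise ValueError("both tables must be complete")

    records: list[RegressionBiasRecord] = []
    for j, mid in enumerate(truth_table.metabolite_ids):
        bt, pt = _ols_slope(x, tv[:, j])
        bi, pi = _ols_slope(x, iv[:, j])
        records.append(
            RegressionBiasRecord(
                metabolite_id=str(mid),
                beta_true=bt,
                beta_imputed=bi,
                beta_diff=bi - bt,
                p_true=pt,
                p_imputed=pi,
                p_diff=pi - pt,
            )
        )
    return records


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(x, y)
    p = float(res.pvalue)
    if np.isnan(p):  # zero-variance outcome: slope 0, no evidence
        return float(res.slope), 1.0
    return float(res.slope), min(max(p, 0.0), 1.0)


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> tuple[float, float]:
    """Classical one-sample t-test against ``mu0``; returns (t, two-sided p)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    if np.std(arr, ddof=1) == 0:
        raise ValueError("zero standard deviation; t statistic undefined")
    res = stats.ttest_1samp(arr, popmean=mu0)
    return float(res.statistic), float(res.pvalue)


def pairwise_wilcoxon(
    groups: dict[str, Sequence[float]] | Sequence[Sequence[float]],
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum p-value for every unordered group pair.

    Uses the exact null distribution for small tie-free samples and the
    normal approximation with tie correction otherwise (scipy's
    Mann-Whitney U, equivalent to the rank-sum test).  The diagonal is 1.
    """
    if not isinstance(groups, dict):
        groups = {str(i): g for i, g in enumerate(groups)}
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {}
    for name in names:
        arr = np.asarray(groups[name], dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        arrays[name] = arr
    out = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ga, gb = arrays[names[a]], arrays[names[b]]
            if np.array_equal(ga, gb):
                p = 1.0
            else:
                p = float(
                    stats.mannwhitneyu(ga, gb, alternative="two-sided").pvalue
                )
            out.iat[a, b] = out.iat[b, a] = p
    return out


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(arr, method="fdr_bh")[1]
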