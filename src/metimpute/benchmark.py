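"""End-to-end benchmark experiments: inject -> impute -> score.

Four experiments mirror the benchmarking protocol:

* :func:`run_accuracy_benchmark` — complete-table accuracy: inject each
  mechanism at each rate, impute with each method, score RMSE / percent
  bias overall and per metabolite (stratified by CV and injected
  missingness).
* :func:`run_consistency_assessment` — internal-consistency bias: compare
  Cronbach's alpha and mean sample-to-sample correlation of the imputed
  table against the truth at 10% / 20% global missingness.
* :func:`run_regression_bias_assessment` — downstream regression bias on
  age-structured biological tables: per-metabolite slope and p-value
  differences, with one-sample t-tests, FDR adjustment and pairwise
  Wilcoxon comparisons across methods.
* :func:`run_indepth_single_value` — the single-value protocol: insert one
  missing value at a time into a naturally incomplete ("full") table,
  re-impute, and relate the per-point percent bias to the host
  metabolite's missingness; plus a wide (10-70%) missingness sweep of
  alpha and regression diffs.

Every experiment is a pure function of (config, seed): injection seeds are
derived per design cell so all methods within a cell see the same mask, and
a ``"oracle"`` pseudo-method (truth passthrough) is accepted everywhere as
a plumbing control that must yield exactly zero error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .data_model import AbundanceTable, log10_transform, read_table, split_complete, summarize_metabolites
from .evaluation import (
    ConsistencyRecord,
    EvaluationRecord,
    cronbach_alpha,
    fdr_adjust,
    mean_pairwise_correlation,
    one_sample_t,
    pairwise_wilcoxon,
    percent_bias,
    regression_bias,
    rmse,
)
from .imputation import METHODS, impute
from .missingness import filter_by_missingness, inject, insert_single_missing
from .synthetic import (
    BioSimConfig,
    ReplicateSimConfig,
    generate_biological_dataset,
    generate_replicate_dataset,
)

__all__ = [
    "BenchmarkConfig",
    "BenchmarkReport",
    "run_accuracy_benchmark",
    "run_consistency_assessment",
    "run_regression_bias_assessment",
    "run_indepth_single_value",
    "write_report",
    "replay",
]

logger = logging.getLogger(__name__)

DEFAULT_RATES = (0.02, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70)
CV_BIN_EDGES = (0.1, 0.2, 0.3)
MISS_BIN_EDGES = (10.0, 20.0, 30.0, 45.0)


def _bin_label(value: float, edges: Sequence[float], unit: str = "") -> str:
    prev = None
    for e in edges:
        if value < e:
            return f"<{e:g}{unit}" if prev is None else f"{prev:g}-{e:g}{unit}"
        prev = e
    return f">{edges[-1]:g}{unit}"


@dataclass(frozen=True)
class BenchmarkConfig:
    """Shared experiment settings.

    ``dataset`` is a generator config (replicate or biological) or a path
    to a CSV abundance table.  ``method_params`` holds per-method
    hyperparameter overrides applied on top of the registry defaults.
    """

    dataset: ReplicateSimConfig | BioSimConfig | str
    mechanisms: tuple[str, ...] = ("mix",)
    rates: tuple[float, ...] = (0.10,)
    methods: tuple[str, ...] = ("rf", "grr", "bpca", "mean")
    method_params: dict[str, dict[str, Any]] = field(default_factory=dict)
    n_repeats: int = 20
    seed: int = 0
    covariate: str = "age"

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        for r in self.rates:
            if not 0.0 < r <= 0.75:
                raise ValueError(f"rate {r} outside (0, 0.75]")
        for m in self.methods:
            if m not in METHODS and m != "oracle":
                raise ValueError(f"unknown method {m!r}")
        for mech in self.mechanisms:
            if mech not in ("mcar", "mar", "mnar", "mix"):
                raise ValueError(f"unknown mechanism {mech!r}")


@dataclass
class BenchmarkReport:
    """Aggregated experiment output with full provenance."""

    records: list[EvaluationRecord] = field(default_factory=list)
    per_metabolite: pd.DataFrame = field(default_factory=pd.DataFrame)
    consistency: pd.DataFrame = field(default_factory=pd.DataFrame)
    regression: pd.DataFrame = field(default_factory=pd.DataFrame)
    aggregates: pd.DataFrame = field(default_factory=pd.DataFrame)
    tests: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)

    def records_frame(self) -> pd.DataFrame:
        if not self.records:
            return pd.DataFrame(
                columns=[f.name for f in dataclasses.fields(EvaluationRecord)]
            )
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])


# -- seeding and shared plumbing ------------------------------------------


def _cell_seed(base: int, *indices: int) -> int:
    """Deterministic per-cell seed derived from the experiment seed."""
    ss = np.random.SeedSequence([int(base), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2**31))


def _materialize(dataset, kind: str) -> AbundanceTable:
    if isinstance(dataset, str) or isinstance(dataset, Path):
        return read_table(dataset)
    if isinstance(dataset, ReplicateSimConfig):
        return generate_replicate_dataset(dataset)
    if isinstance(dataset, BioSimConfig):
        return generate_biological_dataset(dataset)
    raise TypeError(f"cannot materialize dataset for {kind}: {dataset!r}")


def _impute_or_oracle(masked, truth, method, params, seed):
    if method == "oracle":
        return truth
    return impute(masked, method, params=params.get(method), seed=seed).imputed


def _provenance(config: BenchmarkConfig, experiment: str, **extra) -> dict[str, Any]:
    ds = config.dataset
    if isinstance(ds, (ReplicateSimConfig, BioSimConfig)):
        dataset = {
            "type": type(ds).__name__,
            "fields": dataclasses.asdict(ds),
        }
    else:
        dataset = {"type": "path", "fields": {"path": str(ds)}}
    return {
        "experiment": experiment,
        "version": __version__,
        "dataset": dataset,
        "config": {
            "mechanisms": list(config.mechanisms),
            "rates": list(config.rates),
            "methods": list(config.methods),
            "method_params": config.method_params,
            "n_repeats": config.n_repeats,
            "seed": config.seed,
            "covariate": config.covariate,
        },
        **extra,
    }


# -- experiment 1: complete-table accuracy --------------------------------


def run_accuracy_benchmark(config: BenchmarkConfig) -> BenchmarkReport:
    """Inject -> impute -> score RMSE/percent-bias on a complete table."""
    raw = _materialize(config.dataset, "accuracy")
    complete_raw, _ = split_complete(raw)
    if complete_raw.n_metabolites == 0:
        raise ValueError("no complete metabolites to benchmark on")
    summaries = summarize_metabolites(complete_raw)
    cvs = np.array([np.nan if s.cv is None else s.cv for s in summaries])
    table = log10_transform(complete_raw)

    report = BenchmarkReport(provenance=_provenance(config, "accuracy"))
    per_rows: list[dict[str, Any]] = []
    for rep in range(config.n_repeats):
        for mi, mech in enumerate(config.mechanisms):
            for ri, rate in enumerate(config.rates):
                inj_seed = _cell_seed(config.seed, 0, rep, mi, ri)
                try:
                    mask = inject(table, mech, rate, inj_seed)
                except Exception as exc:
                    msg = f"inject failed rep={rep} mech={mech} rate={rate}: {exc}"
                    logger.warning(msg)
                    report.diagnostics.append(msg)
                    continue
                masked = mask.apply(table)
                for method in config.methods:
                    imp_seed = _cell_seed(config.seed, 1, rep, mi, ri)
                    try:
                        imputed = _impute_or_oracle(
                            masked, table, method, config.method_params, imp_seed
                        )
                        overall_rmse = rmse(table, imputed, mask.mask)
                        overall_pb = percent_bias(table, imputed, mask.mask)
                    except Exception as exc:
                        msg = (
                            f"cell failed rep={rep} mech={mech} rate={rate} "
                            f"method={method}: {exc}"
                        )
                        logger.warning(msg)
                        report.diagnostics.append(msg)
                        continue
                    report.records.append(
                        EvaluationRecord(
                            method=method,
                            mechanism=mech,
                            target_rate=rate,
                            rmse=overall_rmse,
                            percent_bias=overall_pb,
                            seed=inj_seed,
                        )
                    )
                    # per-metabolite stratification for the RMSE~CV and
                    # RMSE~missingness regressions
                    iv, tv = imputed.values, table.values
                    for j in range(table.n_metabolites):
                        col_mask = mask.mask[:, j]
                        if not col_mask.any():
                            continue
                        d = iv[col_mask, j] - tv[col_mask, j]
                        col_rmse = float(np.sqrt(np.mean(d * d)))
                        col_pb = float(
                            np.mean(100.0 * np.abs(d) / np.abs(tv[col_mask, j]))
                        )
                        pct_injected = 100.0 * col_mask.sum() / table.n_samples
                        per_rows.append(
                            {
                                "repeat": rep,
                                "mechanism": mech,
                                "target_rate": rate,
                                "method": method,
                                "metabolite_id": table.metabolite_ids[j],
                                "rmse": col_rmse,
                                "percent_bias": col_pb,
                                "cv": cvs[j],
                                "pct_injected_missing": pct_injected,
                                "cv_bin": _bin_label(cvs[j], CV_BIN_EDGES),
                                "missingness_bin": _bin_label(
                                    pct_injected, MISS_BIN_EDGES, "%"
                                ),
                                "seed": inj_seed,
                            }
                        )
    report.per_metabolite = pd.DataFrame(per_rows)
    rf = report.records_frame()
    if len(rf):
        report.aggregates = (
            rf.groupby(["mechanism", "target_rate", "method"])
            .agg(
                median_rmse=("rmse", "median"),
                iqr_rmse=("rmse", lambda s: s.quantile(0.75) - s.quantile(0.25)),
                median_pb=("percent_bias", "median"),
                iqr_pb=(
                    "percent_bias",
                    lambda s: s.quantile(0.75) - s.quantile(0.25),
                ),
                n=("rmse", "size"),
            )
            .reset_index()
        )
        report.tests["rmse_regressions"] = _rmse_regressions(report.per_metabolite)
    return report


def _rmse_regressions(per_metabolite: pd.DataFrame) -> dict[str, Any]:
    """OLS of per-metabolite RMSE on CV and on injected missingness,
    adjusting for method (the benchmark's association analysis)."""
    import statsmodels.formula.api as smf

    df = per_metabolite.dropna(subset=["cv"])
    out: dict[str, Any] = {}
    if df["method"].nunique() > 1:
        cv_fit = smf.ols("rmse ~ cv + C(method)", data=df).fit()
        miss_fit = smf.ols("rmse ~ pct_injected_missing + C(method)", data=df).fit()
    else:
        cv_fit = smf.ols("rmse ~ cv", data=df).fit()
        miss_fit = smf.ols("rmse ~ pct_injected_missing", data=df).fit()
    out["rmse_on_cv"] = {
        "estimate": float(cv_fit.params["cv"]),
        "p": float(cv_fit.pvalues["cv"]),
    }
    out["rmse_on_missingness"] = {
        "estimate": float(miss_fit.params["pct_injected_missing"]),
        "p": float(miss_fit.pvalues["pct_injected_missing"]),
    }
    return out


# -- experiment 2: internal consistency -----------------------------------


def run_consistency_assessment(
    config: BenchmarkConfig, items_axis: str = "samples"
) -> BenchmarkReport:
    """Cronbach's alpha and mean pairwise correlation, imputed vs truth."""
    raw = _materialize(config.dataset, "consistency")
    complete_raw, _ = split_complete(raw)
    table = log10_transform(complete_raw)
    alpha_true = cronbach_alpha(table, items_axis)
    corr_axis = "samples" if items_axis == "samples" else "metabolites"

    report = BenchmarkReport(
        provenance=_provenance(config, "consistency", items_axis=items_axis)
    )
    rows: list[dict[str, Any]] = []
    for rep in range(config.n_repeats):
        for mi, mech in enumerate(config.mechanisms):
            for ri, rate in enumerate(config.rates):
                inj_seed = _cell_seed(config.seed, 0, rep, mi, ri)
                try:
                    mask = inject(table, mech, rate, inj_seed)
                except Exception as exc:
                    report.diagnostics.append(
                        f"inject failed rep={rep} mech={mech} rate={rate}: {exc}"
                    )
                    continue
                masked = mask.apply(table)
                for method in config.methods:
                    imp_seed = _cell_seed(config.seed, 1, rep, mi, ri)
                    try:
                        imputed = _impute_or_oracle(
                            masked, table, method, config.method_params, imp_seed
                        )
                        rec = ConsistencyRecord(
                            alpha_true=alpha_true,
                            alpha_imputed=cronbach_alpha(imputed, items_axis),
                            alpha_diff=cronbach_alpha(imputed, items_axis)
                            - alpha_true,
                            mean_pairwise_corr=mean_pairwise_correlation(
                                imputed, corr_axis
                            ),
                            items_axis=items_axis,
                        )
                    except Exception as exc:
                        report.diagnostics.append(
                            f"cell failed rep={rep} mech={mech} rate={rate} "
                            f"method={method}: {exc}"
                        )
                        continue
                    rows.append(
                        {
                            "repeat": rep,
                            "mechanism": mech,
                            "target_rate": rate,
                            "method": method,
                            **dataclasses.asdict(rec),
                            "seed": inj_seed,
                        }
                    )
    report.consistency = pd.DataFrame(rows)
    report.tests.update(_consistency_tests(report.consistency))
    return report


def _consistency_tests(df: pd.DataFrame) -> dict[str, Any]:
    if df.empty:
        return {}
    wilcoxon: dict[str, Any] = {}
    ttests: dict[str, Any] = {}
    for (rate, mech), grp in df.groupby(["target_rate", "mechanism"]):
        groups = {
            m: sub["alpha_diff"].to_numpy()
            for m, sub in grp.groupby("method")
            if len(sub) > 0
        }
        if len(groups) >= 2:
            wilcoxon[f"rate={rate},mech={mech}"] = pairwise_wilcoxon(groups).to_dict()
    for m, sub in df.groupby("method"):
        vals = sub["alpha_diff"].to_numpy()
        try:
            t, p = one_sample_t(vals)
            ttests[m] = {"t": t, "p": p, "mean": float(np.mean(vals))}
        except ValueError:
            ttests[m] = {"t": None, "p": None, "mean": float(np.mean(vals))}
    return {"alpha_diff_wilcoxon": wilcoxon, "alpha_diff_ttests": ttests}


# -- experiment 3: downstream regression bias -----------------------------


def run_regression_bias_assessment(config: BenchmarkConfig) -> BenchmarkReport:
    """Slope/p-value bias of per-metabolite age regressions after imputation."""
    raw = _materialize(config.dataset, "regression")
    if raw.covariates is None or config.covariate not in raw.covariates:
        raise ValueError(f"dataset lacks the {config.covariate!r} covariate")
    complete_raw, _ = split_complete(raw)
    table = log10_transform(complete_raw)

    report = BenchmarkReport(provenance=_provenance(config, "regression"))
    rows: list[dict[str, Any]] = []
    for rep in range(config.n_repeats):
        for mi, mech in enumerate(config.mechanisms):
            for ri, rate in enumerate(config.rates):
                inj_seed = _cell_seed(config.seed, 0, rep, mi, ri)
                try:
                    mask = inject(table, mech, rate, inj_seed)
                except Exception as exc:
                    report.diagnostics.append(
                        f"inject failed rep={rep} mech={mech} rate={rate}: {exc}"
                    )
                    continue
                masked = mask.apply(table)
                pct_injected = 100.0 * mask.mask.sum(axis=0) / table.n_samples
                for method in config.methods:
                    imp_seed = _cell_seed(config.seed, 1, rep, mi, ri)
                    try:
                        imputed = _impute_or_oracle(
                            masked, table, method, config.method_params, imp_seed
                        )
                        recs = regression_bias(table, imputed, config.covariate)
                    except Exception as exc:
                        report.diagnostics.append(
                            f"cell failed rep={rep} mech={mech} rate={rate} "
                            f"method={method}: {exc}"
                        )
                        continue
                    for j, rec in enumerate(recs):
                        rows.append(
                            {
                                "repeat": rep,
                                "mechanism": mech,
                                "target_rate": rate,
                                "method": method,
                                **dataclasses.asdict(rec),
                                "abs_beta_diff": abs(rec.beta_imputed)
                                - abs(rec.beta_true),
                                "pct_injected_missing": float(pct_injected[j]),
                                "missingness_bin": _bin_label(
                                    float(pct_injected[j]), (10.0, 20.0, 30.0), "%"
                                ),
                                "seed": inj_seed,
                            }
                        )
    report.regression = pd.DataFrame(rows)
    report.tests.update(_regression_tests(report.regression))
    return report


def _regression_tests(df: pd.DataFrame) -> dict[str, Any]:
    if df.empty:
        return {}
    ttests: dict[str, Any] = {}
    methods = sorted(df["method"].unique())
    for m in methods:
        sub = df[df["method"] == m]
        entry: dict[str, Any] = {}
        for col in ("beta_diff", "abs_beta_diff", "p_diff"):
            vals = sub[col].to_numpy()
            try:
                t, p = one_sample_t(vals)
            except ValueError:
                t, p = None, None
            entry[col] = {
                "t": t,
                "p": p,
                "mean": float(np.mean(vals)) if len(vals) else None,
            }
        ttests[m] = entry
    # FDR across methods for the p-value-shift test
    raw_ps = [
        ttests[m]["p_diff"]["p"] for m in methods if ttests[m]["p_diff"]["p"] is not None
    ]
    fdr = fdr_adjust(raw_ps).tolist() if raw_ps else []
    fdr_map = dict(zip([m for m in methods if ttests[m]["p_diff"]["p"] is not None], fdr))
    groups = {
        m: df.loc[df["method"] == m, "abs_beta_diff"].to_numpy() for m in methods
    }
    wilcoxon = (
        pairwise_wilcoxon(groups).to_dict() if len(groups) >= 2 else {}
    )
    return {
        "bias_ttests": ttests,
        "p_diff_fdr": fdr_map,
        "abs_beta_diff_wilcoxon": wilcoxon,
    }


# -- experiment 4: in-depth single-value protocol -------------------------


def run_indepth_single_value(
    config: BenchmarkConfig,
    n_iter: int = 200,
    max_missing_pct: float = 75.0,
    sweep_rates: tuple[float, ...] = (0.10, 0.30, 0.50, 0.70),
    sweep_repeats: int = 3,
    method: str = "rf",
) -> BenchmarkReport:
    """Single-value insertion protocol plus a wide missingness sweep.

    The table must be "full" (naturally incomplete); metabolites above
    ``max_missing_pct`` missing are dropped first.  ``n_iter`` observed
    cells are masked one at a time (without replacement), the whole table
    is re-imputed, and the percent bias at the single inserted point is
    recorded with the host metabolite's natural missingness and CV.  The
    sweep injects the mixture mechanism into the table's complete subset at
    ``sweep_rates`` and records alpha (items = metabolites) and regression
    diffs for the same method.
    """
    raw = _materialize(config.dataset, "indepth")
    if raw.n_missing == 0:
        raise ValueError("in-depth protocol needs a table with natural missingness")
    filtered_raw = filter_by_missingness(raw, max_missing_pct)
    table = log10_transform(filtered_raw)
    summaries = summarize_metabolites(filtered_raw)

    observed = ~table.missing_mask
    eligible = int(observed.sum())
    if n_iter > eligible:
        logger.warning("n_iter %d exceeds %d eligible cells; capping", n_iter, eligible)
        n_iter = eligible

    report = BenchmarkReport(
        provenance=_provenance(
            config,
            "indepth",
            n_iter=n_iter,
            max_missing_pct=max_missing_pct,
            sweep_rates=list(sweep_rates),
            sweep_repeats=sweep_repeats,
            method=method,
        )
    )
    rng = np.random.default_rng(_cell_seed(config.seed, 2))
    flat = np.flatnonzero(observed)
    chosen = rng.choice(flat, size=n_iter, replace=False)
    positions = np.column_stack(np.unravel_index(chosen, observed.shape))

    rows: list[dict[str, Any]] = []
    vals = table.values
    for it, (i, j) in enumerate(positions):
        i, j = int(i), int(j)
        masked_vals = vals.copy()
        masked_vals[i, j] = np.nan
        masked = table.with_values(masked_vals)
        imp_seed = _cell_seed(config.seed, 3, it)
        try:
            res = impute(
                masked, method, params=config.method_params.get(method), seed=imp_seed
            )
        except Exception as exc:
            report.diagnostics.append(f"iteration {it} failed at ({i},{j}): {exc}")
            continue
        true_log, imp_log = float(vals[i, j]), float(res.imputed.values[i, j])
        true_raw, imp_raw = 10.0**true_log, 10.0**imp_log
        s = summaries[j]
        rows.append(
            {
                "iteration": it,
                "row": i,
                "col": j,
                "metabolite_id": table.metabolite_ids[j],
                "true_log10": true_log,
                "imputed_log10": imp_log,
                "abs_error_log10": abs(imp_log - true_log),
                "percent_bias_raw": 100.0 * abs(imp_raw - true_raw) / true_raw,
                "pct_missing": s.pct_missing,
                "cv": s.cv,
                "missingness_bin": _bin_label(s.pct_missing, MISS_BIN_EDGES, "%"),
                "seed": imp_seed,
            }
        )
    single = pd.DataFrame(rows)
    report.per_metabolite = single
    if len(single):
        report.aggregates = (
            single.groupby("missingness_bin")
            .agg(
                median_pb=("percent_bias_raw", "median"),
                median_abs_error=("abs_error_log10", "median"),
                n=("percent_bias_raw", "size"),
            )
            .reset_index()
        )
        from scipy import stats as sps

        sub = single.dropna(subset=["pct_missing"])
        rho, p = sps.spearmanr(sub["pct_missing"], sub["percent_bias_raw"])
        report.tests["pb_vs_missingness_spearman"] = {"rho": float(rho), "p": float(p)}

    # wide-missingness sweep on the complete subset
    complete_raw, _ = split_complete(filtered_raw)
    sweep_rows: list[dict[str, Any]] = []
    if complete_raw.n_metabolites >= 3:
        ctable = log10_transform(complete_raw)
        alpha_true = cronbach_alpha(ctable, "metabolites")
        has_cov = (
            ctable.covariates is not None and config.covariate in ctable.covariates
        )
        for rep in range(sweep_repeats):
            for ri, rate in enumerate(sweep_rates):
                inj_seed = _cell_seed(config.seed, 4, rep, ri)
                try:
                    mask = inject(ctable, "mix", rate, inj_seed)
                    masked = mask.apply(ctable)
                    res = impute(
                        masked,
                        method,
                        params=config.method_params.get(method),
                        seed=inj_seed,
                    )
                    row: dict[str, Any] = {
                        "repeat": rep,
                        "target_rate": rate,
                        "method": method,
                        "alpha_true": alpha_true,
                        "alpha_imputed": cronbach_alpha(res.imputed, "metabolites"),
                        "seed": inj_seed,
                    }
                    row["alpha_diff"] = row["alpha_imputed"] - alpha_true
                    if has_cov:
                        recs = regression_bias(ctable, res.imputed, config.covariate)
                        row["mean_beta_diff"] = float(
                            np.mean([r.beta_diff for r in recs])
                        )
                        row["sd_beta_diff"] = float(
                            np.std([r.beta_diff for r in recs], ddof=1)
                        )
                        row["mean_p_diff"] = float(np.mean([r.p_diff for r in recs]))
                        row["mean_abs_beta_shrink"] = float(
                            np.mean(
                                [abs(r.beta_imputed) - abs(r.beta_true) for r in recs]
                            )
                        )
                    sweep_rows.append(row)
                except Exception as exc:
                    report.diagnostics.append(
                        f"sweep failed rep={rep} rate={rate}: {exc}"
                    )
    report.consistency = pd.DataFrame(sweep_rows)
    return report


# -- reporting -------------------------------------------------------------


def write_report(
    report: BenchmarkReport, output_dir: str | Path, figures: bool = False
) -> list[Path]:
    """Write tidy CSVs plus tests.json and provenance.json.

    Empty sections still produce header-only files.  With ``figures=True``
    a boxplot per experiment section is written as well (requires
    matplotlib).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rf = report.records_frame()
    for name, df in (
        ("records", rf),
        ("per_metabolite", report.per_metabolite),
        ("consistency", report.consistency),
        ("regression", report.regression),
        ("aggregates", report.aggregates),
    ):
        path = out / f"{name}.csv"
        if df is None or df.empty:
            cols = df.columns if df is not None and len(df.columns) else []
            pd.DataFrame(columns=cols).to_csv(path, index=False)
        else:
            df.to_csv(path, index=False)
        written.append(path)

    tests_path = out / "tests.json"
    tests_path.write_text(json.dumps(report.tests, indent=2, default=_json_default))
    written.append(tests_path)
    prov_path = out / "provenance.json"
    prov_path.write_text(
        json.dumps(report.provenance, indent=2, default=_json_default)
    )
    written.append(prov_path)

    if figures:
        written.extend(_write_figures(report, out))
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_figures(report: BenchmarkReport, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: list[Path] = []
    rf = report.records_frame()
    if len(rf):
        fig, ax = plt.subplots(figsize=(8, 4))
        rf.boxplot(column="rmse", by="method", ax=ax)
        ax.set_ylabel("RMSE (log10 scale)")
        fig.suptitle("")
        path = out / "rmse_by_method.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    if len(report.consistency) and "alpha_diff" in report.consistency:
        fig, ax = plt.subplots(figsize=(8, 4))
        by = "method" if "method" in report.consistency else None
        report.consistency.boxplot(column="alpha_diff", by=by, ax=ax)
        ax.set_ylabel("alpha(imputed) - alpha(true)")
        fig.suptitle("")
        path = out / "alpha_diff.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written


_EXPERIMENTS = {
    "accuracy": run_accuracy_benchmark,
    "consistency": run_consistency_assessment,
    "regression": run_regression_bias_assessment,
}


def replay(provenance: dict[str, Any]) -> BenchmarkReport:
    """Re-run an experiment from a provenance block; output is identical."""
    ds_info = provenance["dataset"]
    if ds_info["type"] == "ReplicateSimConfig":
        dataset: Any = ReplicateSimConfig(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in ds_info["fields"].items()
            }
        )
    elif ds_info["type"] == "BioSimConfig":
        dataset = BioSimConfig(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in ds_info["fields"].items()
            }
        )
    else:
        dataset = ds_info["fields"]["path"]
    cfg = provenance["config"]
    config = BenchmarkConfig(
        dataset=dataset,
        mechanisms=tuple(cfg["mechanisms"]),
        rates=tuple(cfg["rates"]),
        methods=tuple(cfg["methods"]),
        method_params=cfg["method_params"],
        n_repeats=cfg["n_repeats"],
        seed=cfg["seed"],
        covariate=cfg.get("covariate", "age"),
    )
    experiment = provenance["experiment"]
    if experiment == "indepth":
        return run_indepth_single_value(
            config,
            n_iter=provenance["n_iter"],
            max_missing_pct=provenance["max_missing_pct"],
            sweep_rates=tuple(provenance["sweep_rates"]),
            sweep_repeats=provenance["sweep_repeats"],
            method=provenance["method"],
        )
    if experiment == "consistency":
        return run_consistency_assessment(
            config, items_axis=provenance.get("items_axis", "samples")
        )
    if experiment not in _EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    return _EXPERIMENTS[experiment](config)
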