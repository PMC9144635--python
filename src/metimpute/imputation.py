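"""Ten single-imputation methods behind a uniform interface.

Every imputer takes an :class:`~metimpute.data_model.AbundanceTable` with
missing entries and returns an :class:`ImputationResult` whose table is
complete.  Two contracts hold for all methods and are enforced centrally:

* observed cells are returned bit-identical (imputers never touch data);
* a complete input is returned unchanged (idempotence).

Simple substitution methods (zero, half-minimum, mean) are scale-aware
closed forms.  Model-based methods (kNN, SVD, BPCA, LLS, RF, GRR, QR) treat
metabolites as variables and samples as observations and are intended to run
on the log10 analysis scale; all iterative methods start from the
metabolite-mean fill so runs are reproducible.

The random-forest imputer follows the missForest iteration (per-variable
random-forest regression, variables visited in increasing order of
missingness, stopping at the first increase of the imputed-value change);
GRR iterates cross-validated ridge regressions; QR iterates per-metabolite
quantile regression; BPCA is a variational Bayes PCA with automatic
relevance determination that reconstructs missing cells from the posterior
mean of a low-rank latent model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

from .data_model import AbundanceTable, LOG10, RAW

__all__ = [
    "ImputationResult",
    "impute",
    "impute_zero",
    "impute_hm",
    "impute_mean",
    "impute_knn",
    "impute_svd",
    "impute_bpca",
    "impute_lls",
    "impute_rf",
    "impute_grr",
    "impute_qr",
    "METHODS",
]

METHODS = ("zero", "hm", "mean", "knn", "svd", "bpca", "lls", "rf", "grr", "qr")


@dataclass
class ImputationResult:
    """A completed table plus provenance and convergence diagnostics."""

    imputed: AbundanceTable
    method: str
    params: dict[str, Any] = field(default_factory=dict)
    n_iterations: int = 0
    converged: bool = True
    seed: int | None = None
    fallbacks: list[str] = field(default_factory=list)


def _check_input(table: AbundanceTable) -> tuple[np.ndarray, np.ndarray]:
    vals = table.values.copy()
    missing = np.isnan(vals)
    return vals, missing


def _result(
    table: AbundanceTable,
    filled: np.ndarray,
    missing: np.ndarray,
    method: str,
    **kwargs,
) -> ImputationResult:
    # restore observed cells bit-identically regardless of method internals
    out = table.values.copy()
    out[missing] = filled[missing]
    if np.isnan(out).any():
        raise RuntimeError(f"{method} left missing cells unimputed")
    return ImputationResult(imputed=table.with_values(out), method=method, **kwargs)


def _col_means(vals: np.ndarray, missing: np.ndarray) -> np.ndarray:
    if (missing.all(axis=0)).any():
        bad = np.flatnonzero(missing.all(axis=0))
        raise ValueError(f"metabolite column(s) {bad.tolist()} have no observed values")
    masked = np.where(missing, np.nan, vals)
    return np.nanmean(masked, axis=0)


def _mean_fill(vals: np.ndarray, missing: np.ndarray) -> np.ndarray:
    filled = vals.copy()
    means = _col_means(vals, missing)
    idx = np.nonzero(missing)
    filled[idx] = means[idx[1]]
    return filled


# -- determined-value substitution ----------------------------------------


def impute_zero(table: AbundanceTable) -> ImputationResult:
    """Missing cells become 0 on the table's current scale."""
    vals, missing = _check_input(table)
    filled = vals.copy()
    filled[missing] = 0.0
    if table.scale == RAW and missing.any():
        # zeros violate the raw-scale positivity invariant by design, so
        # skip validation for this one output
        import pandas as pd

        from .data_model import _table_unchecked

        out = table.values.copy()
        out[missing] = 0.0
        df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
        tbl = _table_unchecked(df, table.scale, table.covariates)
        return ImputationResult(imputed=tbl, method="zero")
    return _result(table, filled, missing, "zero")


def impute_hm(table: AbundanceTable) -> ImputationResult:
    """Half-minimum: a limit-of-detection surrogate.

    Raw scale: half the metabolite's minimum observed value.  Log10 scale:
    min observed - log10(2), which is the same substitution.
    """
    vals, missing = _check_input(table)
    _col_means(vals, missing)  # raises on an all-missing metabolite
    masked = np.where(missing, np.nan, vals)
    col_min = np.nanmin(masked, axis=0)
    fill = col_min - np.log10(2.0) if table.scale == LOG10 else col_min / 2.0
    filled = vals.copy()
    idx = np.nonzero(missing)
    filled[idx] = fill[idx[1]]
    return _result(table, filled, missing, "hm")


def impute_mean(table: AbundanceTable) -> ImputationResult:
    """Missing cells become the metabolite's observed mean."""
    vals, missing = _check_input(table)
    filled = _mean_fill(vals, missing)
    return _result(table, filled, missing, "mean")


# -- k-nearest neighbours --------------------------------------------------


def _knn_distances(vals: np.ndarray, missing: np.ndarray, j: int) -> np.ndarray:
    """Co-observation-normalized Euclidean distance from metabolite j to all."""
    p = vals.shape[1]
    d = np.full(p, np.inf)
    obs_j = ~missing[:, j]
    for m in range(p):
        if m == j:
            continue
        co = obs_j & ~missing[:, m]
        n_co = int(co.sum())
        if n_co == 0:
            continue
        diff = vals[co, j] - vals[co, m]
        d[m] = np.sqrt(np.sum(diff * diff) / n_co)
    return d


def impute_knn(
    table: AbundanceTable, k: int | None = None, weight: bool = True
) -> ImputationResult:
    """Neighbour-metabolite averaging.

    For each metabolite with missing cells, the k nearest metabolites by
    co-observation-normalized Euclidean distance are found; each missing
    cell becomes the (optionally 1/distance-weighted) average of the
    neighbour values observed in that sample.  When no neighbour is
    observed in the needed sample, the metabolite mean is used and the
    fallback recorded.  ``k`` defaults to min(10, available neighbours);
    an explicit ``k`` beyond the available neighbours is an error.
    """
    if k is None:
        k = min(10, table.n_metabolites - 1)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > table.n_metabolites - 1:
        raise ValueError(
            f"k={k} exceeds the {table.n_metabolites - 1} available neighbour metabolites"
        )
    vals, missing = _check_input(table)
    means = _col_means(vals, missing)
    filled = vals.copy()
    fallbacks: list[str] = []
    eps = 1e-12
    for j in range(vals.shape[1]):
        rows = np.flatnonzero(missing[:, j])
        if rows.size == 0:
            continue
        d = _knn_distances(vals, missing, j)
        finite = np.flatnonzero(np.isfinite(d))
        order = finite[np.argsort(d[finite], kind="stable")]
        neighbours = order[:k]
        for i in rows:
            avail = neighbours[~missing[i, neighbours]]
            if avail.size == 0:
                filled[i, j] = means[j]
                fallbacks.append(f"mean fallback at ({i},{j}): no neighbour observed")
                continue
            if weight:
                w = 1.0 / (d[avail] + eps)
                filled[i, j] = float(np.sum(w * vals[i, avail]) / np.sum(w))
            else:
                filled[i, j] = float(np.mean(vals[i, avail]))
    return _result(
        table,
        filled,
        missing,
        "knn",
        params={"k": k, "weight": weight},
        fallbacks=fallbacks,
    )


# -- iterative SVD completion ---------------------------------------------


def impute_svd(
    table: AbundanceTable,
    rank: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ImputationResult:
    """Iterative low-rank completion.

    Missing cells start at the metabolite mean; the matrix is repeatedly
    replaced by its truncated rank-``rank`` reconstruction at the missing
    positions (observed cells re-imposed each pass) until the largest
    relative change of an imputed cell drops below ``tol``.  ``rank``
    defaults to min(5, matrix rank - 1).
    """
    vals, missing = _check_input(table)
    n, p = vals.shape
    if rank is None:
        rank = max(1, min(5, min(n, p) - 1))
    if not 1 <= rank < min(n, p):
        raise ValueError(f"rank must be in [1, {min(n, p) - 1}]")
    filled = _mean_fill(vals, missing)
    if not missing.any():
        return _result(table, filled, missing, "svd", params={"rank": rank})
    converged = False
    it = 0
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        u, s, vt = np.linalg.svd(filled, full_matrices=False)
        recon = (u[:, :rank] * s[:rank]) @ vt[:rank]
        old = filled[missing]
        new = recon[missing]
        filled[missing] = new
        denom = max(float(np.max(np.abs(old))), 1e-12)
        change = float(np.max(np.abs(new - old))) / denom
        trace.append(change)
        if change < tol:
            converged = True
            break
    return _result(
        table,
        filled,
        missing,
        "svd",
        params={"rank": rank, "max_iter": max_iter, "tol": tol, "trace": trace},
        n_iterations=it,
        converged=converged,
    )


# -- Bayesian PCA ----------------------------------------------------------


def impute_bpca(
    table: AbundanceTable,
    n_components: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-5,
    seed: int | None = None,
) -> ImputationResult:
    """Variational Bayes PCA completion with automatic relevance determination.

    Model: for sample i with observed metabolite subset O_i,
    ``y_i = W x_i + mu + eps`` with isotropic noise ``eps ~ N(0, sigma2 I)``
    and an ARD prior ``W[:, q] ~ N(0, I / alpha_q)`` that prunes surplus
    components.  Missing cells are filled with the posterior-mean
    reconstruction ``mu + W E[x_i]``.  The procedure is deterministic
    (SVD-based initialisation); ``seed`` is accepted for interface
    uniformity only.
    """
    vals, missing = _check_input(table)
    n, p = vals.shape
    if n_components is None:
        # keep q well below the matrix rank: at q ~ rank the latent model
        # interpolates the filled matrix and EM stalls at the initial fill;
        # ARD prunes surplus components from any moderate q
        n_components = max(3, min(min(n, p) - 1, min(n, p) // 3))
    if not 1 <= n_components < min(n, p):
        raise ValueError(f"n_components must be in [1, {min(n, p) - 1}]")
    q = n_components
    filled = _mean_fill(vals, missing)
    if not missing.any():
        return _result(table, filled, missing, "bpca", params={"n_components": q})

    mu = filled.mean(axis=0)
    centred = filled - mu
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    # principal-axis initialisation: W spans the top-q right singular vectors
    W = (vt[:q].T * (s[:q] / np.sqrt(n)))
    sigma2 = max(float(np.mean(s[q:] ** 2)) / (n * max(p - q, 1)), 1e-8)
    alpha = np.full(q, 1.0)
    obs = ~missing

    converged = False
    it = 0
    prev_imputed = filled[missing].copy()
    for it in range(1, max_iter + 1):
        # E-step: posterior N(m_i, sigma2 * Minv_i) of the latent scores,
        # using only each sample's observed coordinates
        xm = np.zeros((n, q))
        sum_S = np.zeros((q, q))  # accumulated posterior second moments
        for i in range(n):
            o = obs[i]
            Wo = W[o]
            M = Wo.T @ Wo + sigma2 * np.eye(q)
            Minv = np.linalg.inv(M)
            xm[i] = Minv @ Wo.T @ (filled[i, o] - mu[o])
            sum_S += sigma2 * Minv + np.outer(xm[i], xm[i])

        # M-step on the current completed matrix (EM for the ARD model)
        centred = filled - mu
        A = sum_S + sigma2 * np.diag(alpha)
        W = np.linalg.solve(A, xm.T @ centred).T
        recon = xm @ W.T + mu
        resid = centred - xm @ W.T
        sigma2 = max(
            (float(np.sum(resid**2)) + float(np.trace((sum_S - xm.T @ xm) @ (W.T @ W))))
            / (n * p),
            1e-10,
        )
        alpha = p / (np.sum(W**2, axis=0) + 1e-10)
        mu = np.where(
            obs.any(axis=0),
            np.sum(np.where(obs, vals - xm @ W.T, 0.0), axis=0) / obs.sum(axis=0),
            mu,
        )
        filled[missing] = recon[missing]

        change = float(np.max(np.abs(filled[missing] - prev_imputed)))
        scale = max(float(np.max(np.abs(prev_imputed))), 1e-12)
        prev_imputed = filled[missing].copy()
        if change / scale < tol and it >= 5:  # let ARD shape W before testing
            converged = True
            break

    return _result(
        table,
        filled,
        missing,
        "bpca",
        params={"n_components": q, "max_iter": max_iter, "tol": tol},
        n_iterations=it,
        converged=converged,
        seed=seed,
    )


# -- local least squares ---------------------------------------------------


def _top_correlated(
    vals: np.ndarray, missing: np.ndarray, j: int, k: int, min_co: int = 3
) -> np.ndarray:
    """Indices of the k metabolites most |r|-correlated with j (co-observed)."""
    p = vals.shape[1]
    score = np.full(p, -np.inf)
    obs_j = ~missing[:, j]
    for m in range(p):
        if m == j:
            continue
        co = obs_j & ~missing[:, m]
        if int(co.sum()) < min_co:
            continue
        x, y = vals[co, j], vals[co, m]
        sx, sy = np.std(x), np.std(y)
        if sx == 0 or sy == 0:
            continue
        score[m] = abs(float(np.corrcoef(x, y)[0, 1]))
    order = np.argsort(-score, kind="stable")
    order = order[np.isfinite(score[order])]
    return order[:k]


def impute_lls(table: AbundanceTable, k: int = 10) -> ImputationResult:
    """Local least squares: regress each gap metabolite on its k most
    correlated neighbours over fully co-observed samples, then predict.

    Falls back to the metabolite mean (recorded) when too few complete rows
    exist, the design is rank-deficient, or a neighbour is missing in the
    sample to predict.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals, missing = _check_input(table)
    means = _col_means(vals, missing)
    filled = vals.copy()
    fallbacks: list[str] = []
    for j in range(vals.shape[1]):
        rows = np.flatnonzero(missing[:, j])
        if rows.size == 0:
            continue
        neighbours = _top_correlated(vals, missing, j, k)
        fitted = None
        if neighbours.size:
            fit_rows = np.flatnonzero(
                ~missing[:, j] & ~missing[:, neighbours].any(axis=1)
            )
            if fit_rows.size >= neighbours.size + 2:
                X = np.column_stack(
                    [np.ones(fit_rows.size), vals[np.ix_(fit_rows, neighbours)]]
                )
                y = vals[fit_rows, j]
                coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
                if rank == X.shape[1]:
                    fitted = coef
                else:
                    fallbacks.append(f"metabolite {j}: rank-deficient design")
            else:
                fallbacks.append(f"metabolite {j}: too few complete rows")
        else:
            fallbacks.append(f"metabolite {j}: no correlated neighbours")
        for i in rows:
            if fitted is not None and not missing[i, neighbours].any():
                filled[i, j] = float(
                    fitted[0] + vals[i, neighbours] @ fitted[1:]
                )
            else:
                filled[i, j] = means[j]
                if fitted is not None:
                    fallbacks.append(f"cell ({i},{j}): neighbour missing at sample")
    return _result(
        table, filled, missing, "lls", params={"k": k}, fallbacks=fallbacks
    )


# -- iterative model-based imputers ---------------------------------------


def _iterative_impute(
    table: AbundanceTable,
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray, int], np.ndarray],
    method: str,
    params: dict[str, Any],
    max_iter: int,
    tol: float | None,
    stop_on_increase: bool,
    seed: int | None,
) -> ImputationResult:
    """Shared chained-equations loop.

    Each sweep visits metabolites with missing cells in increasing order of
    missingness and re-predicts their missing cells from the current
    completed matrix.  With ``stop_on_increase`` (missForest rule) the loop
    stops the first time the normalized squared change of the imputed cells
    increases, returning the previous sweep's values; otherwise it stops
    when the max absolute change of imputed cells falls below ``tol``.
    """
    vals, missing = _check_input(table)
    filled = _mean_fill(vals, missing)
    if not missing.any():
        return _result(
            table, filled, missing, method, params=params, n_iterations=0, seed=seed
        )
    order = np.argsort(missing.sum(axis=0), kind="stable")
    order = [j for j in order if missing[:, j].any()]

    prev = filled.copy()
    prev_change = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        before = filled[missing].copy()
        for j in order:
            train = ~missing[:, j]
            pred_rows = np.flatnonzero(missing[:, j])
            preds = fit_predict(filled, np.array(pred_rows), np.flatnonzero(train), j)
            filled[pred_rows, j] = preds
        after = filled[missing]
        change = float(np.sum((after - before) ** 2)) / max(
            float(np.sum(after**2)), 1e-12
        )
        if stop_on_increase:
            if change > prev_change:
                filled = prev  # roll back to the previous sweep
                converged = True
                break
            prev = filled.copy()
            prev_change = change
        else:
            if tol is not None and float(np.max(np.abs(after - before))) < tol:
                converged = True
                break
    return _result(
        table,
        filled,
        missing,
        method,
        params=params,
        n_iterations=it,
        converged=converged,
        seed=seed,
    )


def impute_rf(
    table: AbundanceTable,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int | None = 0,
    max_features: str | float = "sqrt",
) -> ImputationResult:
    """missForest-style iterative random-forest imputation.

    ``max_features="sqrt"`` matches the missForest default mtry of
    floor(sqrt(p)) candidate predictors per split.
    """
    if table.n_metabolites < 2:
        raise ValueError("random-forest imputation needs >= 2 metabolites")
    from sklearn.ensemble import RandomForestRegressor

    base_seed = 0 if seed is None else int(seed)

    def fit_predict(filled, pred_rows, train_rows, j):
        X = np.delete(filled, j, axis=1)
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=(base_seed + j) % (2**32),
            max_features=max_features,
            n_jobs=1,
        )
        rf.fit(X[train_rows], filled[train_rows, j])
        return rf.predict(X[pred_rows])

    return _iterative_impute(
        table,
        fit_predict,
        "rf",
        {"n_trees": n_trees, "max_iter": max_iter, "max_features": max_features},
        max_iter=max_iter,
        tol=None,
        stop_on_increase=True,
        seed=seed,
    )


def impute_grr(
    table: AbundanceTable,
    lambda_grid: np.ndarray | None = None,
    max_iter: int = 10,
    tol: float = 1e-4,
    seed: int | None = 0,
    cv_folds: int | None = None,
) -> ImputationResult:
    """Iterative ridge-regression imputation with per-metabolite CV.

    Each metabolite with gaps is regressed on all others with an L2
    penalty chosen per metabolite over ``lambda_grid`` (default logspace
    1e-4..1e2) by efficient leave-one-out cross-validation (generalized
    CV); pass ``cv_folds`` for explicit k-fold CV instead.
    """
    if table.n_metabolites < 2:
        raise ValueError("ridge imputation needs >= 2 metabolites")
    from sklearn.linear_model import RidgeCV

    if lambda_grid is None:
        lambda_grid = np.logspace(-4, 2, 25)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    def fit_predict(filled, pred_rows, train_rows, j):
        import warnings

        X = np.delete(filled, j, axis=1)
        cv = None if cv_folds is None else min(cv_folds, len(train_rows))
        grid = lambda_grid
        if len(train_rows) <= X.shape[1]:
            # under-determined design: near-zero penalties interpolate and
            # break the leave-one-out shortcut, so floor the grid
            grid = grid[grid >= 1e-2]
            if grid.size == 0:
                grid = np.array([1e-2])
        model = RidgeCV(alphas=grid, cv=cv)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model.fit(X[train_rows], filled[train_rows, j])
        preds = model.predict(X[pred_rows])
        if not np.all(np.isfinite(preds)):
            from sklearn.linear_model import Ridge

            fallback = Ridge(alpha=1.0).fit(X[train_rows], filled[train_rows, j])
            preds = fallback.predict(X[pred_rows])
        return preds

    return _iterative_impute(
        table,
        fit_predict,
        "grr",
        {
            "lambda_grid": lambda_grid.tolist(),
            "max_iter": max_iter,
            "tol": tol,
            "cv_folds": cv_folds,
        },
        max_iter=max_iter,
        tol=tol,
        stop_on_increase=False,
        seed=seed,
    )


def impute_qr(
    table: AbundanceTable,
    quantile: float = 0.5,
    max_iter: int = 5,
    seed: int | None = 0,
    n_predictors: int = 10,
) -> ImputationResult:
    """Iterative per-metabolite quantile-regression imputation.

    Missing cells become the predicted conditional ``quantile`` (pinball
    loss) given the metabolite's most correlated peers; the design is
    restricted to the top ``n_predictors`` by |r| to keep the linear-
    programming fit well-posed when metabolites rival samples in number.
    Degenerate designs fall back to the mean (recorded).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    if table.n_metabolites < 2:
        raise ValueError("quantile-regression imputation needs >= 2 metabolites")
    import statsmodels.api as sm

    vals, missing = _check_input(table)
    fallbacks: list[str] = []

    def fit_predict(filled, pred_rows, train_rows, j):
        k = min(n_predictors, filled.shape[1] - 1)
        neighbours = _top_correlated(filled, np.zeros_like(missing), j, k)
        X = sm.add_constant(filled[np.ix_(train_rows, neighbours)], has_constant="add")
        y = filled[train_rows, j]
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.QuantReg(y, X).fit(q=quantile)
            Xp = sm.add_constant(
                filled[np.ix_(pred_rows, neighbours)], has_constant="add"
            )
            preds = np.asarray(fit.predict(Xp), dtype=float)
            if np.isnan(preds).any():
                raise ValueError("NaN prediction")
            return preds
        except Exception as exc:  # rank-deficient / non-convergent designs
            fallbacks.append(f"metabolite {j}: mean fallback ({exc})")
            return np.full(len(pred_rows), float(np.mean(y)))

    result = _iterative_impute(
        table,
        fit_predict,
        "qr",
        {"quantile": quantile, "max_iter": max_iter, "n_predictors": n_predictors},
        max_iter=max_iter,
        tol=1e-4,
        stop_on_increase=False,
        seed=seed,
    )
    result.fallbacks = fallbacks
    return result


# -- dispatcher ------------------------------------------------------------

_REGISTRY: dict[str, tuple[Callable[..., ImputationResult], dict[str, Any], bool]] = {
    # name -> (function, default params, accepts seed)
    "zero": (impute_zero, {}, False),
    "hm": (impute_hm, {}, False),
    "mean": (impute_mean, {}, False),
    "knn": (impute_knn, {"k": None, "weight": True}, False),
    "svd": (impute_svd, {"rank": None, "max_iter": 100, "tol": 1e-6}, False),
    "bpca": (impute_bpca, {"n_components": None, "max_iter": 100, "tol": 1e-5}, True),
    "lls": (impute_lls, {"k": 10}, False),
    "rf": (impute_rf, {"n_trees": 100, "max_iter": 10, "max_features": "sqrt"}, True),
    "grr": (impute_grr, {"max_iter": 10, "tol": 1e-4}, True),
    "qr": (impute_qr, {"quantile": 0.5, "max_iter": 5}, True),
}


def impute(
    table: AbundanceTable,
    method: str,
    params: dict[str, Any] | None = None,
    seed: int | None = 0,
) -> ImputationResult:
    """Uniform dispatcher over the ten-method registry.

    ``params`` overrides the registered defaults; unknown methods or unknown
    parameter names raise before any computation.  The effective parameters
    are recorded in ``result.params``.
    """
    if method not in _REGISTRY:
        raise ValueError(f"unknown imputation method {method!r}; choose from {METHODS}")
    func, defaults, takes_seed = _REGISTRY[method]
    merged = dict(defaults)
    params = params or {}
    import inspect

    allowed = set(inspect.signature(func).parameters) - {"table", "seed"}
    unknown = set(params) - allowed
    if unknown:
        raise ValueError(f"invalid parameter(s) {sorted(unknown)} for method {method!r}")
    merged.update(params)
    if takes_seed:
        result = func(table, seed=seed, **merged)
    else:
        result = func(table, **merged)
    result.params = {**merged, **result.params}
    result.seed = seed
    return result
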