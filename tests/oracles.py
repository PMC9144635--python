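"""Brute-force reference implementations used only by the test suite.

These deliberately re-derive the neighbour searches and least-squares fits
with plain loops and explicit normal equations, independently of the
package's vectorised code paths.
"""

from __future__ import annotations

import math

import numpy as np


def knn_impute_bruteforce(
    vals: np.ndarray, k: int, weight: bool, eps: float = 1e-12
) -> np.ndarray:
    """Exhaustive neighbour search + averaging for kNN imputation."""
    vals = np.asarray(vals, dtype=float)
    n, p = vals.shape
    missing = np.isnan(vals)
    out = vals.copy()
    col_means = [np.nanmean(vals[:, j]) for j in range(p)]
    for j in range(p):
        if not missing[:, j].any():
            continue
        # distance from j to every other metabolite over co-observed samples
        dists = []
        for m in range(p):
            if m == j:
                dists.append(math.inf)
                continue
            acc, cnt = 0.0, 0
            for i in range(n):
                if not missing[i, j] and not missing[i, m]:
                    acc += (vals[i, j] - vals[i, m]) ** 2
                    cnt += 1
            dists.append(math.sqrt(acc / cnt) if cnt else math.inf)
        order = sorted(
            (m for m in range(p) if math.isfinite(dists[m])),
            key=lambda m: (dists[m], m),
        )
        neighbours = order[:k]
        for i in range(n):
            if not missing[i, j]:
                continue
            avail = [m for m in neighbours if not missing[i, m]]
            if not avail:
                out[i, j] = col_means[j]
            elif weight:
                ws = [1.0 / (dists[m] + eps) for m in avail]
                out[i, j] = sum(
                    w * vals[i, m] for w, m in zip(ws, avail)
                ) / sum(ws)
            else:
                out[i, j] = sum(vals[i, m] for m in avail) / len(avail)
    return out


def lls_impute_bruteforce(vals: np.ndarray, k: int, min_co: int = 3) -> np.ndarray:
    """Correlation-ranked neighbour selection + normal-equation OLS."""
    vals = np.asarray(vals, dtype=float)
    n, p = vals.shape
    missing = np.isnan(vals)
    out = vals.copy()
    col_means = [np.nanmean(vals[:, j]) for j in range(p)]
    for j in range(p):
        if not missing[:, j].any():
            continue
        scores = []
        for m in range(p):
            if m == j:
                continue
            rows = [
                i for i in range(n) if not missing[i, j] and not missing[i, m]
            ]
            if len(rows) < min_co:
                continue
            x = vals[rows, j]
            y = vals[rows, m]
            sx, sy = np.std(x), np.std(y)
            if sx == 0 or sy == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            scores.append((m, abs(r)))
        scores.sort(key=lambda t: (-t[1], t[0]))
        neighbours = [m for m, _ in scores[:k]]
        coef = None
        if neighbours:
            fit_rows = [
                i
                for i in range(n)
                if not missing[i, j]
                and all(not missing[i, m] for m in neighbours)
            ]
            if len(fit_rows) >= len(neighbours) + 2:
                X = np.array(
                    [[1.0] + [vals[i, m] for m in neighbours] for i in fit_rows]
                )
                y = vals[fit_rows, j]
                xtx = X.T @ X
                if np.linalg.matrix_rank(xtx) == X.shape[1]:
                    coef = np.linalg.solve(xtx, X.T @ y)
        for i in range(n):
            if not missing[i, j]:
                continue
            if coef is not None and all(not missing[i, m] for m in neighbours):
                x_row = np.array([1.0] + [vals[i, m] for m in neighbours])
                out[i, j] = float(x_row @ coef)
            else:
                out[i, j] = col_means[j]
    return out


def cronbach_alpha_bruteforce(items: np.ndarray) -> float:
    """alpha from the definition: observations x items matrix."""
    items = np.asarray(items, dtype=float)
    k = items.shape[1]
    item_vars = sum(np.var(items[:, j], ddof=1) for j in range(k))
    total = np.var(items.sum(axis=1), ddof=1)
    return k / (k - 1) * (1 - item_vars / total)
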