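"""Core data containers for wide-format metabolite abundance tables.

The universal currency of the package is the :class:`AbundanceTable`: a
samples x metabolites matrix of peak abundances, on either the raw or the
log10 scale, with optional per-sample covariates (age, sex, batch).  Missing
peaks are NaN.  All downstream modules (missingness injection, imputation,
evaluation, benchmarking) consume and produce this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "MetaboliteSummary",
    "read_table",
    "write_table",
    "read_covariates",
    "log10_transform",
    "summarize_metabolites",
    "split_complete",
]

#: Cell contents interpreted as a missing value when reading delimited text.
DEFAULT_SENTINELS = frozenset({"", "NA", "NaN"})

RAW = "raw"
LOG10 = "log10"
_SCALES = (RAW, LOG10)


@dataclass
class AbundanceTable:
    """Samples x metabolites abundance matrix with IDs, scale and covariates.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with one column per metabolite.
        Missing entries are NaN.
    scale
        ``"raw"`` (every observed value strictly positive) or ``"log10"``.
    covariates
        Optional per-sample DataFrame (e.g. ``age``, ``sex``, ``batch``)
        sharing the sample index.
    """

    data: pd.DataFrame
    scale: str = RAW
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        self.data = self.data.astype(float)
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate metabolite ids: {dupes}")
        if self.scale == RAW:
            vals = self.data.to_numpy()
            observed = vals[~np.isnan(vals)]
            if observed.size and (observed <= 0).any():
                raise ValueError(
                    "raw-scale table contains non-positive observed values; "
                    "zeros/negatives are a scale error, not missingness"
                )
        if self.covariates is not None:
            if not self.covariates.index.equals(self.data.index):
                # accept any ordering but require exactly one row per sample
                missing = self.data.index.difference(self.covariates.index)
                extra = self.covariates.index.difference(self.data.index)
                if len(missing) or len(extra):
                    raise ValueError(
                        f"covariates must cover exactly the table samples "
                        f"(missing={list(missing)}, extra={list(extra)})"
                    )
                self.covariates = self.covariates.loc[self.data.index]

    # -- basic views ------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def metabolite_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        """Matrix view (n_samples, n_metabolites); NaN marks missing."""
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.data.to_numpy())

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(
            self.data.copy(),
            scale=self.scale,
            covariates=None if self.covariates is None else self.covariates.copy(),
        )

    def with_values(self, values: np.ndarray) -> "AbundanceTable":
        """Return a table with the same ids/scale/covariates but new values."""
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return AbundanceTable(df, scale=self.scale, covariates=self.covariates)

    def select_metabolites(self, ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(
            self.data[list(ids)].copy(), scale=self.scale, covariates=self.covariates
        )


def _table_unchecked(
    df: pd.DataFrame, scale: str, covariates: pd.DataFrame | None
) -> AbundanceTable:
    """Build a table without invariant validation.

    Needed for deliberately invariant-breaking outputs such as zero
    imputation on the raw scale (a raw table normally requires observed
    values > 0).
    """
    table = AbundanceTable.__new__(AbundanceTable)
    table.data = df.astype(float)
    table.scale = scale
    table.covariates = covariates
    return table


@dataclass(frozen=True)
class MetaboliteSummary:
    """Per-metabolite observed-data summary.

    ``cv`` is the analytical coefficient of variation sd/mean on the *raw*
    abundance scale; it is None (flagged, never silently zero) when the raw
    mean is non-positive or fewer than two values were observed.
    """

    metabolite_id: str
    mean: float
    sd: float
    cv: float | None
    pct_missing: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_missing <= 100.0:
            raise ValueError("pct_missing must be within [0, 100]")
        if self.cv is not None and self.cv < 0:
            raise ValueError("cv must be non-negative")


# -- I/O -------------------------------------------------------------------


def read_table(
    path: str | Path,
    orientation: str = "samples_by_metabolites",
    sep: str = ",",
    sentinels: Iterable[str] = DEFAULT_SENTINELS,
    scale: str = RAW,
) -> AbundanceTable:
    """Read a wide-format delimited abundance table.

    ``orientation`` declares the file layout: ``"samples_by_metabolites"``
    (rows are samples, the default dialect) or ``"metabolites_by_samples"``
    (transposed).  Cells whose text is in ``sentinels`` become missing;
    any other non-numeric cell is an error naming the offending row/column.
    """
    if orientation not in ("samples_by_metabolites", "metabolites_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sentinels = set(sentinels)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        raise ValueError(
            f"duplicate row ids in {path}: "
            f"{raw.index[raw.index.duplicated()].unique().tolist()}"
        )
    if raw.columns.has_duplicates:
        # pandas mangles duplicated header names as name.1, name.2; detect them
        raise ValueError(f"duplicate column ids in {path}")
    _check_mangled_duplicates(raw.columns, path)

    def parse(cell: str, row: str, col: str) -> float:
        text = cell.strip()
        if text in sentinels:
            return np.nan
        try:
            return float(text)
        except ValueError:
            raise ValueError(
                f"non-numeric cell {cell!r} at row {row!r}, column {col!r} in {path}"
            ) from None

    parsed = pd.DataFrame(
        [
            [parse(raw.iat[i, j], str(raw.index[i]), str(raw.columns[j]))
             for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index.astype(str),
        columns=raw.columns.astype(str),
    )
    if orientation == "metabolites_by_samples":
        parsed = parsed.T
    parsed.index.name = "sample_id"
    return AbundanceTable(parsed, scale=scale)


def _check_mangled_duplicates(columns: pd.Index, path: str | Path) -> None:
    # read_csv silently renames duplicate headers "m1, m1" -> "m1, m1.1";
    # reject when the de-mangled names collide.
    import re

    seen: dict[str, int] = {}
    for name in columns:
        base = re.sub(r"\.\d+$", "", str(name))
        seen[base] = seen.get(base, 0) + 1
    dupes = sorted(b for b, n in seen.items() if n > 1 and b in set(map(str, columns)))
    if dupes:
        raise ValueError(f"duplicate column ids in {path}: {dupes}")


def write_table(table: AbundanceTable, path: str | Path, sep: str = ",") -> None:
    """Write a table as delimited text (rows = samples), missing cells as NA.

    Output is deterministic: column order follows ``metabolite_ids`` and the
    float format is repr-round-trippable, so write -> read is lossless.
    """
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, na_rep="NA", float_format="%.17g")


def read_covariates(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a per-sample covariate file keyed by sample_id."""
    cov = pd.read_csv(path, sep=sep, index_col=0)
    cov.index = cov.index.astype(str)
    if cov.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in covariate file {path}")
    return cov


# -- transforms ------------------------------------------------------------


def log10_transform(table: AbundanceTable) -> AbundanceTable:
    """Log10-transform a raw-scale table; missing entries stay missing."""
    if table.scale != RAW:
        raise ValueError("table is already on the log10 scale")
    vals = table.values
    observed = vals[~np.isnan(vals)]
    if observed.size and (observed <= 0).any():
        raise ValueError("log10 transform requires all observed values > 0")
    out = pd.DataFrame(
        np.log10(vals), index=table.data.index, columns=table.data.columns
    )
    return AbundanceTable(out, scale=LOG10, covariates=table.covariates)


def unlog_transform(table: AbundanceTable) -> AbundanceTable:
    """Back-transform a log10 table to the raw abundance scale."""
    if table.scale != LOG10:
        raise ValueError("table is not on the log10 scale")
    out = pd.DataFrame(
        np.power(10.0, table.values), index=table.data.index, columns=table.data.columns
    )
    return AbundanceTable(out, scale=RAW, covariates=table.covariates)


# -- summaries -------------------------------------------------------------


def summarize_metabolites(table: AbundanceTable) -> list[MetaboliteSummary]:
    """Observed-data mean, sd (n-1), CV and percent missing per metabolite.

    The CV is always the raw-scale analytical CV: log10 tables are
    back-transformed (10**x) before computing sd/mean, since the CV of log
    values is not the conventional analytical CV.
    """
    vals = table.values
    raw_vals = np.power(10.0, vals) if table.scale == LOG10 else vals
    out: list[MetaboliteSummary] = []
    n = table.n_samples
    for j, mid in enumerate(table.metabolite_ids):
        col = vals[:, j]
        obs = col[~np.isnan(col)]
        raw_obs = raw_vals[:, j][~np.isnan(raw_vals[:, j])]
        pct_missing = 100.0 * (n - obs.size) / n if n else 0.0
        mean = float(np.mean(obs)) if obs.size else float("nan")
        sd = float(np.std(obs, ddof=1)) if obs.size >= 2 else float("nan")
        if raw_obs.size >= 2 and np.mean(raw_obs) > 0:
            cv = float(np.std(raw_obs, ddof=1) / np.mean(raw_obs))
        else:
            cv = None
        out.append(
            MetaboliteSummary(
                metabolite_id=str(mid), mean=mean, sd=sd, cv=cv, pct_missing=pct_missing
            )
        )
    return out


def split_complete(table: AbundanceTable) -> tuple[AbundanceTable, AbundanceTable]:
    """Partition into (complete_table, full_table).

    ``complete_table`` keeps exactly the metabolites with zero missing
    entries; ``full_table`` is the unmodified input.  Zero complete
    metabolites is allowed and yields an empty complete table.
    """
    complete_ids = [
        mid
        for mid, col in table.data.items()
        if not col.isna().any()
    ]
    complete = table.select_metabolites(complete_ids)
    return complete, table
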