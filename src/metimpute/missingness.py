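"""Missing-value injection under MCAR, MAR, MNAR and mixture mechanisms.

The injectors take a table (usually a complete one), a global target rate,
and a seed, and return a :class:`MissingnessMask` recording which cells were
removed, by which mechanism, and what the true values were.  Mechanisms:

* **MCAR** — cells removed uniformly at random (acquisition noise,
  incomplete derivatization).
* **MNAR** — detection-limit censoring: metabolites are picked at random,
  a per-metabolite missingness percentage is drawn from a chi-squared
  distribution, and that metabolite's *lowest* observed values are removed.
* **MAR** — interference: a random (driver, target) metabolite pair is
  drawn and the target's values are removed in the samples where the
  driver's abundance ranks highest, emulating a high-abundance co-eluting
  metabolite suppressing detection of another.
* **mixture** — MCAR, MAR and MNAR applied sequentially at equal
  proportions, never re-masking a cell.

Cell counts use round-half-away-from-zero on ``rate * n_observed`` so the
realized rate matches the target to within one cell for MCAR and mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .data_model import AbundanceTable, summarize_metabolites

__all__ = [
    "MissingnessMask",
    "SinglePoint",
    "inject_mcar",
    "inject_mar",
    "inject_mnar",
    "inject_mixture",
    "insert_single_missing",
    "filter_by_missingness",
]

MCAR = "MCAR"
MAR = "MAR"
MNAR = "MNAR"

_MAX_DRAWS = 200_000  # safety stop for the sequential MNAR/MAR loops

#: every metabolite keeps at least this many observed cells after injection,
#: so per-metabolite means/sds (and hence every imputer) stay defined
MIN_KEEP = 2


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class MissingnessMask:
    """Bookkeeping for one injection: what was removed, why, and the truth.

    ``mask[i, j]`` is True iff cell (i, j) was injected missing (cells
    already missing in the source are never masked).  ``mechanisms`` holds
    the per-cell mechanism label at masked positions ('' elsewhere) and
    ``truth`` the removed values (NaN elsewhere), so a masked table can be
    restored exactly.
    """

    mask: np.ndarray
    mechanisms: np.ndarray
    truth: np.ndarray
    target_rate: float
    realized_rate: float
    seed: int
    #: (driver_col, target_col, masked_rows) bookkeeping for each MAR event
    mar_pairs: list[tuple[int, int, tuple[int, ...]]] = field(default_factory=list)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def label_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.mechanisms[self.mask], return_counts=True)
        return {str(l): int(c) for l, c in zip(labels, counts)}

    def apply(self, table: AbundanceTable) -> AbundanceTable:
        """Return a copy of ``table`` with masked cells set to missing."""
        vals = table.values.copy()
        vals[self.mask] = np.nan
        return table.with_values(vals)

    def restore(self, masked_table: AbundanceTable) -> AbundanceTable:
        """Undo :meth:`apply` using the recorded truth."""
        vals = masked_table.values.copy()
        vals[self.mask] = self.truth[self.mask]
        return masked_table.with_values(vals)


class SinglePoint(NamedTuple):
    """Position and metabolite context of a single-value insertion."""

    row: int
    col: int
    sample_id: str
    metabolite_id: str
    true_value: float
    pct_missing: float  # host metabolite's natural missingness, percent
    cv: float | None  # host metabolite's raw-scale CV


def _quota(table: AbundanceTable, rate: float) -> tuple[np.ndarray, int, int]:
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must satisfy 0 <= rate < 1")
    observed = ~table.missing_mask
    n_observed = int(observed.sum())
    if n_observed == 0:
        raise ValueError("table has no observed cells")
    n_cells = _round_half_away(rate * n_observed)
    if n_cells >= n_observed:
        raise ValueError(
            f"rate {rate} would mask all {n_observed} observed cells"
        )
    return observed, n_observed, n_cells


def _finish(
    table: AbundanceTable,
    mask: np.ndarray,
    mechanisms: np.ndarray,
    rate: float,
    seed: int,
    mar_pairs: list[tuple[int, int, tuple[int, ...]]] | None = None,
) -> MissingnessMask:
    observed = ~table.missing_mask
    n_observed = int(observed.sum())
    truth = np.full(table.values.shape, np.nan)
    truth[mask] = table.values[mask]
    return MissingnessMask(
        mask=mask,
        mechanisms=mechanisms,
        truth=truth,
        target_rate=rate,
        realized_rate=float(mask.sum()) / n_observed,
        seed=seed,
        mar_pairs=mar_pairs or [],
    )


# -- MCAR ------------------------------------------------------------------


def inject_mcar(table: AbundanceTable, rate: float, seed: int) -> MissingnessMask:
    """Remove exactly round(rate * n_observed) cells uniformly at random."""
    observed, _, n_cells = _quota(table, rate)
    mask = np.zeros_like(observed)
    mechanisms = np.full(observed.shape, "", dtype=object)
    rng = np.random.default_rng(seed)
    _mcar_into(table, mask, mechanisms, n_cells, rng, eligible=observed)
    return _finish(table, mask, mechanisms, rate, seed)


def _remaining_per_column(table: AbundanceTable, mask: np.ndarray) -> np.ndarray:
    return (~table.missing_mask & ~mask).sum(axis=0)


def _mcar_into(
    table: AbundanceTable,
    mask: np.ndarray,
    mechanisms: np.ndarray,
    n_cells: int,
    rng: np.random.Generator,
    eligible: np.ndarray,
) -> None:
    # uniform sequential draw (shuffled scan) honouring the per-metabolite
    # floor of MIN_KEEP observed cells
    remaining = _remaining_per_column(table, mask)
    flat = np.flatnonzero(eligible & ~mask)
    if n_cells > flat.size:
        raise ValueError("not enough eligible cells for the requested MCAR count")
    rng.shuffle(flat)
    n_cols = mask.shape[1]
    taken = 0
    for idx in flat:
        if taken >= n_cells:
            break
        i, j = divmod(int(idx), n_cols)
        if remaining[j] <= MIN_KEEP:
            continue
        mask[i, j] = True
        mechanisms[i, j] = MCAR
        remaining[j] -= 1
        taken += 1
    if taken < n_cells:
        raise ValueError(
            "MCAR quota infeasible: per-metabolite observed-cell floor reached"
        )


# -- MNAR ------------------------------------------------------------------


def inject_mnar(
    table: AbundanceTable,
    rate: float,
    seed: int,
    chisq_df: float = 6.0,
    cap_frac: float = 0.8,
) -> MissingnessMask:
    """Detection-limit censoring of randomly chosen metabolites.

    Metabolites are drawn one at a time (with replacement); for each, a
    missingness percentage is sampled from chi-squared(``chisq_df``)
    (interpreted as percent, capped at ``cap_frac`` of the metabolite's
    observed cells) and that many of its lowest still-observed values are
    removed, lowest first, ties broken by sample index.  Drawing continues
    until the global quota round(rate * n_observed) is reached; the last
    draw is truncated to land on the quota exactly.
    """
    observed, _, n_cells = _quota(table, rate)
    if chisq_df <= 0:
        raise ValueError("chisq_df must be > 0")
    mask = np.zeros_like(observed)
    mechanisms = np.full(observed.shape, "", dtype=object)
    rng = np.random.default_rng(seed)
    _mnar_into(table, mask, mechanisms, n_cells, rng, observed, chisq_df, cap_frac)
    return _finish(table, mask, mechanisms, rate, seed)


def _mnar_into(
    table: AbundanceTable,
    mask: np.ndarray,
    mechanisms: np.ndarray,
    n_cells: int,
    rng: np.random.Generator,
    eligible: np.ndarray,
    chisq_df: float,
    cap_frac: float,
) -> None:
    vals = table.values
    n_obs_col = eligible.sum(axis=0)  # observed cells per metabolite at start
    remaining = _remaining_per_column(table, mask)
    cap_col = np.minimum(
        np.floor(cap_frac * n_obs_col).astype(int), remaining - MIN_KEEP
    )
    masked_col = np.zeros(vals.shape[1], dtype=int)
    removed = 0
    for _ in range(_MAX_DRAWS):
        if removed >= n_cells:
            return
        capacity = cap_col - masked_col
        open_cols = np.flatnonzero(capacity > 0)
        if open_cols.size == 0:
            raise ValueError(
                "MNAR rate infeasible: every metabolite reached its "
                f"{cap_frac:.0%} censoring cap"
            )
        j = int(rng.choice(open_cols))
        pct = float(rng.chisquare(chisq_df))
        k = _round_half_away(pct / 100.0 * n_obs_col[j])
        k = min(k, int(capacity[j]), n_cells - removed)
        if k <= 0:
            continue
        col_eligible = np.flatnonzero(eligible[:, j] & ~mask[:, j])
        # lowest observed values first; stable sort breaks ties by sample index
        order = col_eligible[np.argsort(vals[col_eligible, j], kind="stable")]
        rows = order[:k]
        mask[rows, j] = True
        mechanisms[rows, j] = MNAR
        masked_col[j] += rows.size
        removed += rows.size
    raise RuntimeError("MNAR sampling did not reach its quota (draw limit hit)")


# -- MAR -------------------------------------------------------------------


def inject_mar(
    table: AbundanceTable,
    rate: float,
    seed: int,
    pct_range: tuple[float, float] = (5.0, 50.0),
) -> MissingnessMask:
    """Interference missingness driven by a co-measured metabolite.

    Repeatedly draw a distinct (driver, target) pair; remove a
    Uniform(``pct_range``) percentage of the target's observed cells,
    starting in the samples where the driver's abundance is highest, until
    the global quota is reached (last pair truncated).
    """
    observed, _, n_cells = _quota(table, rate)
    if table.n_metabolites < 2:
        raise ValueError("MAR needs at least 2 metabolites")
    mask = np.zeros_like(observed)
    mechanisms = np.full(observed.shape, "", dtype=object)
    rng = np.random.default_rng(seed)
    pairs = _mar_into(table, mask, mechanisms, n_cells, rng, observed, pct_range)
    return _finish(table, mask, mechanisms, rate, seed, mar_pairs=pairs)


def _mar_into(
    table: AbundanceTable,
    mask: np.ndarray,
    mechanisms: np.ndarray,
    n_cells: int,
    rng: np.random.Generator,
    eligible: np.ndarray,
    pct_range: tuple[float, float],
) -> list[tuple[int, int, tuple[int, ...]]]:
    vals = table.values
    n_obs_col = eligible.sum(axis=0)
    remaining = _remaining_per_column(table, mask)
    p = vals.shape[1]
    removed = 0
    pairs: list[tuple[int, int, tuple[int, ...]]] = []
    for _ in range(_MAX_DRAWS):
        if removed >= n_cells:
            return pairs
        driver, target = rng.choice(p, size=2, replace=False)
        pct = float(rng.uniform(*pct_range))
        k = _round_half_away(pct / 100.0 * n_obs_col[target])
        k = min(k, n_cells - removed, int(remaining[target]) - MIN_KEEP)
        if k <= 0:
            continue
        # rank samples by driver abundance, highest first (NaN driver last);
        # stable sort keeps the tie-break by sample index deterministic
        driver_col = vals[:, driver]
        sort_key = np.where(np.isnan(driver_col), -np.inf, driver_col)
        order = np.argsort(-sort_key, kind="stable")
        hit = [i for i in order if eligible[i, target] and not mask[i, target]][:k]
        if not hit:
            continue
        mask[hit, target] = True
        mechanisms[hit, target] = MAR
        remaining[target] -= len(hit)
        removed += len(hit)
        pairs.append((int(driver), int(target), tuple(int(i) for i in hit)))
    raise RuntimeError("MAR sampling did not reach its quota (draw limit hit)")


# -- mixture ---------------------------------------------------------------


def inject_mixture(
    table: AbundanceTable,
    rate: float,
    seed: int,
    chisq_df: float = 6.0,
    cap_frac: float = 0.8,
    pct_range: tuple[float, float] = (5.0, 50.0),
) -> MissingnessMask:
    """MCAR, MAR and MNAR applied sequentially at equal proportions.

    The global quota is split three ways; any remainder cells are assigned
    in the fixed order MCAR -> MAR -> MNAR, so mechanism counts differ
    pairwise by at most one.  Later mechanisms only see still-observed
    cells, so the three sub-masks are disjoint.
    """
    observed, _, n_cells = _quota(table, rate)
    if table.n_metabolites < 2:
        raise ValueError("mixture needs at least 2 metabolites (for MAR)")
    base, rem = divmod(n_cells, 3)
    quotas = {
        MCAR: base + (1 if rem >= 1 else 0),
        MAR: base + (1 if rem >= 2 else 0),
        MNAR: base,
    }
    mask = np.zeros_like(observed)
    mechanisms = np.full(observed.shape, "", dtype=object)
    ss = np.random.SeedSequence(seed)
    rng_mcar, rng_mar, rng_mnar = (np.random.default_rng(c) for c in ss.spawn(3))

    eligible = observed & ~mask
    _mcar_into(table, mask, mechanisms, quotas[MCAR], rng_mcar, eligible)
    eligible = observed & ~mask
    pairs = _mar_into(
        table, mask, mechanisms, quotas[MAR], rng_mar, eligible, pct_range
    )
    eligible = observed & ~mask
    _mnar_into(
        table, mask, mechanisms, quotas[MNAR], rng_mnar, eligible, chisq_df, cap_frac
    )
    return _finish(table, mask, mechanisms, rate, seed, mar_pairs=pairs)


MECHANISMS = {
    "mcar": inject_mcar,
    "mar": inject_mar,
    "mnar": inject_mnar,
    "mix": inject_mixture,
}


def inject(
    table: AbundanceTable, mechanism: str, rate: float, seed: int, **kwargs
) -> MissingnessMask:
    """Dispatch to an injector by mechanism name (mcar|mar|mnar|mix)."""
    key = mechanism.lower()
    if key not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}; choose from {sorted(MECHANISMS)}")
    return MECHANISMS[key](table, rate, seed, **kwargs)


# -- single-value insertion ------------------------------------------------


def insert_single_missing(
    full_table: AbundanceTable,
    seed: int,
    exclude: set[tuple[int, int]] | None = None,
) -> tuple[MissingnessMask, SinglePoint]:
    """Mask exactly one observed cell, sampled uniformly from unused cells.

    ``exclude`` holds (row, col) positions already used so repeated calls
    sample without replacement.  Returns the mask and the position with the
    host metabolite's natural percent-missing and CV (computed on the table
    *before* insertion).
    """
    exclude = exclude or set()
    observed = ~full_table.missing_mask
    flat = np.flatnonzero(observed)
    rows, cols = np.unravel_index(flat, observed.shape)
    usable = [
        (int(r), int(c)) for r, c in zip(rows, cols) if (int(r), int(c)) not in exclude
    ]
    if not usable:
        raise ValueError("no eligible observed cells outside the exclude set")
    rng = np.random.default_rng(seed)
    i, j = usable[int(rng.integers(len(usable)))]

    mask = np.zeros(observed.shape, dtype=bool)
    mask[i, j] = True
    mechanisms = np.full(observed.shape, "", dtype=object)
    mechanisms[i, j] = MCAR
    summary = summarize_metabolites(full_table)[j]
    point = SinglePoint(
        row=i,
        col=j,
        sample_id=str(full_table.sample_ids[i]),
        metabolite_id=str(full_table.metabolite_ids[j]),
        true_value=float(full_table.values[i, j]),
        pct_missing=summary.pct_missing,
        cv=summary.cv,
    )
    return _finish(full_table, mask, mechanisms, 0.0, seed), point


def filter_by_missingness(full_table: AbundanceTable, max_pct: float) -> AbundanceTable:
    """Retain metabolites with percent-missing <= max_pct."""
    if not 0.0 <= max_pct <= 100.0:
        raise ValueError("max_pct must be within [0, 100]")
    keep = [
        s.metabolite_id
        for s in summarize_metabolites(full_table)
        if s.pct_missing <= max_pct
    ]
    return full_table.select_metabolites(keep)
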