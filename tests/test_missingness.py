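import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metimpute import (
    AbundanceTable,
    ReplicateSimConfig,
    filter_by_missingness,
    generate_replicate_dataset,
    inject_mar,
    inject_mcar,
    inject_mixture,
    inject_mnar,
    insert_single_missing,
    log10_transform,
    split_complete,
)
from metimpute.missingness import inject


@pytest.fixture(scope="module")
def replicate_log_table():
    return log10_transform(generate_replicate_dataset(ReplicateSimConfig(seed=0)))


def small_table(n=10, p=10, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.uniform(10, 1000, size=(n, p)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"m{j}" for j in range(p)],
    )
    return AbundanceTable(df, scale="raw")


class TestMcar:
    def test_zero_rate_empty_mask(self, replicate_log_table):
        mask = inject_mcar(replicate_log_table, 0.0, seed=1)
        assert mask.n_masked == 0

    def test_exact_count_at_ten_percent(self, replicate_log_table):
        mask = inject_mcar(replicate_log_table, 0.10, seed=1)
        assert mask.n_masked == 900  # 0.10 x (150 x 60)
        assert mask.realized_rate == pytest.approx(0.10)

    def test_never_masks_already_missing(self):
        t = small_table()
        vals = t.values.copy()
        vals[0, 0] = np.nan
        t = t.with_values(vals)
        mask = inject_mcar(t, 0.3, seed=2)
        assert not mask.mask[0, 0]

    def test_per_cell_uniformity(self):
        # chi-square goodness of fit over many seeds on a 10x10 table
        t = small_table()
        counts = np.zeros((10, 10))
        n_seeds = 2000
        for s in range(n_seeds):
            counts += inject_mcar(t, 0.1, seed=s).mask
        expected = n_seeds * 0.1
        chisq = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chisq, df=99)
        assert p > 0.001

    def test_masked_values_unbiased(self):
        # MCAR signature: masked-cell mean indistinguishable from unmasked
        t = small_table(n=20, p=10, seed=3)
        pvals = []
        for s in range(200):
            mask = inject_mcar(t, 0.2, seed=s)
            masked_vals = t.values[mask.mask]
            unmasked = t.values[~mask.mask]
            pvals.append(stats.ttest_ind(masked_vals, unmasked).pvalue)
        frac_sig = np.mean(np.array(pvals) < 0.05)
        assert frac_sig <= 0.12  # ~5% under the null


class TestMnar:
    def test_zero_rate_empty(self, replicate_log_table):
        assert inject_mnar(replicate_log_table, 0.0, seed=1).n_masked == 0

    def test_masks_only_within_metabolite_minima(self, replicate_log_table):
        mask = inject_mnar(replicate_log_table, 0.15, seed=4)
        vals = replicate_log_table.values
        for j in range(vals.shape[1]):
            col_mask = mask.mask[:, j]
            if not col_mask.any():
                continue
            assert np.max(vals[col_mask, j]) <= np.min(vals[~col_mask, j])

    def test_realized_rate_tracks_target(self, replicate_log_table):
        n_obs = replicate_log_table.n_samples * replicate_log_table.n_metabolites
        for s in range(100):
            mask = inject_mnar(replicate_log_table, 0.2, seed=s)
            assert abs(mask.realized_rate - 0.2) <= 1.0 / n_obs

    def test_masked_mean_below_unmasked_per_metabolite(self, replicate_log_table):
        mask = inject_mnar(replicate_log_table, 0.2, seed=5)
        vals = replicate_log_table.values
        for j in range(vals.shape[1]):
            col_mask = mask.mask[:, j]
            if col_mask.any():
                assert vals[col_mask, j].mean() < vals[~col_mask, j].mean()

    def test_invalid_df_rejected(self, replicate_log_table):
        with pytest.raises(ValueError):
            inject_mnar(replicate_log_table, 0.1, seed=0, chisq_df=0)


class TestMar:
    def test_zero_rate_empty(self, replicate_log_table):
        assert inject_mar(replicate_log_table, 0.0, seed=1).n_masked == 0

    def test_requires_two_metabolites(self):
        df = pd.DataFrame({"m1": [1.0, 2.0, 3.0]}, index=list("abc"))
        with pytest.raises(ValueError, match="2 metabolites"):
            inject_mar(AbundanceTable(df, scale="raw"), 0.2, seed=0)

    def test_masked_rows_are_drivers_top_ranks(self, replicate_log_table):
        mask = inject_mar(replicate_log_table, 0.1, seed=6)
        vals = replicate_log_table.values
        assert mask.mar_pairs
        claimed = set()
        for driver, target, rows in mask.mar_pairs:
            assert driver != target
            # rows must be the top-|rows| driver abundances among cells of
            # the target that were still maskable when the pair was drawn
            order = np.argsort(-vals[:, driver], kind="stable")
            available = [
                i for i in order if (i, target) not in claimed
            ][: len(rows)]
            assert sorted(rows) == sorted(available)
            claimed.update((i, target) for i in rows)

    def test_high_driver_abundance_signature(self):
        t = small_table(n=30, p=6, seed=9)
        hits = 0
        n_seeds = 500
        for s in range(n_seeds):
            mask = inject_mar(t, 0.1, seed=s)
            ok = True
            for driver, target, rows in mask.mar_pairs:
                drv = t.values[:, driver]
                if drv[list(rows)].mean() <= drv.mean():
                    ok = False
            hits += ok
        assert hits / n_seeds >= 0.99


class TestMixture:
    def test_equal_proportions_at_twelve_percent(self, replicate_log_table):
        mask = inject_mixture(replicate_log_table, 0.12, seed=7)
        assert mask.n_masked == 1080
        assert mask.label_counts() == {"MCAR": 360, "MAR": 360, "MNAR": 360}

    @pytest.mark.parametrize("rate", [0.02, 0.05, 0.10, 0.33])
    def test_label_counts_differ_by_at_most_one(self, replicate_log_table, rate):
        counts = inject_mixture(replicate_log_table, rate, seed=8).label_counts()
        values = [counts.get(m, 0) for m in ("MCAR", "MAR", "MNAR")]
        assert max(values) - min(values) <= 1

    def test_sub_masks_disjoint(self, replicate_log_table):
        mask = inject_mixture(replicate_log_table, 0.2, seed=9)
        # every masked cell carries exactly one mechanism label
        labels = mask.mechanisms[mask.mask]
        assert set(labels) == {"MCAR", "MAR", "MNAR"}
        assert (mask.mechanisms[~mask.mask] == "").all()

    def test_apply_then_restore_is_identity(self, replicate_log_table):
        mask = inject_mixture(replicate_log_table, 0.25, seed=10)
        masked = mask.apply(replicate_log_table)
        assert np.isnan(masked.values[mask.mask]).all()
        restored = mask.restore(masked)
        np.testing.assert_array_equal(restored.values, replicate_log_table.values)

    def test_supported_rates_span_published_range(self, replicate_log_table):
        for rate in (0.02, 0.70):
            mask = inject_mixture(replicate_log_table, rate, seed=11)
            n_obs = 150 * 60
            assert abs(mask.realized_rate - rate) <= 1.0 / n_obs

    def test_dispatch_by_name(self, replicate_log_table):
        a = inject(replicate_log_table, "mix", 0.1, seed=3)
        b = inject_mixture(replicate_log_table, 0.1, seed=3)
        np.testing.assert_array_equal(a.mask, b.mask)
        with pytest.raises(ValueError, match="unknown mechanism"):
            inject(replicate_log_table, "magic", 0.1, seed=3)


class TestSinglePointInsertion:
    def test_exactly_one_cell(self, tiny_table):
        mask, point = insert_single_missing(tiny_table, seed=0)
        assert mask.n_masked == 1
        assert mask.mask[point.row, point.col]
        assert point.true_value == tiny_table.values[point.row, point.col]

    def test_deterministic_given_seed_and_exclude(self, tiny_table):
        ex = {(0, 0)}
        _, p1 = insert_single_missing(tiny_table, seed=5, exclude=ex)
        _, p2 = insert_single_missing(tiny_table, seed=5, exclude=ex)
        assert (p1.row, p1.col) == (p2.row, p2.col)

    def test_sampling_without_replacement(self):
        t = small_table(n=6, p=6, seed=1)
        exclude: set[tuple[int, int]] = set()
        for s in range(36):
            _, point = insert_single_missing(t, seed=s, exclude=exclude)
            assert (point.row, point.col) not in exclude
            exclude.add((point.row, point.col))
        assert len(exclude) == 36
        with pytest.raises(ValueError, match="no eligible"):
            insert_single_missing(t, seed=99, exclude=exclude)

    def test_reports_host_metabolite_context(self):
        t = small_table(n=10, p=3, seed=2)
        vals = t.values.copy()
        vals[:3, 1] = np.nan
        t = t.with_values(vals)
        # force the insertion into column 1 by excluding all other cells
        exclude = {
            (i, j) for i in range(10) for j in (0, 2)
        }
        _, point = insert_single_missing(t, seed=1, exclude=exclude)
        assert point.col == 1
        assert point.pct_missing == pytest.approx(30.0)


class TestFilterByMissingness:
    def test_threshold(self):
        t = small_table(n=10, p=3, seed=3)
        vals = t.values.copy()
        vals[:5, 1] = np.nan  # 50%
        vals[:8, 2] = np.nan  # 80%
        t = t.with_values(vals)
        kept = filter_by_missingness(t, 75.0)
        assert kept.metabolite_ids == ["m0", "m1"]

    def test_identity_at_hundred(self, tiny_table):
        assert (
            filter_by_missingness(tiny_table, 100.0).metabolite_ids
            == tiny_table.metabolite_ids
        )

    def test_zero_matches_complete_split(self, tiny_table):
        complete, _ = split_complete(tiny_table)
        kept = filter_by_missingness(tiny_table, 0.0)
        assert kept.metabolite_ids == complete.metabolite_ids
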