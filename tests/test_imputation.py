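import numpy as np
import pandas as pd
import pytest

from metimpute import AbundanceTable, METHODS, impute, rmse
from metimpute.imputation import (
    impute_bpca,
    impute_grr,
    impute_hm,
    impute_knn,
    impute_lls,
    impute_mean,
    impute_qr,
    impute_rf,
    impute_svd,
    impute_zero,
)

from .oracles import knn_impute_bruteforce, lls_impute_bruteforce
from .conftest import make_log_table


def gapped_log_table(n=12, p=6, frac=0.15, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(5.0, 0.6, size=(n, p))
    missing = rng.random((n, p)) < frac
    missing[:, 0] = False  # keep one gap-free metabolite
    vals[missing] = np.nan
    return make_log_table(vals)


class TestContracts:
    """Observed-cell preservation and idempotence hold for all ten methods."""

    @pytest.mark.parametrize("method", METHODS)
    def test_observed_cells_bit_identical(self, method):
        table = gapped_log_table(seed=1)
        result = impute(table, method, seed=3)
        observed = ~np.isnan(table.values)
        np.testing.assert_array_equal(
            result.imputed.values[observed], table.values[observed]
        )
        assert not np.isnan(result.imputed.values).any()

    @pytest.mark.parametrize("method", METHODS)
    def test_identity_on_complete_table(self, method, complete_log_table):
        result = impute(complete_log_table, method, seed=3)
        np.testing.assert_array_equal(
            result.imputed.values, complete_log_table.values
        )


class TestSubstitutionMethods:
    def test_zero_fill(self):
        t = make_log_table([[1.2, 0.5], [np.nan, 0.7], [3.4, 0.9]])
        out = impute_zero(t).imputed.values
        assert out[1, 0] == 0.0

    def test_half_minimum_on_raw_scale(self):
        df = pd.DataFrame({"m1": [2.0, 4.0, np.nan], "m2": [1.0, 1.0, 1.0]},
                          index=list("abc"))
        out = impute_hm(AbundanceTable(df, scale="raw")).imputed
        assert out.data.loc["c", "m1"] == 1.0

    def test_half_minimum_log_scale_equivalence(self):
        # log10 column [log10(2), log10(4), NA] -> NA = log10(2) - log10(2) = 0
        t = make_log_table([[0.30103, 1.0], [0.60206, 1.0], [np.nan, 1.0]])
        out = impute_hm(t).imputed.values
        assert out[2, 0] == pytest.approx(0.0, abs=1e-5)

    def test_hm_rejects_all_missing_metabolite(self):
        t = make_log_table([[np.nan, 1.0], [np.nan, 2.0]])
        with pytest.raises(ValueError, match="no observed"):
            impute_hm(t)

    def test_mean_fill_and_mean_preservation(self):
        t = make_log_table([[1.0, 9.9], [2.0, 9.9], [np.nan, 9.9]])
        out = impute_mean(t).imputed.values
        assert out[2, 0] == pytest.approx(1.5)
        assert np.mean(out[:, 0]) == pytest.approx(np.nanmean(t.values[:, 0]))


class TestKnn:
    def test_duplicate_metabolite_is_exact_neighbour(self):
        base = np.array([5.0, 5.5, 6.0, 6.5, 7.0])
        vals = np.column_stack([base, base, base[::-1] + 0.3])
        vals = np.column_stack([vals, vals[:, 2] * 0.5 + 3])
        vals[2, 0] = np.nan
        t = make_log_table(vals)
        out = impute_knn(t, k=1).imputed.values
        assert out[2, 0] == pytest.approx(base[2], abs=1e-9)

    @pytest.mark.parametrize("weight", [True, False])
    def test_matches_bruteforce_oracle(self, weight):
        table = gapped_log_table(n=6, p=6, frac=0.2, seed=4)
        mine = impute_knn(table, k=2, weight=weight).imputed.values
        oracle = knn_impute_bruteforce(table.values, k=2, weight=weight)
        np.testing.assert_allclose(mine, oracle, atol=1e-8)

    def test_k_exceeding_neighbours_rejected(self):
        t = gapped_log_table(p=4)
        with pytest.raises(ValueError, match="exceeds"):
            impute_knn(t, k=4)


class TestSvd:
    def test_rank_one_completion(self):
        u = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        v = np.array([2.0, 1.0, 0.5, 4.0])
        vals = np.outer(u, v)
        vals[2, 1] = np.nan
        t = make_log_table(vals)
        result = impute_svd(t, rank=1, tol=1e-9, max_iter=1000)
        assert result.converged
        assert result.imputed.values[2, 1] == pytest.approx(
            u[2] * v[1], abs=1e-6
        )

    def test_invalid_rank(self):
        with pytest.raises(ValueError, match="rank"):
            impute_svd(gapped_log_table(), rank=0)

    def test_convergence_trace_settles(self):
        # imputed-cell change decays toward the tolerance; on data without
        # exact low-rank structure the decay is slow and honestly flagged
        table = gapped_log_table(n=20, p=8, frac=0.2, seed=6)
        result = impute_svd(table, rank=3, max_iter=100)
        trace = result.params["trace"]
        assert len(trace) == result.n_iterations
        assert trace[-1] < trace[0] / 10
        assert all(b <= a * 1.5 for a, b in zip(trace, trace[1:]))  # no blow-up


class TestBpca:
    def test_beats_mean_on_factor_structured_data(self):
        rng = np.random.default_rng(11)
        n, p, q = 60, 20, 2
        scores = rng.standard_normal((n, q))
        loadings = rng.normal(0, 1.0, size=(p, q))
        vals = 5.0 + scores @ loadings.T + rng.normal(0, 0.1, size=(n, p))
        mask = rng.random((n, p)) < 0.10
        masked_vals = vals.copy()
        masked_vals[mask] = np.nan
        t = make_log_table(masked_vals)
        r_bpca = impute_bpca(t)
        r_mean = impute_mean(t)
        assert rmse(vals, r_bpca.imputed.values, mask) < rmse(
            vals, r_mean.imputed.values, mask
        )

    def test_deterministic(self):
        t = gapped_log_table(seed=8)
        a = impute_bpca(t, seed=1).imputed.values
        b = impute_bpca(t, seed=2).imputed.values
        np.testing.assert_array_equal(a, b)

    def test_invalid_components(self):
        with pytest.raises(ValueError, match="n_components"):
            impute_bpca(gapped_log_table(n=6, p=4), n_components=4)


class TestLls:
    def test_exact_linear_relation_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = 2.0 * x
        vals = np.column_stack([x, y, x[::-1] * 0.1 + 5])
        vals[4, 1] = np.nan
        t = make_log_table(vals)
        out = impute_lls(t, k=1).imputed.values
        assert out[4, 1] == pytest.approx(2.0 * x[4], abs=1e-8)

    def test_zero_k_rejected(self):
        with pytest.raises(ValueError, match="k"):
            impute_lls(gapped_log_table(), k=0)

    def test_matches_bruteforce_oracle(self):
        table = gapped_log_table(n=8, p=6, frac=0.15, seed=12)
        mine = impute_lls(table, k=3).imputed.values
        oracle = lls_impute_bruteforce(table.values, k=3)
        np.testing.assert_allclose(mine, oracle, atol=1e-8)

    def test_fallbacks_recorded_not_silent(self):
        # 3 samples cannot support an OLS fit with 2 neighbours
        vals = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [np.nan, 4.0, 5.0]])
        result = impute_lls(make_log_table(vals), k=2)
        assert result.fallbacks
        assert not np.isnan(result.imputed.values).any()


class TestRf:
    def test_recovers_piecewise_relation(self):
        rng = np.random.default_rng(13)
        n = 200
        x = np.concatenate([rng.uniform(-1, -0.2, n // 2), rng.uniform(0.2, 1, n // 2)])
        rng.shuffle(x)
        y = np.where(x > 0, 1.0, -1.0)
        filler = rng.normal(0, 0.05, size=n)  # uninformative third column
        vals = np.column_stack([x, y, filler])
        missing_rows = rng.choice(n, size=n // 5, replace=False)
        truth = y[missing_rows].copy()
        vals[missing_rows, 1] = np.nan
        t = make_log_table(vals)
        out = impute_rf(t, n_trees=50, seed=0, max_features=1.0).imputed.values
        assert np.all(np.abs(out[missing_rows, 1] - truth) < 0.2)

    def test_deterministic_given_seed(self):
        t = gapped_log_table(seed=14)
        a = impute_rf(t, n_trees=20, seed=7).imputed.values
        b = impute_rf(t, n_trees=20, seed=7).imputed.values
        np.testing.assert_array_equal(a, b)

    def test_no_missing_zero_iterations(self, complete_log_table):
        result = impute_rf(complete_log_table, n_trees=10, seed=0)
        assert result.n_iterations == 0


class TestGrr:
    def test_ridge_to_ols_limit_on_exact_relation(self):
        x = np.linspace(1.0, 3.0, 12)
        vals = np.column_stack([x, 3.0 * x])
        vals[5, 1] = np.nan
        t = make_log_table(vals)
        out = impute_grr(t, lambda_grid=np.array([1e-6, 1e-4])).imputed.values
        assert out[5, 1] == pytest.approx(3.0 * x[5], abs=1e-3)

    def test_shrinkage_monotone_in_lambda(self):
        rng = np.random.default_rng(15)
        x = rng.normal(0, 1, 30) + 5
        y = 1.5 * x + rng.normal(0, 0.05, 30)
        vals = np.column_stack([x, y])
        vals[0, 1] = np.nan
        t = make_log_table(vals)
        # OLS prediction for the missing cell
        fit_rows = np.arange(1, 30)
        X = np.column_stack([np.ones(29), x[fit_rows]])
        coef = np.linalg.lstsq(X, y[fit_rows], rcond=None)[0]
        ols_pred = coef[0] + coef[1] * x[0]
        devs = []
        for lam in (1e-3, 1.0, 1e3):
            out = impute_grr(t, lambda_grid=np.array([lam])).imputed.values
            devs.append(abs(out[0, 1] - ols_pred))
        assert devs[0] <= devs[1] <= devs[2]


class TestQr:
    def test_conditional_median_recovered(self):
        rng = np.random.default_rng(16)
        n = 150
        x = rng.uniform(3, 7, n)
        y = x + rng.uniform(-0.2, 0.2, n)  # symmetric noise, median = x
        vals = np.column_stack([x, y])
        miss = rng.choice(n, size=15, replace=False)
        truth = y[miss].copy()
        vals[miss, 1] = np.nan
        t = make_log_table(vals)
        out = impute_qr(t, quantile=0.5).imputed.values
        assert np.mean(np.abs(out[miss, 1] - x[miss])) < 0.1

    def test_invalid_quantile(self):
        with pytest.raises(ValueError, match="quantile"):
            impute_qr(gapped_log_table(), quantile=1.5)


class TestDispatcher:
    def test_dispatch_matches_direct_call(self):
        t = gapped_log_table(seed=17)
        np.testing.assert_array_equal(
            impute(t, "mean").imputed.values, impute_mean(t).imputed.values
        )

    def test_unknown_method_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="unknown imputation method"):
            impute(tiny_table, "magic")

    def test_unknown_param_rejected_before_compute(self, tiny_table):
        with pytest.raises(ValueError, match="invalid parameter"):
            impute(tiny_table, "knn", params={"bogus": 1})

    def test_param_override_recorded(self):
        t = gapped_log_table(seed=18)
        result = impute(t, "knn", params={"k": 3})
        assert result.params["k"] == 3
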