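"""Design construction and robust OLS inference."""

import numpy as np
import pandas as pd
import pytest

from ltued import (
    ConditionFit,
    DesignSpec,
    EstimationError,
    InputDataError,
    build_design,
    fit_ols_robust,
    summarize_quintile_effects,
)
from ltued.regress import QUINTILE_TERMS, significance_stars
from ltued.synth import TEETH_CONDITION


def brute_force_ols_hc1(y, X):
    """Independent sandwich recomputation with explicit matrix products."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    e = y - X @ beta
    meat = X.T @ np.diag(e**2) @ X
    V = (n / (n - k)) * XtX_inv @ meat @ XtX_inv
    return beta, V


class TestDesign:
    def test_reference_coding(self, small_analysis):
        cond = small_analysis["panel"].conditions[0]
        X = small_analysis["designs"][cond]
        q = small_analysis["assignments"].set_index("zcta_id")["quintile"]
        for zid, quintile in q.items():
            row = X.loc[zid, list(QUINTILE_TERMS)].to_numpy()
            expected = np.zeros(4)
            if quintile > 1:
                expected[quintile - 2] = 1.0
            np.testing.assert_array_equal(row, expected)

    def test_teeth_condition_gains_two_dental_columns(self):
        base = DesignSpec.for_condition("abdominal_pain")
        teeth = DesignSpec.for_condition(TEETH_CONDITION)
        assert len(teeth.all_covariates()) == len(base.all_covariates()) + 2
        assert "dentist_ratio_per_1000" in teeth.all_covariates()

    def test_rows_sorted_by_zcta_id(self, small_analysis):
        cond = small_analysis["panel"].conditions[0]
        X = small_analysis["designs"][cond]
        assert list(X.index) == sorted(X.index)

    def test_missing_assignment_named(self, small_analysis):
        cond = small_analysis["panel"].conditions[0]
        broken = small_analysis["assignments"].iloc[1:]
        dropped = small_analysis["assignments"]["zcta_id"].iloc[0]
        with pytest.raises(InputDataError, match=str(dropped)):
            build_design(
                small_analysis["panel"], small_analysis["zcta"], broken,
                DesignSpec.for_condition(cond),
            )

    def test_fraction_scale_divides_percentages(self, small_analysis):
        cond = small_analysis["panel"].conditions[0]
        _, Xp, _ = build_design(
            small_analysis["panel"], small_analysis["zcta"],
            small_analysis["assignments"], DesignSpec.for_condition(cond),
        )
        _, Xf, _ = build_design(
            small_analysis["panel"], small_analysis["zcta"],
            small_analysis["assignments"],
            DesignSpec.for_condition(cond, covariate_scale="fraction"),
        )
        np.testing.assert_allclose(Xf["pct_white"], Xp["pct_white"] / 100.0)


class TestOlsRobust:
    def test_exact_linear_interpolation(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"const": 1.0, "x": x})
        fit = fit_ols_robust(pd.Series(2.0 + 3.0 * x), X)
        np.testing.assert_allclose(fit.params.to_numpy(), [2.0, 3.0], atol=1e-12)
        np.testing.assert_allclose(fit.bse.to_numpy(), 0.0, atol=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_brute_force_sandwich(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n, k = int(rng.integers(20, 60)), int(rng.integers(2, 8))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
            y = X @ rng.normal(size=k) + rng.normal(size=n) * rng.uniform(0.5, 2)
            fit = fit_ols_robust(pd.Series(y), pd.DataFrame(X))
            beta, V = brute_force_ols_hc1(y, X)
            np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-8)
            np.testing.assert_allclose(fit.cov_params.to_numpy(), V, rtol=1e-8)

    def test_hc1_is_hc0_times_dof_factor(self):
        rng = np.random.default_rng(9)
        n, k = 40, 4
        X = pd.DataFrame(np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))]))
        y = pd.Series(rng.normal(size=n))
        se0 = fit_ols_robust(y, X, cov_type="HC0").bse.to_numpy()
        se1 = fit_ols_robust(y, X, cov_type="HC1").bse.to_numpy()
        np.testing.assert_allclose(se1, se0 * np.sqrt(n / (n - k)), rtol=1e-12)

    def test_equal_residual_magnitudes_match_classical_se(self):
        """When all residuals have the same magnitude the HC1 sandwich
        collapses to the classical OLS variance (the n/(n-k) correction
        exactly offsets the missing averaging)."""
        import statsmodels.api as sm

        n = 20
        x = np.tile([0.0, 1.0], n // 2)
        y = np.tile([0.0, 1.0, 1.0, 0.0], n // 4) * 2 - 0.5  # residuals +/- const
        X = pd.DataFrame({"const": np.ones(n), "x": x})
        fit = fit_ols_robust(pd.Series(y), X, cov_type="HC1")
        assert len(set(np.round(np.abs(y - sm.OLS(y, X).fit().fittedvalues), 12))) == 1
        classical = sm.OLS(y, X).fit().bse
        np.testing.assert_allclose(fit.bse.to_numpy(), classical, rtol=1e-10)

    def test_all_zero_covariate_raises_rank_error(self, small_analysis):
        cond = small_analysis["panel"].conditions[0]
        X = small_analysis["designs"][cond].copy()
        X["dead_column"] = 0.0
        y = small_analysis["panel"].rates[cond]
        with pytest.raises(EstimationError, match="dead_column"):
            fit_ols_robust(y.sort_index(), X)

    def test_more_terms_than_rows_rejected(self):
        X = pd.DataFrame(np.eye(3))
        with pytest.raises(InputDataError):
            fit_ols_robust(pd.Series([1.0, 2.0, 3.0]), X)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(10)
        n = 50
        X = pd.DataFrame(
            np.column_stack([np.ones(n), rng.normal(size=(n, 3))]),
            columns=["const", "a", "b", "c"],
        )
        y = pd.Series(X.to_numpy() @ [1, 2, 3, 4] + rng.normal(size=n))
        perm = rng.permutation(n)
        f1 = fit_ols_robust(y, X)
        f2 = fit_ols_robust(y.iloc[perm], X.iloc[perm])
        np.testing.assert_allclose(f1.params, f2.params, rtol=1e-10)
        np.testing.assert_allclose(f1.bse, f2.bse, rtol=1e-10)

    def test_serialization_round_trip(self, small_analysis):
        fit = next(iter(small_analysis["fits"].values()))
        back = ConditionFit.from_dict(fit.to_dict())
        pd.testing.assert_series_equal(back.params, fit.params)
        pd.testing.assert_frame_equal(back.cov_params, fit.cov_params)
        assert back.n_obs == fit.n_obs and back.condition == fit.condition


class TestSummary:
    @pytest.mark.parametrize(
        "p, stars", [(0.005, "***"), (0.04, "**"), (0.09, "*"), (0.2, "")]
    )
    def test_star_thresholds(self, p, stars):
        assert significance_stars(p) == stars

    def _fake_fit(self, cond, coefs, ses):
        idx = pd.Index(["const", *QUINTILE_TERMS])
        params = pd.Series([0.0, *coefs], index=idx)
        bse = pd.Series([1.0, *ses], index=idx)
        import scipy.stats

        n, k = 100, 5
        t = params / bse
        p = pd.Series(2 * scipy.stats.t.sf(np.abs(t), n - k), index=idx)
        tc = scipy.stats.t.ppf(0.975, n - k)
        ci = pd.DataFrame({"lower": params - tc * bse, "upper": params + tc * bse})
        return ConditionFit(
            condition=cond, terms=list(idx), params=params, bse=bse, tvalues=t,
            pvalues=p, conf_int=ci,
            cov_params=pd.DataFrame(np.diag(bse**2), index=idx, columns=idx),
            r_squared=0.3, adj_r_squared=0.25, f_stat=5.0, f_pvalue=0.001, n_obs=n,
        )

    def test_fifteen_fits_give_sixty_coefficients(self):
        fits = [self._fake_fit(f"c{i}", [1, 2, 3, 4], [0.5] * 4) for i in range(15)]
        table, counts = summarize_quintile_effects(fits)
        assert len(table) == 60 and counts["n_coefficients"] == 60
        assert counts["n_positive"] == 60

    def test_all_zero_coefficients_no_stars_no_positives(self):
        table, counts = summarize_quintile_effects(
            [self._fake_fit("c", [0, 0, 0, 0], [1.0] * 4)]
        )
        assert counts["n_positive"] == 0 and counts["n_significant_05"] == 0
        assert (table["stars"] == "").all()
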