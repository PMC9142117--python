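"""Counterfactual prediction, rate-to-count conversion, and the report."""

import numpy as np
import pandas as pd
import pytest

from ltued import (
    InputDataError,
    counterfactual_design,
    finalize_report,
    quintile_descriptives,
    rates_to_visits,
    simulate_q1,
    summarize_simulation,
)
from ltued.regress import QUINTILE_TERMS, fit_ols_robust


def design_for(quintiles, covs=None):
    n = len(quintiles)
    X = pd.DataFrame({"const": np.ones(n)}, index=[f"Z{i:03d}" for i in range(n)])
    for j, term in enumerate(QUINTILE_TERMS, start=2):
        X[term] = (np.asarray(quintiles) == j).astype(float)
    if covs is not None:
        X["cov"] = covs
    return X


def fitted(X, beta, noise_seed=None, sd=0.5):
    rng = np.random.default_rng(0 if noise_seed is None else noise_seed)
    y = X.to_numpy() @ np.asarray(beta, dtype=float)
    if noise_seed is not None:
        y = y + sd * rng.normal(size=len(y))
    return fit_ols_robust(pd.Series(y, index=X.index), X, condition="c"), pd.Series(
        y, index=X.index
    )


class TestCounterfactual:
    def test_q1_areas_keep_factual_prediction_exactly(self):
        quintiles = [1, 2, 3, 4, 5] * 4
        X = design_for(quintiles)
        fit, _ = fitted(X, [5, 1, 2, 3, 4], noise_seed=3)
        pred_cf = simulate_q1(fit, X)
        factual = np.clip(X.to_numpy() @ fit.params.to_numpy(), 0, None)
        q1_rows = np.asarray(quintiles) == 1
        np.testing.assert_array_equal(pred_cf.to_numpy()[q1_rows], factual[q1_rows])

    def test_q3_area_drops_by_exactly_its_coefficient(self):
        quintiles = [1, 1, 2, 3, 4, 5, 3, 2, 1, 4, 5, 1]
        X = design_for(quintiles)
        fit, _ = fitted(X, [5.0, 1.0, 2.0, 3.0, 4.0])  # exact fit, no noise
        pred = simulate_q1(fit, X)
        factual = X.to_numpy() @ fit.params.to_numpy()
        drop = factual - pred.to_numpy()
        assert drop[quintiles.index(3)] == pytest.approx(2.0, abs=1e-10)
        assert drop[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_elementwise_brute_force(self, small_analysis):
        """Oracle: predictions equal a python-loop dot product of the modified
        design rows with the coefficients."""
        cond = small_analysis["panel"].conditions[0]
        fit = small_analysis["fits"][cond]
        X = small_analysis["designs"][cond]
        pred = simulate_q1(fit, X)
        beta = fit.params
        for zid, row in X.iterrows():
            acc = 0.0
            for term in X.columns:
                val = 0.0 if term in QUINTILE_TERMS else row[term]
                acc += beta[term] * val
            assert pred[zid] == pytest.approx(max(acc, 0.0), rel=1e-12, abs=1e-12)

    def test_q2q4_mode_spares_q5(self):
        X = design_for([1, 2, 3, 4, 5, 5])
        fit, _ = fitted(X, [5.0, 1.0, 2.0, 3.0, 4.0])
        pred = simulate_q1(fit, X, mode="q2q4")
        assert pred.iloc[4] == pytest.approx(9.0)  # Q5 effect retained
        assert pred.iloc[1] == pytest.approx(5.0)  # Q2 removed

    def test_term_mismatch_rejected(self):
        X = design_for([1, 2, 3, 4, 5, 1, 2, 3, 4, 5])
        fit, _ = fitted(X, [1, 1, 1, 1, 1])
        with pytest.raises(InputDataError):
            simulate_q1(fit, X.rename(columns={"ltu_q2": "other"}))


class TestRatesToVisits:
    def test_single_area(self):
        zctas = pd.DataFrame({"zcta_id": ["A"], "pop_year1": [1000], "pop_year2": [1000]})
        assert rates_to_visits(pd.Series({"A": 5.0}), zctas) == 10

    def test_all_zero(self, toy_zctas):
        rates = pd.Series(0.0, index=["A", "B", "C"])
        assert rates_to_visits(rates, toy_zctas) == 0

    def test_rounding_half_away_from_zero_once_on_total(self, toy_zctas):
        # A: 0.25 visits, B: 0.25 -> total 0.5 rounds to 1 (not 0+0)
        rates = pd.Series({"A": 0.125, "B": 0.25})
        assert rates_to_visits(rates, toy_zctas) == 1

    def test_status_quo_counts_equal_raw_totals(self, small_analysis):
        """Round trip with the rate stage: observed rates convert back to the
        exact filtered visit totals."""
        panel = small_analysis["panel"]
        zcta = small_analysis["zcta"]
        for cond in panel.conditions:
            assert rates_to_visits(panel.rates[cond], zcta) == int(
                panel.counts[cond].sum()
            )

    def test_missing_population_named(self, toy_zctas):
        with pytest.raises(InputDataError, match="Zmissing"):
            rates_to_visits(pd.Series({"Zmissing": 1.0}), toy_zctas)


class TestReport:
    def test_change_columns_and_flags_from_report(self, small_analysis):
        report = summarize_simulation(
            small_analysis["panel"], small_analysis["zcta"],
            small_analysis["fits"], small_analysis["designs"],
        )
        # change arithmetic is exact against the report's own columns
        np.testing.assert_array_equal(
            report["visit_change"].to_numpy(),
            (report["simulated_visits"] - report["status_quo_visits"]).to_numpy(),
        )
        np.testing.assert_array_equal(
            report["rate_change"].to_numpy(),
            (report["simulated_mean"] - report["status_quo_mean"]).round(1).to_numpy(),
        )
        disjoint = (report["simulated_ci_upper"] < report["status_quo_ci_lower"]) | (
            report["simulated_ci_lower"] > report["status_quo_ci_upper"]
        )
        np.testing.assert_array_equal(report["significant"].to_numpy(), disjoint.to_numpy())

    def test_identical_inputs_give_zero_changes_no_flags(self):
        rows = pd.DataFrame(
            {
                "condition": ["c1", "c2"],
                "status_quo_mean": [5.0, 3.0],
                "status_quo_ci_lower": [4.0, 2.5],
                "status_quo_ci_upper": [6.0, 3.5],
                "status_quo_visits": [100, 50],
                "simulated_mean": [5.0, 3.0],
                "simulated_ci_lower": [4.0, 2.5],
                "simulated_ci_upper": [6.0, 3.5],
                "simulated_visits": [100, 50],
            }
        )
        out = finalize_report(rows)
        assert (out["rate_change"] == 0).all()
        assert (out["visit_change"] == 0).all()
        assert not out["significant"].any()

    def test_disjoint_intervals_flagged(self):
        rows = pd.DataFrame(
            {
                "condition": ["c"],
                "status_quo_mean": [9.3],
                "status_quo_ci_lower": [8.7],
                "status_quo_ci_upper": [9.9],
                "status_quo_visits": [53034],
                "simulated_mean": [7.2],
                "simulated_ci_lower": [7.0],
                "simulated_ci_upper": [7.4],
                "simulated_visits": [37283],
            }
        )
        assert finalize_report(rows)["significant"].iloc[0]

    def test_nonnegative_effects_imply_simulated_below_factual_mean(self):
        rng = np.random.default_rng(11)
        X = design_for(rng.integers(1, 6, size=100))
        fit, _ = fitted(X, [4.0, 0.5, 1.0, 1.5, 2.0], noise_seed=12)
        assert (fit.params[list(QUINTILE_TERMS)] >= 0).all()
        factual = np.clip(X.to_numpy() @ fit.params.to_numpy(), 0, None)
        assert simulate_q1(fit, X).mean() <= factual.mean() + 1e-12

    def test_all_q1_world_reports_zero_changes(self):
        """A fit applied to a world where every area already sits in Q1 and
        observed rates equal the factual predictions yields all-zero change
        columns."""
        n = 20
        X_train = design_for([1, 2, 3, 4, 5] * 4)
        fit, _ = fitted(X_train, [5, 1, 2, 3, 4], noise_seed=14, sd=0.3)
        X1 = design_for([1] * n)
        factual = pd.Series(
            np.clip(X1.to_numpy() @ fit.params.to_numpy(), 0, None), index=X1.index
        )
        zctas = pd.DataFrame({"zcta_id": X1.index, "pop_year1": 1000, "pop_year2": 1000})
        from ltued.visits import RatePanel

        counts = (factual * 2000 / 1000).round().astype(int).to_frame("c")
        panel = RatePanel(["c"], counts, factual.to_frame("c"),
                          pd.Series(2000.0, index=X1.index))
        report = summarize_simulation(panel, zctas, {"c": fit}, {"c": X1})
        assert report["visit_change"].iloc[0] == 0
        assert report["rate_change"].iloc[0] == 0.0


def test_quintile_descriptives_shape(small_analysis):
    desc = quintile_descriptives(
        small_analysis["zcta"], small_analysis["assignments"], small_analysis["panel"]
    )
    assert {"mean_q1", "sd_q5", "n_q3"} <= set(desc.columns)
    n_conditions = len(small_analysis["panel"].conditions)
    assert desc["variable"].str.startswith("rate:").sum() == n_conditions
    covered = desc[desc["variable"] == "pct_white"].iloc[0]
    assert sum(covered[f"n_q{q}"] for q in range(1, 6)) == len(small_analysis["zcta"])
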