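"""Counterfactual standardization: every area set to the lowest LTU quintile.

The regression coefficients say how much higher a condition's uninsured ED
visit rate is in areas of higher long-term-uninsured concentration.  To turn
that into policy-relevant numbers, the fitted models are used to predict each
area's rate after replacing its quintile indicators with the reference level
Q1 while holding every covariate fixed (g-computation / regression
standardization), and predicted rates are converted back into visit counts
using each area's own two-year population.  The report pairs the observed
("status quo") mean rate and total visits with their simulated counterparts
and flags conditions whose 95% intervals do not overlap.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import InputDataError
from .regress import ConditionFit, QUINTILE_TERMS
from .visits import RatePanel, two_year_population

__all__ = [
    "REPLACE_MODES",
    "counterfactual_design",
    "simulate_q1",
    "rates_to_visits",
    "finalize_report",
    "summarize_simulation",
    "quintile_descriptives",
]

#: which quintile indicators are reset to the reference level.
#: "q2q5" sends every area to Q1; "q2q4" leaves Q5 areas untouched.
REPLACE_MODES = ("q2q5", "q2q4")


def _replaced_terms(mode: str) -> tuple[str, ...]:
    if mode not in REPLACE_MODES:
        raise InputDataError(f"unknown replacement mode {mode!r}")
    return QUINTILE_TERMS if mode == "q2q5" else QUINTILE_TERMS[:-1]


def counterfactual_design(X: pd.DataFrame, mode: str = "q2q5") -> pd.DataFrame:
    """Copy of the design with the replaced quintile indicators zeroed.

    Only the quintile columns change; covariates are held constant, which is
    exactly the "all else equal" clause of the standardization.
    """
    Xcf = X.copy()
    for term in _replaced_terms(mode):
        if term in Xcf.columns:
            Xcf[term] = 0.0
    return Xcf


def simulate_q1(
    fit: ConditionFit, X: pd.DataFrame, mode: str = "q2q5"
) -> pd.Series:
    """Per-ZCTA counterfactual predicted rate under the Q1 scenario.

    The prediction is the modified design row times the fitted coefficient
    vector, floored at zero (rates are nonnegative).  Areas already in Q1
    keep their factual prediction exactly.
    """
    if list(X.columns) != list(fit.terms):
        raise InputDataError(
            f"design terms {list(X.columns)} do not match fit terms {fit.terms}"
        )
    pred = counterfactual_design(X, mode).to_numpy() @ fit.params.to_numpy()
    return pd.Series(np.clip(pred, 0.0, None), index=X.index, name=fit.condition)


def rates_to_visits(rates: pd.Series, zctas: pd.DataFrame) -> int:
    """Convert per-1000 rates back into a total visit count.

    ``round(sum_z rate_z * two_year_pop_z / 1000)``, rounding half away from
    zero once on the grand total, so observed rates round-trip to the raw
    filtered visit totals exactly.
    """
    pop = two_year_population(zctas)
    missing = rates.index.difference(pop.index)
    if len(missing):
        raise InputDataError(f"no population for zcta_id={missing[0]!r}")
    total = float((rates * pop.loc[rates.index]).sum() / 1000.0)
    return int(math.copysign(math.floor(abs(total) + 0.5), total))


def finalize_report(rows: pd.DataFrame) -> pd.DataFrame:
    """Derive the change columns and significance flags of the report.

    ``rows`` must carry, per condition: ``status_quo_mean``,
    ``status_quo_ci_lower/upper``, ``status_quo_visits``, ``simulated_mean``,
    ``simulated_ci_lower/upper``, ``simulated_visits``.  Adds
    ``rate_change`` (simulated minus status quo, reported to one decimal),
    ``visit_change`` (simulated minus status-quo counts), and
    ``significant`` (True iff the two 95% intervals are disjoint).

    Kept separate from :func:`summarize_simulation` so the change arithmetic
    can be exercised on externally supplied columns.
    """
    out = rows.copy()
    out["rate_change"] = (out["simulated_mean"] - out["status_quo_mean"]).round(1)
    out["visit_change"] = (
        out["simulated_visits"].astype(int) - out["status_quo_visits"].astype(int)
    )
    out["significant"] = (out["simulated_ci_upper"] < out["status_quo_ci_lower"]) | (
        out["simulated_ci_lower"] > out["status_quo_ci_upper"]
    )
    return out


def summarize_simulation(
    panel: RatePanel,
    zctas: pd.DataFrame,
    fits: Mapping[str, ConditionFit],
    designs: Mapping[str, pd.DataFrame],
    mode: str = "q2q5",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Status-quo vs counterfactual rates and visit counts, per condition.

    Status-quo mean rates are unweighted across ZCTAs with a t interval
    (mean +/- t * SD / sqrt(n)); the simulated mean's interval is a delta-
    method interval from the fit's robust covariance, with a the column-mean
    vector of the counterfactual design: SE = sqrt(a' V a).  Visit counts on
    both sides weight each area by its own two-year population.
    """
    if set(fits) != set(designs):
        raise InputDataError("fits and designs must cover the same conditions")
    missing = [c for c in fits if c not in panel.conditions]
    if missing:
        raise InputDataError(f"panel has no condition {missing[0]!r}")

    rows = []
    for cond in panel.conditions:
        if cond not in fits:
            continue
        fit, X = fits[cond], designs[cond]
        obs = panel.rates[cond]
        n = len(obs)
        sq_mean = float(obs.mean())
        sq_se = float(obs.std(ddof=1) / np.sqrt(n))
        t_sq = scipy.stats.t.ppf(1 - alpha / 2, n - 1)

        pred = simulate_q1(fit, X, mode)
        a = counterfactual_design(X, mode).mean(axis=0).to_numpy()
        var = float(a @ fit.cov_params.to_numpy() @ a)
        sim_se = math.sqrt(max(var, 0.0))
        t_sim = scipy.stats.t.ppf(1 - alpha / 2, fit.df_resid)
        sim_mean = float(pred.mean())

        rows.append(
            {
                "condition": cond,
                "status_quo_mean": sq_mean,
                "status_quo_ci_lower": sq_mean - t_sq * sq_se,
                "status_quo_ci_upper": sq_mean + t_sq * sq_se,
                "status_quo_visits": rates_to_visits(obs, zctas),
                "simulated_mean": sim_mean,
                "simulated_ci_lower": sim_mean - t_sim * sim_se,
                "simulated_ci_upper": sim_mean + t_sim * sim_se,
                "simulated_visits": rates_to_visits(pred, zctas),
            }
        )
    return finalize_report(pd.DataFrame(rows))


def quintile_descriptives(
    zctas: pd.DataFrame,
    assignments: pd.DataFrame,
    panel: RatePanel | None = None,
) -> pd.DataFrame:
    """Per-quintile mean (SD) of every covariate and, optionally, rates.

    Mirrors the descriptive table of the analysis: one row per variable,
    columns q1..q5 holding "mean (sd)" pairs as separate mean_/sd_ columns.
    """
    merged = zctas.merge(assignments[["zcta_id", "quintile"]], on="zcta_id")
    numeric = [
        c for c in zctas.columns if c != "zcta_id" and pd.api.types.is_numeric_dtype(zctas[c])
    ]
    blocks = {c: merged.groupby("quintile")[c] for c in numeric}
    if panel is not None:
        q = assignments.set_index("zcta_id")["quintile"]
        for cond in panel.conditions:
            blocks[f"rate:{cond}"] = panel.rates[cond].groupby(q.loc[panel.zcta_ids])
    rows = []
    for name, grouped in blocks.items():
        mean, sd, size = grouped.mean(), grouped.std(ddof=1), grouped.size()
        row = {"variable": name}
        for qi in range(1, 6):
            row[f"mean_q{qi}"] = float(mean.get(qi, np.nan))
            row[f"sd_q{qi}"] = float(sd.get(qi, np.nan))
            row[f"n_q{qi}"] = int(size.get(qi, 0))
        rows.append(row)
    return pd.DataFrame(rows)
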