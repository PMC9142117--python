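"""Per-condition ecological regression with robust variance.

Each condition's two-year ED visit rate (per 1000 population, one row per
ZCTA) is regressed by ordinary least squares on the four LTU quintile
indicators Q2-Q5 (Q1 is the reference) plus area-level covariates.  Because
rate variances shrink with area population, the error is heteroskedastic by
construction; standard errors therefore come from a heteroskedasticity-
consistent sandwich, HC1 by default:

    V = (n / (n - k)) (X'X)^-1 X' diag(e^2) X (X'X)^-1

with t-based p values and confidence intervals on n - k degrees of freedom.
The tooth-disease condition additionally adjusts for dental-care supply and
use (dentist ratio, share with no dental visit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .exceptions import EstimationError, InputDataError
from .synth import TEETH_CONDITION
from .visits import RatePanel

__all__ = [
    "BASE_COVARIATES",
    "DENTAL_COVARIATES",
    "QUINTILE_TERMS",
    "DesignSpec",
    "ConditionFit",
    "build_design",
    "fit_ols_robust",
    "summarize_quintile_effects",
]

#: covariates entering every condition's model
BASE_COVARIATES = (
    "pct_white",
    "pct_black",
    "pct_less_hs",
    "pct_below_200fpl",
    "pct_unemployed_16plus",
    "pct_delayed_care_cost",
    "pct_no_usual_source",
    "pct_obese",
)

#: extra covariates for the tooth-disease condition only
DENTAL_COVARIATES = ("dentist_ratio_per_1000", "pct_no_dental_visit")

#: quintile indicator columns (Q1 is the omitted reference)
QUINTILE_TERMS = ("ltu_q2", "ltu_q3", "ltu_q4", "ltu_q5")


@dataclass(frozen=True)
class DesignSpec:
    """Which columns enter one condition's regression.

    ``covariate_scale`` is "percent" (0-100, the storage scale) or
    "fraction" (divide percentage columns by 100 before fitting); the dental
    flag appends the two dental covariates.
    """

    condition: str
    covariates: tuple[str, ...] = BASE_COVARIATES
    dental: bool = False
    covariate_scale: str = "percent"

    @classmethod
    def for_condition(
        cls, condition: str, covariate_scale: str = "percent",
        teeth_condition: str = TEETH_CONDITION,
    ) -> "DesignSpec":
        return cls(
            condition=condition,
            dental=(condition == teeth_condition),
            covariate_scale=covariate_scale,
        )

    def all_covariates(self) -> tuple[str, ...]:
        return self.covariates + (DENTAL_COVARIATES if self.dental else ())


@dataclass
class ConditionFit:
    """One condition's OLS fit with robust (sandwich) inference.

    Coefficients are in rate units (visits per 1000 population over two
    years); ``cov_params`` is the robust covariance used for delta-method
    prediction intervals downstream.  ``f_pvalue`` is the classical overall
    F test computed from sums of squares.
    """

    condition: str
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame  # columns "lower", "upper"
    cov_params: pd.DataFrame
    r_squared: float
    adj_r_squared: float
    f_stat: float
    f_pvalue: float
    n_obs: int
    cov_type: str = "HC1"
    extra: dict = field(default_factory=dict)

    @property
    def df_resid(self) -> int:
        return self.n_obs - len(self.terms)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "terms": self.terms,
            "params": self.params.tolist(),
            "bse": self.bse.tolist(),
            "tvalues": self.tvalues.tolist(),
            "pvalues": self.pvalues.tolist(),
            "conf_int": self.conf_int.to_numpy().tolist(),
            "cov_params": self.cov_params.to_numpy().tolist(),
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "f_stat": self.f_stat,
            "f_pvalue": self.f_pvalue,
            "n_obs": self.n_obs,
            "cov_type": self.cov_type,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionFit":
        terms = list(d["terms"])
        idx = pd.Index(terms)
        return cls(
            condition=d["condition"],
            terms=terms,
            params=pd.Series(d["params"], index=idx),
            bse=pd.Series(d["bse"], index=idx),
            tvalues=pd.Series(d["tvalues"], index=idx),
            pvalues=pd.Series(d["pvalues"], index=idx),
            conf_int=pd.DataFrame(d["conf_int"], index=idx, columns=["lower", "upper"]),
            cov_params=pd.DataFrame(d["cov_params"], index=idx, columns=idx),
            r_squared=d["r_squared"],
            adj_r_squared=d["adj_r_squared"],
            f_stat=d["f_stat"],
            f_pvalue=d["f_pvalue"],
            n_obs=d["n_obs"],
            cov_type=d["cov_type"],
        )

    def report_frame(self) -> pd.DataFrame:
        """Tidy per-term report (estimate, robust SE, t, p, CI bounds)."""
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.params.to_numpy(),
                "robust_se": self.bse.to_numpy(),
                "t": self.tvalues.to_numpy(),
                "p": self.pvalues.to_numpy(),
                "ci_lower": self.conf_int["lower"].to_numpy(),
                "ci_upper": self.conf_int["upper"].to_numpy(),
            }
        )


def build_design(
    panel: RatePanel,
    zctas: pd.DataFrame,
    assignments: pd.DataFrame,
    spec: DesignSpec,
) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Assemble (response, design matrix, term names) for one condition.

    One row per ZCTA, sorted by zcta_id; columns are the intercept, the four
    quintile indicators, then the spec's covariates.  A ZCTA present in the
    panel but missing an assignment or a covariate raises
    :class:`InputDataError` naming it.
    """
    if spec.condition not in panel.conditions:
        raise InputDataError(f"panel has no condition {spec.condition!r}")
    ids = panel.zcta_ids.sort_values()

    assign = assignments.set_index("zcta_id")["quintile"]
    missing = ids.difference(assign.index)
    if len(missing):
        raise InputDataError(f"no quintile assignment for zcta_id={missing[0]!r}")

    covs = list(spec.all_covariates())
    ztab = zctas.set_index("zcta_id")
    for name in covs:
        if name not in ztab.columns:
            raise InputDataError(f"ZCTA table is missing covariate {name!r}")
    missing = ids.difference(ztab.index)
    if len(missing):
        raise InputDataError(f"no covariate row for zcta_id={missing[0]!r}")
    block = ztab.loc[ids, covs].astype(float)
    bad = block.isna().any(axis=1)
    if bad.any():
        zid = block.index[bad][0]
        names = [c for c in covs if pd.isna(block.loc[zid, c])]
        raise InputDataError(f"zcta_id={zid!r} has missing covariate value(s): {names}")
    if spec.covariate_scale == "fraction":
        pct = [c for c in covs if c.startswith("pct_")]
        block[pct] = block[pct] / 100.0

    q = assign.loc[ids].to_numpy()
    X = pd.DataFrame({"const": np.ones(len(ids))}, index=ids)
    for j, term in enumerate(QUINTILE_TERMS, start=2):
        X[term] = (q == j).astype(float)
    for name in covs:
        X[name] = block[name].to_numpy()

    y = panel.rates.loc[ids, spec.condition].rename(spec.condition)
    return y, X, list(X.columns)


def _collinear_terms(X: np.ndarray, terms: list[str]) -> list[str]:
    """Columns whose QR pivot magnitude collapses (candidates for collinearity)."""
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [t for t, d in zip(terms, diag) if d <= tol]


def fit_ols_robust(
    y: pd.Series,
    X: pd.DataFrame,
    terms: list[str] | None = None,
    cov_type: str = "HC1",
    condition: str | None = None,
) -> ConditionFit:
    """OLS with heteroskedasticity-consistent standard errors.

    Inference uses the requested sandwich flavor (HC0, HC1 or HC3) with the
    t distribution on n - k degrees of freedom; R-squared, its adjusted
    version, and the overall F statistic come from the classical sums of
    squares.  Rank-deficient designs raise :class:`EstimationError` listing
    the offending columns.
    """
    if cov_type not in ("HC0", "HC1", "HC3"):
        raise InputDataError(f"unsupported robust covariance flavor {cov_type!r}")
    terms = list(terms) if terms is not None else list(X.columns)
    n, k = X.shape
    if n <= k:
        raise InputDataError(f"need more observations than terms: n={n}, k={k}")
    Xa = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(Xa) < k:
        raise EstimationError(
            f"design matrix is rank deficient; collinear term candidates: "
            f"{_collinear_terms(Xa, terms)}"
        )

    res = sm.OLS(np.asarray(y, dtype=float), Xa).fit(cov_type=cov_type, use_t=True)

    idx = pd.Index(terms)
    params = pd.Series(res.params, index=idx)
    bse = pd.Series(res.bse, index=idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = params / bse
    tvals = tvals.where(bse > 0, np.where(params.abs() > 0, np.inf * np.sign(params), 0.0))
    df = n - k
    pvals = pd.Series(2.0 * scipy.stats.t.sf(np.abs(tvals), df), index=idx)
    tcrit = scipy.stats.t.ppf(0.975, df)
    ci = pd.DataFrame(
        {"lower": params - tcrit * bse, "upper": params + tcrit * bse}, index=idx
    )

    yv = np.asarray(y, dtype=float)
    ss_res = float(np.sum(res.resid**2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / df
    p_model = k - 1  # slopes, excluding the intercept
    if p_model > 0 and r2 < 1.0:
        f_stat = (r2 / p_model) / ((1.0 - r2) / df)
        f_p = float(scipy.stats.f.sf(f_stat, p_model, df))
    else:
        f_stat, f_p = np.inf, 0.0

    return ConditionFit(
        condition=condition or getattr(y, "name", None) or "",
        terms=terms,
        params=params,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        conf_int=ci,
        cov_params=pd.DataFrame(res.cov_params(), index=idx, columns=idx),
        r_squared=r2,
        adj_r_squared=adj,
        f_stat=float(f_stat),
        f_pvalue=f_p,
        n_obs=n,
        cov_type=cov_type,
    )


def significance_stars(p: float) -> str:
    """Conventional star flags: * p<0.10, ** p<0.05, *** p<0.01."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def summarize_quintile_effects(
    fits: list[ConditionFit],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Long summary of the Q2-Q5 coefficients across conditions.

    Returns the per-(condition, quintile-term) table with 95% CIs and star
    flags, plus headline tallies: how many of the quintile coefficients are
    positive and how many are significant at the 0.05 level.
    """
    if not fits:
        raise InputDataError("need at least one fitted condition")
    rows = []
    for fit in fits:
        for term in QUINTILE_TERMS:
            if term not in fit.params.index:
                continue
            p = float(fit.pvalues[term])
            rows.append(
                {
                    "condition": fit.condition,
                    "term": term,
                    "estimate": float(fit.params[term]),
                    "ci_lower": float(fit.conf_int.loc[term, "lower"]),
                    "ci_upper": float(fit.conf_int.loc[term, "upper"]),
                    "p": p,
                    "stars": significance_stars(p),
                }
            )
    table = pd.DataFrame(rows)
    counts = {
        "n_coefficients": len(table),
        "n_positive": int((table["estimate"] > 0).sum()),
        "n_significant_05": int((table["p"] < 0.05).sum()),
    }
    return table, counts
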