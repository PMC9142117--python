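"""Area-level long-term-uninsured (LTU) propensity score and quintiles.

No survey measures the long-term-uninsured share of small areas directly, so
a propensity-style index is constructed: an area-level logistic-type model of
the characteristics known to predict long-term uninsurance (uninsured rate,
minority share, low education, unemployment, non-family households, poverty)
yields a score in (0, 1) per ZCTA, and areas are ranked into quintiles Q1
(lowest concentration) through Q5 (highest).

Two readings of the area-level "logistic regression" are offered:

``fractional``  (default)
    Fractional-response logistic regression — the uninsured share (on the
    0-1 scale) is the outcome, the remaining five predictors plus an
    intercept form the linear predictor, fit by binomial quasi-likelihood.
``median-binary``
    A conventional logistic fit of the indicator "uninsured share above the
    sample median" on the same predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import DegenerateDataError, EstimationError, InputDataError

__all__ = [
    "PROPENSITY_PREDICTORS",
    "PROPENSITY_OUTCOME",
    "PropensityModel",
    "fit_propensity",
    "score_propensity",
    "assign_quintiles",
]

#: the five area characteristics entering the linear predictor
PROPENSITY_PREDICTORS = (
    "pct_hispanic",
    "pct_less_hs",
    "pct_unemployed_16plus",
    "pct_nonfamily_households",
    "pct_below_200fpl",
)

#: the outcome variable (uninsured share of adults 18-64)
PROPENSITY_OUTCOME = "pct_uninsured_18_64"

_MAXITER = 100
_TOL = 1e-8


@dataclass
class PropensityModel:
    """A fitted LTU propensity model (logit link).

    ``params`` includes the intercept under the name ``const``; ``spec``
    records which outcome reading was fit.
    """

    params: pd.Series
    cov_params: pd.DataFrame
    spec: str
    predictors: tuple[str, ...]
    n_obs: int
    converged: bool
    link: str = "logit"

    def linear_predictor(self, zctas: pd.DataFrame) -> pd.Series:
        X = _design(zctas, self.predictors)
        return X @ self.params


def _design(zctas: pd.DataFrame, predictors) -> pd.DataFrame:
    for name in predictors:
        if name not in zctas.columns:
            raise InputDataError(f"ZCTA table is missing predictor column {name!r}")
    bad = zctas[list(predictors)].isna().any(axis=1)
    if bad.any():
        row = zctas.loc[bad].iloc[0]
        missing = [p for p in predictors if pd.isna(row[p])]
        raise InputDataError(
            f"zcta_id={row['zcta_id']!r} has missing predictor value(s): {missing}"
        )
    X = zctas[list(predictors)].astype(float)
    X.insert(0, "const", 1.0)
    X.index = zctas["zcta_id"]
    return X


def fit_propensity(
    zctas: pd.DataFrame,
    spec: str = "fractional",
    predictors: tuple[str, ...] = PROPENSITY_PREDICTORS,
    outcome: str = PROPENSITY_OUTCOME,
) -> PropensityModel:
    """Fit the area-level LTU propensity model by IRLS.

    Raises :class:`DegenerateDataError` for constant or collinear predictors
    and :class:`EstimationError` on separation or non-convergence within the
    iteration budget (100 IRLS steps at relative tolerance 1e-8).
    """
    if spec not in ("fractional", "median-binary"):
        raise InputDataError(f"unknown propensity spec {spec!r}")
    n, p = len(zctas), len(predictors)
    if n < p + 2:
        raise InputDataError(f"need at least {p + 2} ZCTAs to fit {p} predictors, got {n}")

    zctas = zctas.sort_values("zcta_id", ignore_index=True)
    for name in (outcome, *predictors):
        if name not in zctas.columns:
            raise InputDataError(f"ZCTA table is missing column {name!r}")
        if np.ptp(zctas[name].to_numpy(dtype=float)) == 0.0 and name != outcome:
            raise DegenerateDataError(f"predictor {name!r} is constant across ZCTAs")

    X = _design(zctas, predictors)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DegenerateDataError(
            f"predictors are collinear: design rank < {X.shape[1]} for {list(predictors)}"
        )

    share = zctas[outcome].to_numpy(dtype=float) / 100.0
    if spec == "fractional":
        y = np.clip(share, 0.0, 1.0)
    else:
        y = (share > np.median(share)).astype(float)

    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # binomial non-integer warning
            res = model.fit(maxiter=_MAXITER, tol=_TOL)
    except PerfectSeparationError as err:
        raise EstimationError(f"perfect separation in propensity fit: {err}") from err
    if not res.converged:
        raise EstimationError(
            f"propensity IRLS did not converge in {_MAXITER} iterations "
            f"(deviance trace tail: {res.fit_history['deviance'][-3:]})"
        )
    return PropensityModel(
        params=res.params,
        cov_params=res.cov_params(),
        spec=spec,
        predictors=tuple(predictors),
        n_obs=n,
        converged=bool(res.converged),
    )


def score_propensity(model: PropensityModel, zctas: pd.DataFrame) -> pd.DataFrame:
    """Predicted LTU propensity per ZCTA: inverse-logit of the linear predictor.

    Returns a frame (zcta_id, score) in the input's row order; scores lie in
    (0, 1) and are strictly increasing in the linear predictor.
    """
    eta = model.linear_predictor(zctas)
    return pd.DataFrame(
        {"zcta_id": zctas["zcta_id"].to_numpy(), "score": expit(eta.to_numpy())}
    )


def assign_quintiles(scores: pd.DataFrame) -> pd.DataFrame:
    """Rank ZCTAs by score into five near-equal quintiles, Q5 = highest.

    Sorting is by (score, zcta_id) ascending, so ties are broken
    deterministically and input order never matters.  When the number of
    areas is not a multiple of five, the extra members go to the lowest
    quintiles first (392 areas -> sizes 79, 79, 78, 78, 78).  A warning is
    emitted if tied scores straddle a quintile boundary, since the split is
    then an artifact of the id tie-break.
    """
    n = len(scores)
    if n < 5:
        raise InputDataError(f"need at least 5 scored ZCTAs, got {n}")
    ordered = scores.sort_values(["score", "zcta_id"], ignore_index=True)
    sizes = _quintile_sizes(n)
    quint = np.repeat(np.arange(1, 6), sizes)

    bounds = np.cumsum(sizes)[:-1]
    svals = ordered["score"].to_numpy()
    if any(svals[b - 1] == svals[b] for b in bounds):
        warnings.warn(
            "tied scores straddle a quintile boundary; assignment there is "
            "determined by the zcta_id tie-break",
            stacklevel=2,
        )
    out = ordered.assign(quintile=quint)
    return out.sort_values("zcta_id", ignore_index=True)


def _quintile_sizes(n: int) -> list[int]:
    base, rem = divmod(n, 5)
    return [base + 1 if i < rem else base for i in range(5)]
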