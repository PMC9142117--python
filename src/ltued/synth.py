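"""Synthetic ZCTA covariate tables and ED encounter records.

The real analysis inputs — a statewide all-payer ED encounter census joined
to small-area survey covariates — are restricted, so this module generates
both tables with known ground truth.  Generation is latent-quintile-first:
each ZCTA is assigned a latent long-term-uninsured (LTU) quintile, covariates
are drawn conditional on that quintile from a per-quintile mean/SD
calibration, and qualifying visit counts are drawn from a Poisson law whose
mean follows a linear model in the quintile indicators.  That construction
makes the published descriptive gradient (covariates and visit rates rising
from Q1 to Q5) hold by design and gives every downstream stage an exact
recovery target.

A configurable share of additional "noise" encounters is appended, each
violating exactly one inclusion criterion (insured payer, age outside 18-64,
or an invalid area label), so the filtering stage has known-true exclusion
counts to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .visits import AGE_RANGE, PAYER_CATEGORIES, UNINSURED_PAYERS, INVALID_ZCTA

__all__ = [
    "ConditionEffect",
    "GeneratorConfig",
    "GroundTruth",
    "DEFAULT_CALIBRATION",
    "DEFAULT_EFFECTS",
    "TEETH_CONDITION",
    "ZCTA_COVARIATES",
    "generate_zcta_table",
    "generate_visits",
    "draw_rate_panel",
    "latent_quintile_sizes",
]

#: covariate columns of a ZCTA record, in generation order
ZCTA_COVARIATES = (
    "pct_white",
    "pct_black",
    "pct_uninsured_18_64",
    "pct_hispanic",
    "pct_less_hs",
    "pct_unemployed_16plus",
    "pct_nonfamily_households",
    "pct_below_200fpl",
    "pct_obese",
    "pct_delayed_care_cost",
    "pct_no_usual_source",
    "pct_no_dental_visit",
    "dentist_ratio_per_1000",
)

# Per-quintile (mean, SD) calibration for each covariate, quintile 1..5.
# Percentages are on the 0-100 scale; the dentist ratio is per 1000 persons.
# The area-deprivation gradient is monotone for every covariate except
# %white (decreasing) and the dentist ratio (richer areas have more
# dentists).  The uninsured / Hispanic / non-family rows have no published
# stratified values and use plausible South-Carolina-like gradients.
DEFAULT_CALIBRATION: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "pct_white": ((81, 72, 66, 58, 49), (16, 20, 20, 22, 24)),
    "pct_black": ((18, 26, 32, 40, 48), (16, 20, 20, 22, 25)),
    "pct_uninsured_18_64": ((14, 18, 21, 24, 28), (4, 4, 4, 4, 5)),
    "pct_hispanic": ((3, 4, 5, 6, 7), (2, 3, 3, 3, 4)),
    "pct_less_hs": ((13, 17, 19, 23, 26), (9, 7, 6, 8, 6)),
    "pct_unemployed_16plus": ((7.7, 10.7, 13.1, 13.8, 18.5), (3.7, 4.3, 4.6, 4.5, 7.6)),
    "pct_nonfamily_households": ((28, 30, 32, 34, 37), (6, 6, 6, 6, 7)),
    "pct_below_200fpl": ((12, 16, 18, 22, 29), (8, 6, 6, 7, 7)),
    "pct_obese": ((29, 30, 32, 33, 34), (5, 5, 5, 6, 7)),
    "pct_delayed_care_cost": ((17, 18, 19, 19, 20), (3, 2, 3, 4, 4)),
    "pct_no_usual_source": ((18, 19, 18, 18, 18), (3, 4, 4, 4, 5)),
    "pct_no_dental_visit": ((34, 36, 39, 39, 41), (7, 5, 6, 7, 7)),
    "dentist_ratio_per_1000": ((0.43, 0.43, 0.35, 0.35, 0.35), (0.22, 0.21, 0.18, 0.21, 0.19)),
}

TEETH_CONDITION = "diseases_of_the_teeth"


@dataclass(frozen=True)
class ConditionEffect:
    """True data-generating parameters for one condition's visit rate.

    The expected two-year rate per 1000 population of a ZCTA in latent
    quintile q is ``intercept + quintile_effects[q-2]`` (zero for q=1) plus
    any covariate terms, with Gaussian area-level noise of ``residual_sd``
    added before the Poisson count draw.  Units are visits per 1000 persons
    over the two study years.
    """

    intercept: float
    quintile_effects: tuple[float, float, float, float]  # Q2..Q5 vs Q1
    covariate_slopes: dict[str, float] = field(default_factory=dict)
    residual_sd: float = 2.0

    def linear_predictor(self, quintile: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(quintile), self.intercept, dtype=float)
        qeff = np.array([0.0, *self.quintile_effects])
        eta += qeff[quintile - 1]
        for name, slope in self.covariate_slopes.items():
            eta += slope * covariates[name].to_numpy()
        return eta


# Intercepts are the quintile-1 mean rates; the Q2-Q5 offsets are regression
# effect sizes on the same rate-per-1000 scale.  Together they reproduce the
# rising rate gradient across quintiles.
DEFAULT_EFFECTS: dict[str, ConditionEffect] = {
    "abdominal_pain": ConditionEffect(6.1, (1.96, 3.40, 2.40, 2.74)),
    "chest_pain": ConditionEffect(6.3, (0.8, 1.4, 1.9, 1.5)),
    "cellulitis_and_abscess": ConditionEffect(4.8, (1.1, 3.7, 2.4, 1.7)),
    TEETH_CONDITION: ConditionEffect(4.5, (0.99, 2.8, 2.7, 1.3)),
    "contusions_intact_skin": ConditionEffect(7.4, (-0.03, 1.2, 0.4, -1.2)),
    "other_symptoms_ill_defined": ConditionEffect(4.2, (0.5, 1.1, 0.7, 1.4)),
    "other_dorsopathies": ConditionEffect(3.9, (1.63, 1.7, 1.9, 2.2)),
    "headache": ConditionEffect(2.5, (1.7, 1.0, 1.4, 0.6)),
    "other_sprains_strains_back": ConditionEffect(2.7, (0.9, 1.3, 0.7, 0.2)),
    "urinary_tract_infection": ConditionEffect(3.3, (-0.08, 0.5, 1.1, 0.5)),
    "other_injuries": ConditionEffect(3.1, (0.8, 1.3, 0.5, 1.0)),
    "joint_derangements": ConditionEffect(2.8, (-0.04, 0.6, -0.01, 0.02)),
    "acute_bronchitis": ConditionEffect(2.5, (0.2, 1.3, 0.5, 0.4)),
    "sprains_strains_neck": ConditionEffect(2.4, (-0.3, 0.4, 0.0, -0.1)),
    "other_rheumatism": ConditionEffect(1.8, (0.4, 1.0, 0.8, 0.8)),
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-data generator.

    Defaults emulate the study conditions: 392 areas, annual 18-64
    populations averaging a few thousand persons, the published per-quintile
    covariate calibration and rate effect sizes, and a raw encounter stream
    in which roughly three quarters of records fail the inclusion filters
    (the published flow kept 1,062,418 of 4,076,200 visits, a 73.9% exclusion
    share).

    ``count_mode`` selects Poisson sampling of qualifying counts (default)
    or deterministic rounding of the expected count ("expected"), the latter
    mainly for exact-identity testing.
    """

    n_zcta: int = 392
    seed: int = 0
    covariate_calibration: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = field(
        default_factory=lambda: dict(DEFAULT_CALIBRATION)
    )
    effect_spec: dict[str, ConditionEffect] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    conditions: tuple[str, ...] | None = None  # None -> all of effect_spec
    population_range: tuple[int, int] = (500, 14000)  # annual 18-64 persons
    noise_fraction: float = 0.739
    count_mode: str = "poisson"  # or "expected"
    study_years: tuple[int, int] = (2012, 2013)

    def validate(self) -> None:
        if self.n_zcta < 5:
            raise ConfigurationError(f"n_zcta must be >= 5, got {self.n_zcta}")
        if not (0.0 <= self.noise_fraction < 1.0):
            raise ConfigurationError(
                f"noise_fraction must be in [0, 1), got {self.noise_fraction}"
            )
        lo, hi = self.population_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"population_range must satisfy 1 <= min <= max, got {self.population_range}"
            )
        if self.count_mode not in ("poisson", "expected"):
            raise ConfigurationError(f"unknown count_mode {self.count_mode!r}")
        for name, (means, sds) in self.covariate_calibration.items():
            if len(means) != 5 or len(sds) != 5:
                raise ConfigurationError(
                    f"covariate_calibration[{name!r}] needs 5 means and 5 SDs"
                )
            if any(s < 0 for s in sds):
                raise ConfigurationError(f"covariate_calibration[{name!r}] has a negative SD")
        for name, eff in self.effect_spec.items():
            if eff.residual_sd < 0:
                raise ConfigurationError(f"effect_spec[{name!r}].residual_sd is negative")
        for cond in self.condition_list():
            if cond not in self.effect_spec:
                raise ConfigurationError(f"condition {cond!r} missing from effect_spec")

    def condition_list(self) -> list[str]:
        return list(self.conditions) if self.conditions is not None else list(self.effect_spec)

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Copy with fields replaced (convenience for tests and sweeps)."""
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery testing.

    ``latent_quintile`` is indexed by zcta_id; ``expected_rates`` holds the
    noiseless-but-for-Gaussian-residual linear predictor (the Poisson mean on
    the rate scale); ``qualifying_counts`` the integer counts actually drawn.
    """

    latent_quintile: pd.Series
    effects: dict[str, ConditionEffect]
    qualifying_counts: pd.DataFrame | None = None
    expected_rates: pd.DataFrame | None = None
    n_qualifying: int = 0
    n_noise: int = 0


def latent_quintile_sizes(n: int) -> list[int]:
    """Near-equal five-way split; any remainder goes to the lowest quintiles."""
    base, rem = divmod(n, 5)
    return [base + 1 if i < rem else base for i in range(5)]


def _streams(seed: int):
    """Three independent child generators: covariates, counts, noise records.

    Separate streams mean adding or removing noise records can never perturb
    the covariate or count draws for the same seed.
    """
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def generate_zcta_table(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the ZCTA covariate table conditional on latent LTU quintiles.

    Returns the table (one row per ZCTA, id order) and a :class:`GroundTruth`
    carrying the latent quintile of every area.  Percentage covariates are
    clamped to [0, 100]; the dentist ratio to [0, inf).
    """
    config.validate()
    cov_rng, _, _ = _streams(config.seed)
    n = config.n_zcta
    width = max(4, len(str(n)))
    ids = [f"Z{i:0{width}d}" for i in range(1, n + 1)]
    quintile = np.repeat(np.arange(1, 6), latent_quintile_sizes(n))

    lo, hi = config.population_range
    table = pd.DataFrame({"zcta_id": ids})
    table["pop_year1"] = cov_rng.integers(lo, hi + 1, size=n)
    table["pop_year2"] = cov_rng.integers(lo, hi + 1, size=n)

    for name in ZCTA_COVARIATES:
        means, sds = config.covariate_calibration[name]
        mu = np.asarray(means, dtype=float)[quintile - 1]
        sd = np.asarray(sds, dtype=float)[quintile - 1]
        vals = mu + sd * cov_rng.standard_normal(n)
        if name.startswith("pct_"):
            vals = np.clip(vals, 0.0, 100.0)
        else:
            vals = np.clip(vals, 0.0, None)
        table[name] = vals

    truth = GroundTruth(
        latent_quintile=pd.Series(quintile, index=pd.Index(ids, name="zcta_id")),
        effects=dict(config.effect_spec),
    )
    return table, truth


def _draw_condition_counts(
    zcta_table: pd.DataFrame, config: GeneratorConfig, count_rng: np.random.Generator,
    quintile: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Qualifying visit counts and expected rates per ZCTA x condition.

    The expected rate is ``max(0, eta)`` with eta the linear predictor plus
    Gaussian residual; the count is Poisson with mean
    ``rate * two_year_pop / 1000`` (or its rounded expectation in
    "expected" mode).
    """
    ids = pd.Index(zcta_table["zcta_id"], name="zcta_id")
    pop2 = (zcta_table["pop_year1"] + zcta_table["pop_year2"]).to_numpy(dtype=float)
    counts = {}
    rates = {}
    for cond in config.condition_list():
        eff = config.effect_spec[cond]
        eta = eff.linear_predictor(quintile, zcta_table)
        if eff.residual_sd > 0:
            eta = eta + eff.residual_sd * count_rng.standard_normal(len(ids))
        eta = np.clip(eta, 0.0, None)
        mean = eta * pop2 / 1000.0
        if config.count_mode == "poisson":
            counts[cond] = count_rng.poisson(mean)
        else:
            counts[cond] = np.rint(mean).astype(np.int64)
        rates[cond] = eta
    return (
        pd.DataFrame(counts, index=ids, dtype=np.int64),
        pd.DataFrame(rates, index=ids),
    )


def draw_rate_panel(
    zcta_table: pd.DataFrame, truth: GroundTruth, config: GeneratorConfig
):
    """Qualifying counts and rates per ZCTA x condition, skipping episode rows.

    Uses the same count stream as :func:`generate_visits`, so the panel it
    returns equals what filtering and rate computation would recover from the
    full record expansion — convenient for replicated recovery studies where
    materializing every episode row is pointless.  Updates ``truth`` in place.
    """
    from .visits import RatePanel  # local import: visits does not need synth

    config.validate()
    _, count_rng, _ = _streams(config.seed)
    quintile = truth.latent_quintile.loc[zcta_table["zcta_id"]].to_numpy()
    counts, expected = _draw_condition_counts(zcta_table, config, count_rng, quintile)
    truth.qualifying_counts = counts
    truth.expected_rates = expected
    truth.n_qualifying = int(counts.to_numpy().sum())
    pop2 = (
        (zcta_table["pop_year1"] + zcta_table["pop_year2"])
        .set_axis(counts.index)
        .astype(float)
    )
    rates = 1000.0 * counts.div(pop2, axis=0)
    return RatePanel(config.condition_list(), counts, rates, pop2)


def generate_visits(
    zcta_table: pd.DataFrame, truth: GroundTruth, config: GeneratorConfig
) -> pd.DataFrame:
    """Episode-level encounter records implied by the planted rate model.

    Qualifying records (uninsured payer, age 18-64, valid area) are the count
    expansion of the Poisson draws; on top of them
    ``round(n_qualifying * f / (1 - f))`` noise records are appended, each
    violating exactly one inclusion criterion, where f is
    ``config.noise_fraction``.  The planted counts are stored on ``truth``.
    """
    config.validate()
    if len(zcta_table) == 0:
        raise ConfigurationError("zcta_table is empty")
    _, count_rng, noise_rng = _streams(config.seed)
    quintile = truth.latent_quintile.loc[zcta_table["zcta_id"]].to_numpy()

    counts, expected = _draw_condition_counts(zcta_table, config, count_rng, quintile)
    truth.qualifying_counts = counts
    truth.expected_rates = expected

    conditions = config.condition_list()
    total_q = int(counts.to_numpy().sum())
    zcta_rep = np.repeat(
        np.tile(counts.index.to_numpy(), len(conditions)),
        counts.to_numpy().T.ravel(),
    )
    cond_rep = np.repeat(np.asarray(conditions, dtype=object), counts.sum(axis=0).to_numpy())

    uninsured = sorted(UNINSURED_PAYERS)
    qual = pd.DataFrame(
        {
            "encounter_id": [f"E{i:08d}" for i in range(1, total_q + 1)],
            "zcta_id": zcta_rep,
            "age": count_rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1, size=total_q),
            "payer": np.asarray(uninsured, dtype=object)[
                count_rng.integers(0, len(uninsured), size=total_q)
            ],
            "condition": cond_rep,
            "year": np.asarray(config.study_years)[
                count_rng.integers(0, len(config.study_years), size=total_q)
            ],
        }
    )

    f = config.noise_fraction
    n_noise = int(round(total_q * f / (1.0 - f))) if f > 0 else 0
    truth.n_qualifying = total_q
    truth.n_noise = n_noise
    if n_noise == 0:
        return qual

    insured = [p for p in PAYER_CATEGORIES if p not in UNINSURED_PAYERS]
    violation = noise_rng.integers(0, 3, size=n_noise)  # 0 payer, 1 age, 2 area
    zctas = zcta_table["zcta_id"].to_numpy()
    noise_zcta = zctas[noise_rng.integers(0, len(zctas), size=n_noise)].astype(object)
    noise_zcta[violation == 2] = INVALID_ZCTA

    noise_payer = np.asarray(uninsured, dtype=object)[
        noise_rng.integers(0, len(uninsured), size=n_noise)
    ]
    noise_payer[violation == 0] = np.asarray(insured, dtype=object)[
        noise_rng.integers(0, len(insured), size=int((violation == 0).sum()))
    ]

    noise_age = noise_rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1, size=n_noise)
    n_young_old = int((violation == 1).sum())
    young_old = np.where(
        noise_rng.random(n_young_old) < 0.5,
        noise_rng.integers(0, AGE_RANGE[0], size=n_young_old),
        noise_rng.integers(AGE_RANGE[1] + 1, 95, size=n_young_old),
    )
    noise_age[violation == 1] = young_old

    noise = pd.DataFrame(
        {
            "encounter_id": [f"N{i:08d}" for i in range(1, n_noise + 1)],
            "zcta_id": noise_zcta,
            "age": noise_age,
            "payer": noise_payer,
            "condition": np.asarray(conditions, dtype=object)[
                noise_rng.integers(0, len(conditions), size=n_noise)
            ],
            "year": np.asarray(config.study_years)[
                noise_rng.integers(0, len(config.study_years), size=n_noise)
            ],
        }
    )
    return pd.concat([qual, noise], ignore_index=True)
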