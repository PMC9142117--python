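"""Encounter-level filtering and ZCTA-level visit rates.

This module turns episode-level emergency-department (ED) encounter records
into the area-level analysis inputs: it applies the uninsured-adult inclusion
filters, tabulates the most frequent minor diagnostic categories
("conditions"), and computes two-year visit rates per 1000 population for
every ZCTA x condition cell.

Encounter tables are plain :class:`pandas.DataFrame` objects with the columns
listed in :data:`VISIT_COLUMNS`; ZCTA covariate tables carry at least
``zcta_id``, ``pop_year1`` and ``pop_year2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputDataError

#: every primary-payer category an encounter record may carry
PAYER_CATEGORIES = (
    "self_pay",
    "indigent_charitable",
    "medicare",
    "medicaid",
    "commercial",
    "workers_comp",
    "other_government",
    "hmo",
)

#: payers treated as "uninsured" (kept by the inclusion filter)
UNINSURED_PAYERS = frozenset({"self_pay", "indigent_charitable"})

#: adult age band retained by the inclusion filter, inclusive
AGE_RANGE = (18, 64)

#: required columns of an encounter table
VISIT_COLUMNS = ("encounter_id", "zcta_id", "age", "payer", "condition", "year")

#: sentinel used for encounters whose billing area is not a valid ZCTA
INVALID_ZCTA = "invalid"


@dataclass(frozen=True)
class FilterTally:
    """Bookkeeping for one pass of :func:`filter_encounters`.

    Every input record is attributed exactly once: either kept, excluded by
    the *first* failed criterion in the fixed order payer -> age -> area, or
    counted as unparseable (unknown payer code, missing/negative age,
    missing area label).
    """

    n_input: int
    n_kept: int
    excluded_payer: int
    excluded_age: int
    excluded_area: int
    excluded_unparseable: int = 0

    @property
    def conserved(self) -> bool:
        """True iff kept + all exclusion buckets account for every input."""
        return self.n_input == (
            self.n_kept
            + self.excluded_payer
            + self.excluded_age
            + self.excluded_area
            + self.excluded_unparseable
        )


@dataclass
class RatePanel:
    """Dense ZCTA x condition panel of visit counts and rates per 1000.

    ``rate = 1000 * count / (pop_year1 + pop_year2)`` exactly, so the panel
    round-trips: ``rate * two_year_pop / 1000`` recovers the integer count.
    ZCTAs with no visits of a condition contribute rate 0 rather than being
    dropped, so every condition regresses on the full set of areas.
    """

    conditions: list[str]
    counts: pd.DataFrame  # index zcta_id, one column per condition, int
    rates: pd.DataFrame  # same shape, float
    two_year_pop: pd.Series  # index zcta_id

    @property
    def zcta_ids(self) -> pd.Index:
        return self.counts.index

    def to_long(self) -> pd.DataFrame:
        """Long form (zcta_id, condition, count, rate), sorted and dense."""
        long = (
            self.counts.stack()
            .rename("count")
            .to_frame()
            .join(self.rates.stack().rename("rate"))
            .reset_index()
        )
        long.columns = ["zcta_id", "condition", "count", "rate"]
        return long.sort_values(["condition", "zcta_id"], ignore_index=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame, two_year_pop: pd.Series) -> "RatePanel":
        counts = long.pivot(index="zcta_id", columns="condition", values="count")
        rates = long.pivot(index="zcta_id", columns="condition", values="rate")
        conditions = list(counts.columns)
        return cls(conditions, counts.astype(int), rates, two_year_pop.loc[counts.index])


def _require_columns(records: pd.DataFrame, columns=VISIT_COLUMNS) -> None:
    missing = [c for c in columns if c not in records.columns]
    if missing:
        raise InputDataError(f"encounter table is missing columns: {missing}")


def filter_encounters(
    records: pd.DataFrame, valid_zctas
) -> tuple[pd.DataFrame, FilterTally]:
    """Apply the uninsured-adult inclusion criteria to encounter records.

    Kept records satisfy all of: payer in the uninsured set (self-pay or
    indigent/charitable), age in [18, 64], and a billing area present in
    ``valid_zctas``.  Exclusions are attributed to the first failed criterion
    in the order payer -> age -> area; records that cannot be parsed at all
    (unknown payer category, null or negative age, null area) fall into a
    separate bucket.

    Parameters
    ----------
    records
        Encounter table with the :data:`VISIT_COLUMNS` columns.
    valid_zctas
        Iterable of area labels considered valid (typically the ZCTA table's
        ``zcta_id`` column).

    Returns
    -------
    (kept, tally)
        The retained records (original row order preserved) and the
        conservation tally.
    """
    valid = frozenset(valid_zctas)
    if not valid:
        raise InputDataError("valid_zctas must be nonempty")
    _require_columns(records)
    n = len(records)
    if n == 0:
        return records.copy(), FilterTally(0, 0, 0, 0, 0, 0)

    age = pd.to_numeric(records["age"], errors="coerce")
    payer = records["payer"]
    area = records["zcta_id"]

    unparseable = (
        ~payer.isin(PAYER_CATEGORIES) | age.isna() | (age < 0) | area.isna()
    ).to_numpy()
    payer_fail = (~payer.isin(UNINSURED_PAYERS)).to_numpy() & ~unparseable
    age_fail = (
        ((age < AGE_RANGE[0]) | (age > AGE_RANGE[1])).to_numpy()
        & ~unparseable
        & ~payer_fail
    )
    area_fail = (
        (~area.isin(valid)).to_numpy() & ~unparseable & ~payer_fail & ~age_fail
    )
    kept_mask = ~(unparseable | payer_fail | age_fail | area_fail)

    tally = FilterTally(
        n_input=n,
        n_kept=int(kept_mask.sum()),
        excluded_payer=int(payer_fail.sum()),
        excluded_age=int(age_fail.sum()),
        excluded_area=int(area_fail.sum()),
        excluded_unparseable=int(unparseable.sum()),
    )
    return records.loc[kept_mask].copy(), tally


def tabulate_conditions(records: pd.DataFrame, k: int) -> list[tuple[str, int]]:
    """Rank conditions by visit count and return the top ``k``.

    Ties in count are broken by condition label ascending, which makes the
    selection deterministic.  Asking for more conditions than exist returns
    all of them with a warning.
    """
    if k < 1:
        raise InputDataError(f"k must be >= 1, got {k}")
    counts = records.groupby("condition").size()
    ranked = counts.sort_index().sort_values(ascending=False, kind="stable")
    if len(ranked) < k:
        warnings.warn(
            f"requested top {k} conditions but only {len(ranked)} are present",
            stacklevel=2,
        )
    top = ranked.iloc[:k]
    return list(zip(top.index.tolist(), [int(c) for c in top.to_numpy()]))


def two_year_population(zctas: pd.DataFrame) -> pd.Series:
    """Sum of the two annual 18-64 populations, indexed by zcta_id."""
    pop = (
        zctas.set_index("zcta_id")[["pop_year1", "pop_year2"]]
        .sum(axis=1)
        .rename("two_year_pop")
    )
    bad = pop[pop <= 0]
    if len(bad):
        raise InputDataError(
            f"nonpositive two-year population for zcta_id={bad.index[0]!r}"
        )
    return pop


def compute_rates(
    records: pd.DataFrame, zctas: pd.DataFrame, conditions: list[str]
) -> RatePanel:
    """Two-year visit rates per 1000 population, dense over ZCTA x condition.

    Each cell's rate is ``1000 * count / (pop_year1 + pop_year2)``; pairs
    with no visits get count 0 and rate 0.  Every record must belong to a
    ZCTA of the covariate table — the inclusion filter guarantees that.
    """
    pop = two_year_population(zctas)
    zcta_ids = pop.index

    stray = records.loc[~records["zcta_id"].isin(zcta_ids), "zcta_id"]
    if len(stray):
        raise InputDataError(
            f"record references unknown zcta_id={stray.iloc[0]!r}; "
            "run filter_encounters first"
        )

    sub = records[records["condition"].isin(conditions)]
    counts = (
        pd.crosstab(sub["zcta_id"], sub["condition"])
        .reindex(index=zcta_ids, columns=conditions, fill_value=0)
        .astype(int)
    )
    counts.index.name = "zcta_id"
    rates = 1000.0 * counts.div(pop, axis=0)
    return RatePanel(list(conditions), counts, rates, pop)
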