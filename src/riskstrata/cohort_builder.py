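"""Eligibility filters, randomized training/study split, and admission counts.

The study design pairs a *base year* (predictors) with the following
*performance year* (outcomes).  The training arm is calibrated on one pairing
and the held-out study arm is evaluated on the next, so no pairing is shared
between arms.  Eligibility mirrors standard fee-for-service risk-adjustment
practice: aged 65+ at the start of the base year, continuously enrolled in
Parts A and B over both years (decedents kept if fully enrolled while
living), with Medicare Advantage (Part C) enrollees and ESRD beneficiaries
excluded; dual-eligible (state buy-in) beneficiaries are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortSpec:
    """One base-year/performance-year pairing plus the eligibility knobs."""

    base_year: int
    min_age: int = 65
    include_decedents: bool = True
    exclude_part_c: bool = True
    exclude_esrd: bool = True
    split_seed: int = 0

    @property
    def performance_year(self) -> int:
        return self.base_year + 1


def apply_eligibility(beneficiaries: pd.DataFrame, spec: CohortSpec) -> pd.Index:
    """Return the sorted ids eligible for the spec's base/performance pairing.

    Continuous enrollment means 12 Part A months and 12 Part B months in both
    the base and the performance year.  Decedents are retained only when
    death falls in (or after) the performance year and every year while
    living is fully enrolled -- prorated to the death month in the death
    year.  Ids missing a row for either year are excluded with a warning.
    """
    years = (spec.base_year, spec.performance_year)
    sub = beneficiaries[beneficiaries["year"].isin(years)]
    wide = sub.pivot_table(
        index="beneficiary_id",
        columns="year",
        values=["part_a_months", "part_b_months"],
        aggfunc="first",
    )
    wide = wide.reindex(
        columns=pd.MultiIndex.from_product([["part_a_months", "part_b_months"], years])
    )
    per_id = sub.drop_duplicates("beneficiary_id").set_index("beneficiary_id")

    have_both = wide.notna().all(axis=1)
    n_missing = int((~have_both).sum())
    if n_missing:
        logger.warning(
            "%d beneficiaries missing enrollment rows for %s excluded", n_missing, years
        )
    wide = wide[have_both]
    per_id = per_id.loc[wide.index]

    age = spec.base_year - per_id["birth_year"]
    ok = age >= spec.min_age

    death = pd.to_datetime(
        per_id["death_date"].replace("", pd.NA), errors="coerce"
    )
    death_year = death.dt.year
    death_month = death.dt.month

    full = pd.Series(True, index=wide.index)
    for y in years:
        required = pd.Series(12, index=wide.index)
        if spec.include_decedents:
            died_this_year = death_year == y
            required[died_this_year] = death_month[died_this_year]
            required[death_year < y] = 0
        for part in ("part_a_months", "part_b_months"):
            full &= wide[(part, y)] >= required
    ok &= full

    if spec.include_decedents:
        # a death during the base year leaves no performance-year outcome
        ok &= ~(death_year <= spec.base_year).fillna(False)
    else:
        ok &= death.isna()

    if spec.exclude_part_c:
        any_c = (
            sub.groupby("beneficiary_id")["part_c_any"].any().reindex(wide.index)
        )
        ok &= ~any_c.fillna(False).astype(bool)
    if spec.exclude_esrd:
        any_esrd = sub.groupby("beneficiary_id")["esrd"].any().reindex(wide.index)
        ok &= ~any_esrd.fillna(False).astype(bool)

    return pd.Index(sorted(wide.index[ok]))


def split_train_study(eligible_ids, split_seed: int) -> pd.Series:
    """Assign each id a pseudo-random integer; even parity -> training arm.

    Returns a Series indexed by id with values ``"training"``/``"study"``.
    Deterministic given the seed; the two arms partition the input.
    """
    ids = sorted(eligible_ids)
    if not ids:
        raise ValueError("empty id set")
    rng = np.random.default_rng(split_seed)
    draws = rng.integers(0, 2**31, size=len(ids))
    arm = np.where(draws % 2 == 0, "training", "study")
    return pd.Series(arm, index=pd.Index(ids, name="beneficiary_id"), name="arm")


def count_admissions(claims: pd.DataFrame, ids, year: int) -> pd.Series:
    """Per-id inpatient admission counts for one calendar year.

    Sums ``admission_count`` over inpatient claims with
    ``service_year == year``; ids without claims get 0.  Returned in the
    order of ``ids``.
    """
    ids = list(ids)
    inpt = claims[
        (claims["setting"] == "inpatient") & (claims["service_year"] == year)
    ]
    counts = inpt.groupby("beneficiary_id")["admission_count"].sum()
    return counts.reindex(ids, fill_value=0).astype(int).rename("admissions")


def build_cohort(
    beneficiaries: pd.DataFrame, spec: CohortSpec
) -> pd.DataFrame:
    """Eligibility + split for one pairing; returns the cohort table
    (beneficiary_id, arm, base_year, performance_year)."""
    eligible = apply_eligibility(beneficiaries, spec)
    arms = split_train_study(eligible, spec.split_seed)
    return pd.DataFrame(
        {
            "beneficiary_id": arms.index,
            "arm": arms.values,
            "base_year": spec.base_year,
            "performance_year": spec.performance_year,
        }
    )
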