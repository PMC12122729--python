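"""End-to-end study pipeline: cohort -> profiles -> fit -> stratify -> segments.

Mirrors the study design: the randomized training arm is calibrated on the
first base/performance pairing (e.g. 2017 diagnoses -> 2018 admissions), and
the disjoint study arm is evaluated on the next pairing (2018 -> 2019), so
the two arms never share a pairing.  Eligibility is evaluated per pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import (
    cohort_builder,
    hcc_mapper,
    regression_engine,
    segments_reporting,
    stratification,
)


@dataclass
class StudyResult:
    """Everything the study computes on one simulated or loaded population."""

    training_ids: pd.Index
    study_ids: pd.Index
    observed: pd.Series  # study-arm performance-year admission counts
    coefficients: pd.Series | None = None  # indexed by design column id
    expected: pd.Series | None = None
    quintiles: pd.Series | None = None
    quintile_summaries: list = field(default_factory=list)
    segment_summaries: list | None = None
    r_squared: float | None = None

    @property
    def marginal_rate(self) -> float:
        """Study-arm admissions per beneficiary (person-year)."""
        return float(self.observed.mean())


def run_study(
    beneficiaries: pd.DataFrame,
    claims: pd.DataFrame,
    table: hcc_mapper.MappingTable,
    split_seed: int,
    years: tuple[int, ...] = (2017, 2018, 2019),
    fit: bool = True,
) -> StudyResult:
    """Run the full analysis on raw beneficiary and claim tables.

    ``years`` is (training base, study base, study performance).  The
    training pairing is ``years[0] -> years[0]+1`` and the study pairing
    ``years[1] -> years[1]+1``.  With ``fit=False`` only the cohort and the
    observed study-arm counts are computed (cheap calibration probes).
    """
    if len(years) != 3:
        raise ValueError("years must be (training base, study base, study performance)")
    train_spec = cohort_builder.CohortSpec(base_year=years[0], split_seed=split_seed)
    study_spec = cohort_builder.CohortSpec(base_year=years[1], split_seed=split_seed)

    all_ids = beneficiaries["beneficiary_id"].drop_duplicates()
    arms = cohort_builder.split_train_study(all_ids, split_seed)
    train_eligible = cohort_builder.apply_eligibility(beneficiaries, train_spec)
    study_eligible = cohort_builder.apply_eligibility(beneficiaries, study_spec)
    training_ids = pd.Index(
        sorted(set(train_eligible) & set(arms.index[arms == "training"]))
    )
    study_ids = pd.Index(sorted(set(study_eligible) & set(arms.index[arms == "study"])))
    if len(training_ids) == 0 or len(study_ids) == 0:
        raise ValueError("empty training or study arm after eligibility filters")

    observed = cohort_builder.count_admissions(
        claims, study_ids, study_spec.performance_year
    )
    result = StudyResult(training_ids=training_ids, study_ids=study_ids, observed=observed)
    if not fit:
        return result

    train_profiles = hcc_mapper.build_profiles(
        claims, beneficiaries, training_ids, train_spec.base_year, table
    )
    study_profiles = hcc_mapper.build_profiles(
        claims, beneficiaries, study_ids, study_spec.base_year, table
    )
    X_t = regression_engine.build_design_matrix(train_profiles, table.category_ids)
    X_s = regression_engine.build_design_matrix(study_profiles, table.category_ids)
    y_t = cohort_builder.count_admissions(
        claims, X_t.row_ids, train_spec.performance_year
    )
    b = regression_engine.fit_least_squares(X_t, y_t.to_numpy())
    expected_arr = regression_engine.predict(X_s, b, col_ids=X_t.col_ids)

    result.coefficients = pd.Series(b, index=list(X_t.col_ids), name="coefficient")
    expected = pd.Series(expected_arr, index=list(X_s.row_ids), name="expected")
    observed = observed.reindex(expected.index)
    result.expected = expected
    result.observed = observed

    quintiles = stratification.assign_quintiles(
        expected.to_numpy(), expected.index.to_numpy()
    )
    result.quintiles = quintiles
    aligned_obs = observed.loc[quintiles.index]
    aligned_exp = expected.loc[quintiles.index]
    result.quintile_summaries = stratification.quintile_summary(
        quintiles, aligned_exp.to_numpy(), aligned_obs.to_numpy()
    )
    result.r_squared = stratification.r_squared(
        aligned_obs.to_numpy(), aligned_exp.to_numpy()
    )
    memberships = segments_reporting.cumulative_segments(quintiles)
    result.segment_summaries = segments_reporting.segment_summary(
        memberships, aligned_obs, aligned_exp
    )
    return result


def run_synthetic_study(
    n_beneficiaries: int, seed: int, table: hcc_mapper.MappingTable | None = None
) -> StudyResult:
    """Default-calibrated synthetic population through the full pipeline."""
    from . import synthetic_data

    params = synthetic_data.default_params(n_beneficiaries, seed=seed)
    if table is None:
        table = hcc_mapper.fixture_mapping_table(params.n_categories)
    bene, claims = synthetic_data.generate_population(params, table)
    return run_study(bene, claims, table, split_seed=seed + 101, years=params.years)
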