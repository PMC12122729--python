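"""Generator distributional checks, determinism, and calibration helpers."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from riskstrata import cohort_builder, hcc_mapper, synthetic_data
from riskstrata.synthetic_data import (
    GeneratorParams,
    calibrate_defaults,
    default_params,
    generate_population,
    nb_shape_for_zero_fraction,
)


def _flat_params(n, base_rate, frailty=math.inf, n_categories=4, seed=0, **kw):
    """Params with uniform base rates and inert categories unless overridden."""
    cells = {c: base_rate for c in hcc_mapper.demographic_cell_ids()}
    defaults = dict(
        n_beneficiaries=n,
        n_categories=n_categories,
        category_prevalences=np.full(n_categories, 0.05),
        category_effects=np.ones(n_categories),
        demographic_cells=cells,
        frailty_shape=frailty,
        death_rate=0.0,
        exclusion_rates={"part_c": 0.0, "esrd": 0.0},
        seed=seed,
    )
    defaults.update(kw)
    return GeneratorParams(**defaults)


class TestValidation:
    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError, match="n_beneficiaries"):
            _flat_params(0, 0.1)

    def test_prevalence_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="category_prevalences"):
            GeneratorParams(
                n_beneficiaries=10,
                n_categories=5,
                category_prevalences=np.full(4, 0.1),
            )

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError, match="persistence"):
            _flat_params(10, 0.1, persistence=1.5)
        with pytest.raises(ValueError, match="effects"):
            _flat_params(10, 0.1, category_effects=np.array([1.0, -1.0, 1.0, 1.0]))


class TestGeneration:
    def test_seed_determinism_byte_identical(self):
        params = default_params(1500, seed=33)
        b1, c1 = generate_population(params)
        b2, c2 = generate_population(params)
        assert b1.to_csv(index=False) == b2.to_csv(index=False)
        assert c1.to_csv(index=False) == c2.to_csv(index=False)

    def test_poisson_closed_form_when_model_is_inert(self):
        # no frailty, no category effects, flat base rate 0.1 -> Poisson(0.1)
        n = 20_000
        params = _flat_params(n, 0.1, seed=4)
        bene, claims = generate_population(params)
        ids = bene["beneficiary_id"].drop_duplicates()
        counts = cohort_builder.count_admissions(claims, ids, 2018)
        zero_frac = (counts == 0).mean()
        # binomial MC error on P(0) = e^-0.1
        p0 = math.exp(-0.1)
        se = math.sqrt(p0 * (1 - p0) / n)
        assert abs(zero_frac - p0) < 4 * se
        assert abs(counts.mean() - 0.1) < 4 * math.sqrt(0.1 / n)

    def test_unit_mean_frailty_preserves_analytic_mean(self):
        # finite frailty must not shift the mean: compare the simulated
        # performance-year mean with the frailty-free analytic value
        n = 40_000
        k = 6
        prev = np.linspace(0.02, 0.2, k)
        eff = np.linspace(1.2, 2.5, k)
        params = _flat_params(
            n,
            0.15,
            frailty=0.8,
            n_categories=k,
            category_prevalences=prev,
            category_effects=eff,
            persistence=0.9,
            seed=9,
        )
        table = hcc_mapper.fixture_mapping_table(k, n_rules=0)  # independence holds
        bene, claims, latent = generate_population(params, table, return_latent=True)
        counts = latent["counts_by_year"][2018]
        analytic = 0.15 * np.prod(1 + prev * 0.9 * (eff - 1))
        se = counts.std(ddof=1) / math.sqrt(n)
        assert abs(counts.mean() - analytic) < 3 * se

    def test_finite_frailty_overdisperses_counts(self):
        params = default_params(50_000, seed=2)
        _, _, latent = generate_population(params, return_latent=True)
        counts = latent["counts_by_year"][2019]
        assert counts.var(ddof=1) > 1.5 * counts.mean()

    def test_claims_round_trip_recovers_drawn_categories(self, fixture_table):
        """hcc_mapper profiles reconstructed from emitted claims must equal
        the generator's drawn post-hierarchy categories exactly."""
        params = default_params(2500, seed=13)
        bene, claims, latent = generate_population(
            params, fixture_table, return_latent=True
        )
        ids = list(latent["ids"])
        for year in (2017, 2018):
            alive = (latent["death_year"] == 0) | (latent["death_year"] >= year)
            flags = hcc_mapper.category_flag_matrix(claims, ids, year, fixture_table)
            assert (flags[alive] == latent["z_by_year"][year][alive]).all()
            assert not flags[~alive].any()

    def test_admission_count_marks_inpatient_claims_only(self, small_population):
        _, _, claims, _ = small_population
        inpatient = claims["setting"] == "inpatient"
        assert (claims.loc[inpatient, "admission_count"] == 1).all()
        assert (claims.loc[~inpatient, "admission_count"] == 0).all()

    def test_enrollment_stops_after_death(self, small_population):
        _, bene, _, _ = small_population
        died = bene[bene["death_date"] != ""].copy()
        death_year = died["death_date"].str.slice(0, 4).astype(int)
        after = died[died["year"] > death_year]
        assert (after["part_a_months"] == 0).all()
        assert (after["part_b_months"] == 0).all()


class TestNbShapeOracle:
    def test_matches_root_of_zero_probability_equation(self):
        # the study stratum mean 0.689 with 63% zeros implies shape ~0.6;
        # 0.6141952 frozen from brentq on r and sympy.nsolve at 20 digits
        r = nb_shape_for_zero_fraction(0.689, 0.63)
        assert abs(r - 0.6141952328) < 1e-8
        assert abs((r / (r + 0.689)) ** r - 0.63) < 1e-10

    def test_rejects_underdispersed_inputs(self):
        with pytest.raises(ValueError, match="Poisson"):
            nb_shape_for_zero_fraction(0.5, math.exp(-0.5) / 2)


class TestCalibrateDefaults:
    def test_satisfied_constraints_return_start_unchanged(self):
        start = _flat_params(20_000, 0.25, seed=21)
        # generous band around the known mean: already a fixed point
        out = calibrate_defaults(
            [("marginal_rate", 0.25, 0.05)], start=start, n_sim=20_000
        )
        assert out.demographic_cells == start.demographic_cells
        assert out.frailty_shape == start.frailty_shape

    def test_single_free_base_rate_recovers_poisson_mean(self):
        start = _flat_params(40_000, 0.15, seed=22)
        out = calibrate_defaults(
            [("marginal_rate", 0.27, 0.01)], start=start, n_sim=40_000
        )
        rates = set(np.round(list(out.demographic_cells.values()), 6))
        assert len(rates) == 1  # uniform scaling preserved the flat structure
        assert abs(rates.pop() - 0.27) < 0.02

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError, match="unknown calibration statistic"):
            calibrate_defaults([("median_rate", 0.5, 0.1)])

    def test_infeasible_constraints_raise_with_worst_violation(self):
        start = _flat_params(5_000, 0.1, seed=23)
        with pytest.raises(synthetic_data.CalibrationError, match="marginal_rate"):
            calibrate_defaults(
                [("marginal_rate", 0.1, 1e-9)], start=start, n_sim=5_000, max_iter=2
            )
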