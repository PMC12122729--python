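"""Design-matrix construction and least-squares contracts."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riskstrata import hcc_mapper
from riskstrata.regression_engine import (
    DesignMatrix,
    build_design_matrix,
    design_columns,
    fit_least_squares,
    predict,
)


def profiles_frame(rows):
    return pd.DataFrame(
        rows, columns=["beneficiary_id", "base_year", "demographic_cell", "hcc_flags"]
    )


CATS = ("CC001", "CC002", "CC003")


class TestBuildDesignMatrix:
    def test_empty_profile_row_is_pure_demographic(self):
        X = build_design_matrix(
            profiles_frame([("b1", 2018, "F_65_69", "")]), CATS
        )
        row = X.toarray()[0]
        assert row.sum() == 1
        assert row[X.col_ids.index("F_65_69")] == 1

    def test_demographic_block_is_exclusive_and_exhaustive(self, small_population, fixture_table):
        params, bene, claims, _ = small_population
        ids = bene["beneficiary_id"].drop_duplicates().iloc[:500]
        profiles = hcc_mapper.build_profiles(claims, bene, ids, 2018, fixture_table)
        X = build_design_matrix(profiles, fixture_table.category_ids)
        n_cells = len(hcc_mapper.demographic_cell_ids())
        demo_block = X.toarray()[:, :n_cells]
        assert (demo_block.sum(axis=1) == 1).all()

    def test_matches_hand_written_matrix(self):
        profiles = profiles_frame(
            [
                ("b3", 2018, "M_90plus", "CC001;CC003"),
                ("b1", 2018, "F_65_69", ""),
                ("b2", 2018, "F_65_69", "CC002"),
            ]
        )
        X = build_design_matrix(profiles, CATS)
        assert X.row_ids == ("b1", "b2", "b3")  # sorted for determinism
        cols = design_columns(CATS)
        expect = np.zeros((3, len(cols)))
        expect[0, cols.index("F_65_69")] = 1
        expect[1, cols.index("F_65_69")] = 1
        expect[1, cols.index("CC002")] = 1
        expect[2, cols.index("M_90plus")] = 1
        expect[2, cols.index("CC001")] = 1
        expect[2, cols.index("CC003")] = 1
        np.testing.assert_array_equal(X.toarray(), expect)

    def test_unknown_category_named_in_error(self):
        with pytest.raises(ValueError, match="CC999"):
            build_design_matrix(
                profiles_frame([("b1", 2018, "F_65_69", "CC999")]), CATS
            )


class TestFitLeastSquares:
    def test_identity_design_returns_y(self):
        y = np.array([3.0, -1.0, 2.5, 0.0])
        b = fit_least_squares(np.eye(4), y)
        np.testing.assert_allclose(b, y, atol=1e-12)

    def test_recovers_exact_solution_when_consistent(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 5))
        b0 = rng.normal(size=5)
        b = fit_least_squares(X, X @ b0)
        np.testing.assert_allclose(b, b0, atol=1e-8)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=50)
    def test_matches_pseudoinverse_oracle_on_random_systems(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        b = fit_least_squares(X, y)
        oracle = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(b, oracle, atol=1e-8)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=50)
    def test_residual_orthogonality_contract(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 6))
        y = rng.poisson(1.0, size=40).astype(float)
        b = fit_least_squares(X, y)
        grad = np.abs(X.T @ (y - X @ b)).max()
        assert grad <= 1e-6 * np.abs(X.T @ y).max()

    def test_rank_deficient_falls_back_to_minimum_norm(self):
        rng = np.random.default_rng(3)
        base = rng.random((20, 2))
        X = np.column_stack([base, base[:, 0]])  # duplicated column
        y = rng.random(20)
        b = fit_least_squares(X, y)
        oracle = np.linalg.pinv(X) @ y
        np.testing.assert_allclose(b, oracle, atol=1e-8)
        # minimum norm splits the duplicated column's weight equally
        assert abs(b[0] - b[2]) < 1e-8

    def test_all_zero_column_warns_and_gets_zero_coefficient(self, caplog):
        rng = np.random.default_rng(4)
        X = rng.random((15, 3))
        X[:, 1] = 0.0
        with caplog.at_level(logging.WARNING):
            b = fit_least_squares(X, rng.random(15))
        assert "all-zero" in caplog.text
        assert b[1] == pytest.approx(0.0, abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            fit_least_squares(np.eye(3), np.ones(4))

    def test_fitted_mean_preserved_by_demographic_partition(self, small_population, fixture_table):
        """Demographic cells partition every row, so fitted values keep the
        training mean exactly (the composite-intercept property)."""
        params, bene, claims, _ = small_population
        from riskstrata import cohort_builder

        ids = bene["beneficiary_id"].drop_duplicates()
        profiles = hcc_mapper.build_profiles(claims, bene, ids, 2017, fixture_table)
        X = build_design_matrix(profiles, fixture_table.category_ids)
        y = cohort_builder.count_admissions(claims, X.row_ids, 2018).to_numpy()
        b = fit_least_squares(X, y)
        fitted = predict(X, b)
        assert abs(fitted.mean() - y.mean()) < 1e-8

    def test_sse_not_improvable_by_perturbation(self):
        rng = np.random.default_rng(6)
        X = rng.random((60, 5))
        y = rng.poisson(0.5, 60).astype(float)
        b = fit_least_squares(X, y)
        sse = np.sum((y - X @ b) ** 2)
        for _ in range(100):
            delta = rng.normal(scale=1e-3, size=5)
            assert np.sum((y - X @ (b + delta)) ** 2) >= sse - 1e-12


class TestPredict:
    def test_zero_coefficients_give_zero_expectations(self):
        X = build_design_matrix(
            profiles_frame([("b1", 2018, "F_65_69", "CC001")]), CATS
        )
        np.testing.assert_array_equal(predict(X, np.zeros(len(X.col_ids))), [0.0])

    def test_unit_row_returns_cell_coefficient(self):
        X = build_design_matrix(profiles_frame([("b1", 2018, "F_70_74", "")]), CATS)
        b = np.arange(len(X.col_ids), dtype=float)
        assert predict(X, b)[0] == b[X.col_ids.index("F_70_74")]

    def test_hand_computed_products(self):
        X = build_design_matrix(
            profiles_frame(
                [("b1", 2018, "F_65_69", "CC001;CC002"), ("b2", 2018, "M_90plus", "")]
            ),
            CATS,
        )
        b = np.ones(len(X.col_ids)) * 0.5
        np.testing.assert_allclose(predict(X, b), [1.5, 0.5])

    def test_negative_expectations_are_retained(self):
        X = build_design_matrix(profiles_frame([("b1", 2018, "F_65_69", "CC001")]), CATS)
        b = np.zeros(len(X.col_ids))
        b[X.col_ids.index("CC001")] = -2.0
        assert predict(X, b)[0] == -2.0

    def test_column_order_mismatch_rejected(self):
        X = build_design_matrix(profiles_frame([("b1", 2018, "F_65_69", "")]), CATS)
        wrong = tuple(reversed(X.col_ids))
        with pytest.raises(ValueError, match="column order"):
            predict(X, np.zeros(len(X.col_ids)), col_ids=wrong)
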