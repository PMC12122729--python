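import numpy as np
import pandas as pd
import pytest

from riskstrata import hcc_mapper, synthetic_data


@pytest.fixture(scope="session")
def fixture_table():
    return hcc_mapper.fixture_mapping_table()


@pytest.fixture(scope="session")
def small_table():
    """Compact mapping table: 8 categories, 2 dominance rules."""
    return hcc_mapper.fixture_mapping_table(n_categories=8, n_rules=2)


@pytest.fixture(scope="session")
def small_population(fixture_table):
    """A default-calibrated population small enough for per-test reuse."""
    params = synthetic_data.default_params(4000, seed=7)
    bene, claims, latent = synthetic_data.generate_population(
        params, fixture_table, return_latent=True
    )
    return params, bene, claims, latent


def make_beneficiary_rows(
    bid,
    birth_year=1945,
    sex="F",
    death_date="",
    months=None,
    part_c=False,
    esrd=False,
    dual=False,
    years=(2017, 2018, 2019),
):
    """Hand-built enrollment rows for one beneficiary (one row per year)."""
    months = months if months is not None else {y: 12 for y in years}
    rows = []
    for y in years:
        rows.append(
            {
                "beneficiary_id": bid,
                "sex": sex,
                "birth_year": birth_year,
                "death_date": death_date,
                "year": y,
                "part_a_months": months.get(y, 12),
                "part_b_months": months.get(y, 12),
                "part_c_any": part_c,
                "esrd": esrd,
                "dual_buyin": dual,
            }
        )
    return rows


@pytest.fixture
def beneficiary_rows():
    return make_beneficiary_rows


def claims_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "beneficiary_id",
            "service_year",
            "setting",
            "diagnosis_codes",
            "admission_count",
        ],
    )


@pytest.fixture
def make_claims():
    return claims_frame
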