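"""Shared fixtures: published bundles and small synthetic cohorts."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from bpref import cohort as coh
from bpref.reference import load_bundled_model
from bpref.synthetic import GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def slopes_model():
    return load_bundled_model("ehr_random_slopes")


@pytest.fixture(scope="session")
def intercept_model():
    return load_bundled_model("ehr_random_intercept")


@pytest.fixture(scope="session")
def clean_table(slopes_model):
    """Contamination-free encounter table, 800 children."""
    cfg = GeneratorConfig(n_children=800, seed=11).without_contamination()
    return simulate_cohort(cfg, slopes_model)


@pytest.fixture(scope="session")
def clean_rows(clean_table):
    """Analysis rows (one per child-day) from the clean table."""
    return coh.average_same_day(clean_table)


@pytest.fixture(scope="session")
def contaminated_table(slopes_model):
    """Encounter table with every contamination type injected at 2%."""
    cfg = GeneratorConfig(n_children=1200, seed=5)
    return simulate_cohort(cfg, slopes_model)


@pytest.fixture(scope="session")
def built_contaminated(contaminated_table):
    """Full cleaning (attrition + averaging + plausibility) of the contaminated table."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rows, report, removed = coh.build_cohort(contaminated_table)
    return rows, report, removed


def iid_cohort_from_model(model, n_rows: int, seed: int, sex: str = "M") -> pd.DataFrame:
    """Cross-sectional Gaussian draw from a reference model.

    Ages uniform over [3, 18), height Z standard normal (truncated to the
    evaluation domain), BP ~ N(mu(age, h), sigma(age, h)) independently per
    row; used where an exchangeable, non-longitudinal sample is the right
    test bed (quantile regression, classification counting).
    """
    rng = np.random.default_rng(seed)
    age = rng.uniform(3.0, 18.0 - 1e-9, n_rows)
    hz = np.clip(rng.standard_normal(n_rows), -4.9, 4.9)
    out = {"child_id": [f"X{i:07d}" for i in range(n_rows)], "sex": sex,
           "age": age, "age10": age - 10.0, "height_z": hz,
           "calendar_year": rng.integers(2009, 2022, n_rows)}
    for bp_type in ("sbp", "dbp"):
        mu = np.asarray(model.expected_bp(sex, bp_type, age, hz))
        sd = np.asarray(model.conditional_sd(sex, bp_type, age, hz))
        out[bp_type] = mu + sd * rng.standard_normal(n_rows)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def iid_rows(slopes_model):
    return iid_cohort_from_model(slopes_model, 30_000, seed=17)
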