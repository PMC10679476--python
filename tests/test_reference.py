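"""Reference-engine behaviour: means, SDs, Z-scores, percentiles, categories."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpref.reference import (
    CoefficientSet,
    RandomEffectSpec,
    ReferenceModel,
    Stratum,
    classify,
    height_percentile_to_z,
    load_bundle,
    percentile_of_z,
    percentile_table,
    save_bundle,
    z_from_mean_sd,
    z_of_percentile,
)


class TestExpectedBP:
    def test_boys_systolic_at_age12_height90th_random_slopes(self, slopes_model):
        # published worked example: (age-10)=2, heightZ=1.28 -> 109.32 mmHg
        assert round(slopes_model.expected_bp("M", "sbp", 12, 1.28), 2) == 109.32

    def test_boys_systolic_at_age12_height90th_random_intercept(self, intercept_model):
        # direct polynomial evaluation of the constant-SD coefficient column
        assert round(intercept_model.expected_bp("M", "sbp", 12, 1.28), 2) == 109.36

    def test_intercept_only_polynomial_is_constant(self):
        coef = CoefficientSet(intercept=100.0)
        st_ = Stratum(fixed=coef, sigma=10.0)
        model = ReferenceModel({("M", "sbp"): st_})
        for age, hz in [(3, -2), (10, 0), (17.9, 4.5)]:
            assert model.expected_bp("M", "sbp", age, hz) == 100.0

    def test_out_of_domain_rejected(self, slopes_model):
        with pytest.raises(ValueError, match="age"):
            slopes_model.expected_bp("M", "sbp", 2.5, 0.0)
        with pytest.raises(ValueError, match="height"):
            slopes_model.expected_bp("M", "sbp", 10.0, 5.5)


class TestConditionalSD:
    def test_quadratic_form_reconstruction(self, slopes_model):
        """sqrt(sigma_obs^2 + v' Sigma v) recomputed by hand at v=(1,2,1.28)."""
        re = slopes_model.stratum("M", "sbp").random_effects
        s = np.array([re.sigma_intercept, re.sigma_age, re.sigma_height])
        rho = np.array([[1, re.rho_intercept_age, re.rho_intercept_height],
                        [re.rho_intercept_age, 1, re.rho_age_height],
                        [re.rho_intercept_height, re.rho_age_height, 1]])
        v = np.array([1.0, 2.0, 1.28])
        hand = np.sqrt(re.sigma_observation**2 + v @ (rho * np.outer(s, s)) @ v)
        assert slopes_model.conditional_sd("M", "sbp", 12, 1.28) == pytest.approx(hand, abs=1e-12)
        # published value, within printed-coefficient rounding
        assert abs(hand - 9.66368) < 0.01

    def test_collapses_to_scalar_when_slopes_zero(self):
        spec = RandomEffectSpec(sigma_intercept=5.0, sigma_age=0.0, sigma_height=0.0,
                                sigma_observation=8.0)
        model = ReferenceModel({("M", "sbp"): Stratum(
            fixed=CoefficientSet(intercept=100.0), random_effects=spec)})
        expected = np.sqrt(25.0 + 64.0)
        for age, hz in [(3, -2), (12, 1.28), (17, 2)]:
            assert model.conditional_sd("M", "sbp", age, hz) == pytest.approx(expected)

    def test_sd_surface_stays_near_constant_sd_value(self, slopes_model):
        """Boys-systolic SD stays in [8.5, 11] for ages 3-17, |heightZ| <= 2."""
        ages = np.linspace(3, 17, 29)
        hzs = np.linspace(-2, 2, 17)
        aa, hh = np.meshgrid(ages, hzs)
        sd = slopes_model.conditional_sd("M", "sbp", aa.ravel(), hh.ravel())
        assert sd.min() >= 8.5 and sd.max() <= 11.0

    def test_sd_never_below_residual_sd_on_domain_grid(self, slopes_model):
        for sex in ("M", "F"):
            for bp in ("sbp", "dbp"):
                re = slopes_model.stratum(sex, bp).random_effects
                ages = np.linspace(3, 17.99, 40)
                hzs = np.linspace(-5, 5, 21)
                aa, hh = np.meshgrid(ages, hzs)
                sd = slopes_model.conditional_sd(sex, bp, aa.ravel(), hh.ravel())
                assert np.all(sd >= re.sigma_observation - 1e-12)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            RandomEffectSpec(sigma_intercept=1, sigma_age=1, sigma_height=1,
                             rho_intercept_age=0.95, rho_intercept_height=0.95,
                             rho_age_height=-0.95, sigma_observation=1)


class TestZAndPercentile:
    def test_published_worked_example_constant_sd(self):
        z = z_from_mean_sd(120.0, 109.39, 9.644)
        assert round(z, 3) == 1.100
        assert round(percentile_of_z(z), 1) == 86.4

    def test_published_worked_example_random_slopes(self):
        z = z_from_mean_sd(120.0, 109.46, 9.66368)
        assert round(z, 3) == 1.091
        assert round(percentile_of_z(z), 1) == 86.2

    def test_observed_at_mean_gives_zero(self, slopes_model):
        mu = slopes_model.expected_bp("F", "dbp", 8.0, -0.5)
        assert slopes_model.z_score("F", "dbp", 8.0, -0.5, mu) == pytest.approx(0.0)

    def test_median_percentile(self):
        assert percentile_of_z(0.0) == pytest.approx(50.0)

    @settings(deadline=None, max_examples=60)
    @given(age=st.floats(3.0, 17.99), hz=st.floats(-4.5, 4.5), p=st.floats(0.5, 99.5))
    def test_percentile_round_trip(self, slopes_model, age, hz, p):
        bp = slopes_model.bp_at_percentile("M", "sbp", age, hz, p)
        z = slopes_model.z_score("M", "sbp", age, hz, bp)
        assert abs(percentile_of_z(z) - p) < 1e-9
        assert abs(z - z_of_percentile(p)) < 1e-9

    def test_percentile_monotone_in_observed_bp(self, slopes_model):
        obs = np.linspace(70, 160, 50)
        pct = slopes_model.percentile("M", "sbp", 10.0, 0.0, obs)
        assert np.all(np.diff(pct) > 0)

    def test_invalid_inputs_rejected(self, slopes_model):
        with pytest.raises(ValueError):
            slopes_model.bp_at_percentile("M", "sbp", 10, 0, 0.0)
        with pytest.raises(ValueError):
            slopes_model.bp_at_percentile("M", "sbp", 10, 0, 100.0)
        with pytest.raises(ValueError):
            z_from_mean_sd(120, 100, 0.0)
        with pytest.raises(ValueError):
            slopes_model.z_score("M", "sbp", 10, 0, -5.0)


class TestHeightConversion:
    def test_90th_percentile_rounds_to_published_value(self):
        assert round(height_percentile_to_z(90), 2) == 1.28

    def test_full_precision_used_internally(self):
        assert height_percentile_to_z(90) == pytest.approx(1.2815515655, abs=1e-9)


class TestPercentileTable:
    def test_monotone_in_bp_percentile_everywhere(self, slopes_model):
        tab = percentile_table(slopes_model, "M", "sbp")
        for _, grp in tab.groupby(["age", "height_percentile"]):
            vals = grp.sort_values("bp_percentile")["bp_mmhg"].to_numpy()
            assert np.all(np.diff(vals) > 0)

    def test_median_cell_equals_expected_bp_at_zero_height_z(self, slopes_model):
        tab = percentile_table(slopes_model, "M", "sbp")
        cell = tab[(tab.age == 12) & (tab.height_percentile == 50) & (tab.bp_percentile == 50)]
        assert cell["bp_mmhg"].iloc[0] == pytest.approx(
            slopes_model.expected_bp("M", "sbp", 12, 0.0), abs=1e-9)

    def test_height_z_column_matches_conversion(self, slopes_model):
        tab = percentile_table(slopes_model, "F", "dbp", ages=[10])
        h90 = tab[tab.height_percentile == 90]["height_z"].iloc[0]
        assert round(h90, 2) == 1.28


class TestClassification:
    def test_category_boundaries_lower_bound_inclusive(self, slopes_model):
        p95 = slopes_model.bp_at_percentile("M", "sbp", 10, 0, 95)
        assert classify(slopes_model, "M", "sbp", 10, 0, p95, "banker5") == "stage1"
        assert classify(slopes_model, "M", "sbp", 10, 0, p95 + 12.0, "banker5") == "stage2"
        assert classify(slopes_model, "M", "sbp", 10, 0, p95 - 1e-9, "banker5") == "elevated"

    def test_median_observation_is_normal_in_both_schemes(self, slopes_model):
        p50 = slopes_model.bp_at_percentile("M", "sbp", 10, 0, 50)
        for scheme in ("banker5", "aap4"):
            assert classify(slopes_model, "M", "sbp", 10, 0, p50, scheme) == "normal"

    def test_banker5_low_bucket_merged_into_aap4_normal(self, slopes_model):
        p5 = slopes_model.bp_at_percentile("M", "sbp", 10, 0, 5)
        assert classify(slopes_model, "M", "sbp", 10, 0, p5, "banker5") == "low"
        assert classify(slopes_model, "M", "sbp", 10, 0, p5, "aap4") == "normal"

    def test_category_monotone_in_observed_bp(self, slopes_model):
        order = {"low": 0, "normal": 1, "elevated": 2, "stage1": 3, "stage2": 4}
        cats = [order[classify(slopes_model, "F", "sbp", 9, 0.5, bp, "banker5")]
                for bp in np.linspace(70, 160, 60)]
        assert np.all(np.diff(cats) >= 0)

    def test_adult_absolute_scheme(self, slopes_model):
        assert classify(slopes_model, "M", "sbp", 15, 0, 118, "adult_absolute") == "normal"
        assert classify(slopes_model, "M", "sbp", 15, 0, 125, "adult_absolute") == "elevated"
        assert classify(slopes_model, "M", "sbp", 15, 0, 134, "adult_absolute") == "stage1"
        assert classify(slopes_model, "M", "sbp", 15, 0, 141, "adult_absolute") == "stage2"
        assert classify(slopes_model, "M", "dbp", 15, 0, 85, "adult_absolute") == "stage1"
        with pytest.raises(ValueError, match="ages >= 13"):
            classify(slopes_model, "M", "sbp", 10, 0, 120, "adult_absolute")

    def test_unknown_scheme_rejected(self, slopes_model):
        with pytest.raises(ValueError, match="scheme"):
            classify(slopes_model, "M", "sbp", 10, 0, 100, "who")


class TestBundleIO:
    def test_round_trip_evaluations_identical(self, slopes_model, tmp_path):
        path = tmp_path / "bundle.json"
        save_bundle(slopes_model, path)
        loaded = load_bundle(path)
        ages = np.linspace(3, 17.9, 15)
        hzs = np.linspace(-4, 4, 9)
        aa, hh = np.meshgrid(ages, hzs)
        for sex in ("M", "F"):
            for bp in ("sbp", "dbp"):
                for fn in ("expected_bp", "conditional_sd"):
                    a = getattr(slopes_model, fn)(sex, bp, aa.ravel(), hh.ravel())
                    b = getattr(loaded, fn)(sex, bp, aa.ravel(), hh.ravel())
                    np.testing.assert_allclose(a, b, rtol=0, atol=1e-12)

    def test_published_strings_survive_verbatim(self, tmp_path, slopes_model):
        path = tmp_path / "bundle.json"
        save_bundle(slopes_model, path)
        doc = json.loads(path.read_text())
        assert doc["strata"]["M:sbp"]["random_effects"]["sigma_observation"] == "7.76685"

    def test_unsupported_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"schema_version": 99, "strata": {}}))
        with pytest.raises(ValueError, match="schema_version"):
            load_bundle(path)
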