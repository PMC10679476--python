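"""Model-agreement statistics: weighted kappa, Z regressions, reclassification."""

import copy

import numpy as np
import pandas as pd
import pytest

from bpref import agreement as agr
from bpref.reference import CoefficientSet, ReferenceModel, Stratum
from tests.conftest import iid_cohort_from_model


def shifted_model(model: ReferenceModel, delta: float) -> ReferenceModel:
    """Same model with every stratum's intercept shifted by ``delta`` mmHg."""
    strata = {}
    for key, st in model.strata.items():
        fixed = CoefficientSet(intercept=st.fixed.intercept + delta, coeffs=dict(st.fixed.coeffs))
        if st.sigma is not None:
            strata[key] = Stratum(fixed=fixed, sigma=st.sigma, metadata=dict(st.metadata))
        else:
            strata[key] = Stratum(fixed=fixed, random_effects=st.random_effects,
                                  metadata=dict(st.metadata))
    return ReferenceModel(strata, name=f"{model.name}+{delta}")


class TestWeightedKappa:
    def test_identical_sequences_give_one(self):
        a = np.array([0, 1, 2, 3, 4, 2, 1, 0] * 10)
        assert agr.weighted_kappa(a, a, n_levels=5) == pytest.approx(1.0)

    def test_independent_labels_give_near_zero(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 5, 20_000)
        b = rng.integers(0, 5, 20_000)
        assert abs(agr.weighted_kappa(a, b, n_levels=5)) < 0.02

    def test_hand_expanded_two_by_two_table(self):
        """O = [[45, 5], [5, 45]]: expand the formula by hand as the oracle."""
        a = np.array([0] * 50 + [1] * 50)
        b = np.array([0] * 45 + [1] * 5 + [0] * 5 + [1] * 45)
        # w = [[0,1],[1,0]]; sum(wO) = 10; marginals 50/50 -> E offdiag 25 each
        # kappa = 1 - 10 / 50 = 0.8
        assert agr.weighted_kappa(a, b, n_levels=2) == pytest.approx(0.8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sklearn_quadratic_kappa(self, seed):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(seed)
        base = rng.integers(0, 5, 3000)
        noisy = np.clip(base + rng.integers(-1, 2, 3000), 0, 4)
        ours = agr.weighted_kappa(base, noisy, n_levels=5)
        ref = sklearn_metrics.cohen_kappa_score(base, noisy, weights="quadratic")
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_invariant_to_affine_order_preserving_relabelling(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 4, 2000)
        b = np.clip(a + rng.integers(-1, 2, 2000), 0, 3)
        k0 = agr.weighted_kappa(a, b, n_levels=4)
        k_shift = agr.weighted_kappa(a + 2, b + 2, n_levels=6)
        k_scale = agr.weighted_kappa(2 * a, 2 * b, n_levels=7)
        assert k_shift == pytest.approx(k0, abs=1e-12)
        assert k_scale == pytest.approx(k0, abs=1e-12)

    def test_degenerate_marginals_flagged_undefined(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = agr.weighted_kappa(np.zeros(10, int), np.zeros(10, int), n_levels=3)
        assert np.isnan(out)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            agr.weighted_kappa([0, 1], [0, 1, 2])


class TestCohortKappa:
    def test_model_against_itself_is_perfect(self, iid_rows, slopes_model):
        out = agr.cohort_kappa(iid_rows.iloc[:2000], slopes_model, slopes_model)
        assert out["sbp"] == 1.0 and out["dbp"] == 1.0 and out["overall"] == 1.0

    def test_interpretation_bands(self):
        assert agr.kappa_interpretation(0.9) == "excellent"
        assert agr.kappa_interpretation(0.65) == "substantial"
        assert agr.kappa_interpretation(-0.2) == "none"


class TestZvsZRegression:
    def test_identity_models(self, iid_rows, slopes_model):
        out = agr.z_vs_z_regression(iid_rows.iloc[:3000], slopes_model, slopes_model)
        for rec in out.itertuples():
            assert rec.intercept == pytest.approx(0.0, abs=1e-10)
            assert rec.slope == pytest.approx(1.0, abs=1e-10)
            assert rec.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_affine_mean_shift_recovered(self, intercept_model, slopes_model):
        """model_a = model_b with mu + 2 and the same constant SD: Z_a = Z_b - 2/sigma."""
        rows = iid_cohort_from_model(intercept_model, 4000, seed=41)
        shifted = shifted_model(intercept_model, +2.0)
        out = agr.z_vs_z_regression(rows, shifted, intercept_model)
        for rec in out.itertuples():
            sigma = intercept_model.stratum("M", rec.bp_type).sigma
            assert rec.slope == pytest.approx(1.0, abs=1e-9)
            assert rec.intercept == pytest.approx(-2.0 / sigma, abs=1e-9)

    def test_unrelated_noise_gives_near_zero_r2(self, intercept_model):
        rng = np.random.default_rng(6)
        rows = iid_cohort_from_model(intercept_model, 4000, seed=43)
        noise_rows = rows.copy()
        # independent redraw of BP destroys the Z-Z relationship
        for bp in ("sbp", "dbp"):
            noise_rows[bp] = rng.permutation(rows[bp].to_numpy())
        out_self = agr.z_vs_z_regression(rows, intercept_model, intercept_model)
        rows_mixed = rows.copy()
        rows_mixed["sbp_b"] = noise_rows["sbp"]
        # regress Z of permuted data on Z of original: no association
        za = agr._z_by_type(noise_rows, intercept_model)
        zb = agr._z_by_type(rows, intercept_model)
        r = np.corrcoef(za["sbp"], zb["sbp"])[0, 1]
        assert abs(r) < 0.05
        assert out_self.r_squared.min() > 0.999


class TestReclassification:
    def test_identical_models_reclassify_nothing(self, iid_rows, slopes_model):
        out = agr.reclassification(iid_rows.iloc[:5000], slopes_model, slopes_model)
        assert (out.fraction_reclassified_down == 0.0).all()

    def test_counting_oracle_on_shifted_comparator(self, intercept_model):
        rows = iid_cohort_from_model(intercept_model, 30_000, seed=47)
        primary = shifted_model(intercept_model, +3.0)   # 95th curve 3 mmHg above
        out = agr.reclassification(rows, primary, intercept_model)
        # brute-force count for the overall systolic band
        sub = rows[(rows.age >= 3) & (rows.age < 13)]
        thr_b = np.asarray(intercept_model.bp_at_percentile(
            "M", "sbp", sub.age.to_numpy(), sub.height_z.to_numpy(), 95))
        obs = sub.sbp.to_numpy()
        above = obs >= thr_b
        frac_hand = float((obs[above] < thr_b[above] + 3.0).mean())
        got = out[(out.bp_type == "sbp") & (out.band == "overall")]
        assert got.fraction_reclassified_down.iloc[0] == pytest.approx(frac_hand, abs=1e-12)
        assert got.n_above_comparator.iloc[0] == int(above.sum())

    def test_fraction_monotone_in_threshold_gap(self, intercept_model):
        rows = iid_cohort_from_model(intercept_model, 20_000, seed=53)
        fracs = []
        for delta in (1.0, 3.0, 6.0):
            out = agr.reclassification(rows, shifted_model(intercept_model, delta),
                                       intercept_model)
            fracs.append(out[(out.bp_type == "sbp") & (out.band == "overall")]
                         .fraction_reclassified_down.iloc[0])
        assert fracs[0] < fracs[1] < fracs[2]

    def test_invalid_threshold_and_bands_rejected(self, iid_rows, slopes_model):
        with pytest.raises(ValueError, match="threshold"):
            agr.reclassification(iid_rows, slopes_model, slopes_model, threshold_pct=100.0)
        with pytest.raises(ValueError, match="partition"):
            agr.reclassification(iid_rows, slopes_model, slopes_model,
                                 age_bands=((3, 6), (7, 13)))


class TestCalendarDrift:
    def test_stationary_cohort_slope_consistent_with_zero(self, clean_rows, slopes_model):
        out = agr.calendar_drift(clean_rows, slopes_model)
        for rec in out.itertuples():
            assert abs(rec.slope_per_year) < 3 * rec.slope_se

    def test_injected_trend_recovered(self, clean_rows, slopes_model):
        rows = clean_rows.copy()
        sd = np.concatenate([
            np.asarray(slopes_model.conditional_sd(sex, "sbp",
                                                   rows.loc[rows.sex == sex, "age"].to_numpy(),
                                                   rows.loc[rows.sex == sex, "height_z"].to_numpy()))
            for sex in ("M", "F")])
        order = np.concatenate([rows.index[rows.sex == sex] for sex in ("M", "F")])
        sd_aligned = pd.Series(sd, index=order).sort_index().to_numpy()
        rows["sbp"] = rows["sbp"] + 0.03 * sd_aligned * (rows["calendar_year"] - 2015)
        out = agr.calendar_drift(rows, slopes_model)
        sbp = out[out.bp_type == "sbp"].iloc[0]
        assert sbp.slope_per_year == pytest.approx(0.03, abs=3 * sbp.slope_se)
        assert sbp.p_value < 0.001

    def test_year_permutation_kills_trend(self, clean_rows, slopes_model):
        rows = clean_rows.copy()
        rng = np.random.default_rng(59)
        rows["calendar_year"] = rng.permutation(rows["calendar_year"].to_numpy())
        out = agr.calendar_drift(rows, slopes_model)
        for rec in out.itertuples():
            assert abs(rec.slope_per_year) < 3.5 * rec.slope_se

    def test_single_year_rejected(self, clean_rows, slopes_model):
        rows = clean_rows.copy()
        rows["calendar_year"] = 2015
        with pytest.raises(ValueError, match="calendar"):
            agr.calendar_drift(rows, slopes_model)


class TestSubgroupECDF:
    def test_single_group_equals_pooled(self, clean_rows, slopes_model):
        rows = clean_rows.copy()
        rows["site"] = "only_site"
        out = agr.subgroup_ecdf(rows, slopes_model, "site")
        assert set(out["site"]) == {"only_site"}
        sbp = out[out.bp_type == "sbp"]
        z = agr._z_by_type(rows, slopes_model)["sbp"].to_numpy()
        at_zero = sbp[sbp.z == 0.0].ecdf.iloc[0]
        assert at_zero == pytest.approx((z <= 0).mean(), abs=1e-12)

    def test_identically_distributed_groups_have_small_ks_distance(self, clean_rows,
                                                                    slopes_model):
        out = agr.subgroup_ecdf(clean_rows, slopes_model, "sex")
        sbp = out[out.bp_type == "sbp"]
        m = sbp[sbp.sex == "M"].sort_values("z").ecdf.to_numpy()
        f = sbp[sbp.sex == "F"].sort_values("z").ecdf.to_numpy()
        ks = np.max(np.abs(m - f))
        n_m = (clean_rows.sex == "M").sum()
        n_f = (clean_rows.sex == "F").sum()
        crit = 1.63 * np.sqrt((n_m + n_f) / (n_m * n_f))  # alpha = 0.01
        assert ks < crit

    def test_missing_grouping_column_rejected(self, clean_rows, slopes_model):
        with pytest.raises(ValueError, match="grouping"):
            agr.subgroup_ecdf(clean_rows, slopes_model, "clinic_color")
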