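"""Agreement diagnostics between two BP reference models on a cohort.

Covers the comparison battery used when a newly derived reference is set
against an established one: squared-weight Cohen's kappa over ordinal BP
categories, Z-vs-Z ordinary least squares, reclassification fractions at a
percentile threshold, calendar-year drift of Z-scores, and per-subgroup
empirical CDFs of Z.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .reference import BANKER5_LABELS, ReferenceModel, category_codes, classify

BP_TYPES = ("sbp", "dbp")

#: Interpretation bands for kappa (slight/fair/moderate/substantial/excellent).
KAPPA_BANDS = ((0.0, "none"), (0.01, "slight"), (0.21, "fair"), (0.41, "moderate"),
               (0.61, "substantial"), (0.81, "excellent"))


def kappa_interpretation(kappa: float) -> str:
    label = "none"
    for lo, name in KAPPA_BANDS:
        if kappa >= lo:
            label = name
    return label


def weighted_kappa(categories_a, categories_b, n_levels: int | None = None) -> float:
    """Cohen's kappa with squared weights w_ij = (i - j)^2.

    ``kappa_w = 1 - sum(w * O) / sum(w * E)`` with observed contingency O and
    expected E from the product of the marginals.  Inputs are integer ordinal
    codes over the same ``n_levels`` levels.  Degenerate marginals (both
    raters stuck on one category) leave chance agreement undefined; NaN is
    returned with a warning.
    """
    a = np.asarray(categories_a, dtype=int)
    b = np.asarray(categories_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("category sequences must be equal-length 1-D arrays")
    if len(a) == 0:
        raise ValueError("empty category sequences")
    k = int(n_levels) if n_levels is not None else int(max(a.max(), b.max())) + 1
    if a.min() < 0 or b.min() < 0 or a.max() >= k or b.max() >= k:
        raise ValueError("category codes out of range")
    obs = np.zeros((k, k))
    np.add.at(obs, (a, b), 1.0)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    i = np.arange(k)
    w = (i[:, None] - i[None, :]) ** 2
    denom = float((w * expected).sum())
    if denom == 0.0:
        warnings.warn("weighted kappa undefined: degenerate single-category marginals")
        return float("nan")
    return 1.0 - float((w * obs).sum()) / denom


def _z_by_type(rows: pd.DataFrame, model: ReferenceModel) -> pd.DataFrame:
    out = {}
    for bp_type in BP_TYPES:
        z = np.empty(len(rows))
        for sex in ("M", "F"):
            m = (rows["sex"] == sex).to_numpy()
            if m.any():
                sub = rows[m]
                z[m] = model.z_score(sex, bp_type, sub["age"].to_numpy(),
                                     sub["height_z"].to_numpy(), sub[bp_type].to_numpy())
        out[bp_type] = z
    return pd.DataFrame(out, index=rows.index)


def categorize_cohort(rows: pd.DataFrame, model: ReferenceModel,
                      scheme: str = "banker5") -> pd.DataFrame:
    """Ordinal category codes per row and BP type under a model."""
    out = {}
    for bp_type in BP_TYPES:
        labels = [
            classify(model, sex, bp_type, age, hz, obs, scheme)
            for sex, age, hz, obs in zip(rows["sex"], rows["age"], rows["height_z"], rows[bp_type])
        ]
        out[bp_type] = category_codes(labels, scheme)
    return pd.DataFrame(out, index=rows.index)


def cohort_kappa(rows: pd.DataFrame, model_a: ReferenceModel, model_b: ReferenceModel,
                 scheme: str = "banker5") -> dict:
    """Squared-weight kappa per BP type plus overall.

    "Overall" pools the systolic and diastolic classifications as separate
    observations.
    """
    cat_a = categorize_cohort(rows, model_a, scheme)
    cat_b = categorize_cohort(rows, model_b, scheme)
    k = len(BANKER5_LABELS) if scheme == "banker5" else len(BANKER5_LABELS) - 1
    out = {}
    for bp_type in BP_TYPES:
        out[bp_type] = weighted_kappa(cat_a[bp_type], cat_b[bp_type], n_levels=k)
    pooled_a = np.concatenate([cat_a[t] for t in BP_TYPES])
    pooled_b = np.concatenate([cat_b[t] for t in BP_TYPES])
    out["overall"] = weighted_kappa(pooled_a, pooled_b, n_levels=k)
    return out


def z_vs_z_regression(rows: pd.DataFrame, model_a: ReferenceModel,
                      model_b: ReferenceModel) -> pd.DataFrame:
    """OLS of model_a's Z on model_b's Z: Z_a = intercept + slope * Z_b."""
    za = _z_by_type(rows, model_a)
    zb = _z_by_type(rows, model_b)
    recs = []
    for bp_type in BP_TYPES:
        res = sm.OLS(za[bp_type].to_numpy(), sm.add_constant(zb[bp_type].to_numpy())).fit()
        recs.append({"bp_type": bp_type, "intercept": float(res.params[0]),
                     "slope": float(res.params[1]), "r_squared": float(res.rsquared)})
    return pd.DataFrame(recs)


DEFAULT_AGE_BANDS = ((3.0, 6.0), (6.0, 13.0))


def reclassification(rows: pd.DataFrame, model_a: ReferenceModel, model_b: ReferenceModel,
                     threshold_pct: float = 95.0, age_bands=DEFAULT_AGE_BANDS) -> pd.DataFrame:
    """Among rows at/above model_b's threshold percentile, the fraction that
    fall below it under model_a, per BP type and age band over [3, 13)."""
    if not 0.0 < threshold_pct < 100.0:
        raise ValueError("threshold percentile must lie strictly between 0 and 100")
    bands = sorted(tuple(map(float, b)) for b in age_bands)
    if bands[0][0] != 3.0 or bands[-1][1] != 13.0 or any(
            bands[i][1] != bands[i + 1][0] for i in range(len(bands) - 1)):
        raise ValueError("age bands must partition [3, 13)")
    recs = []
    for bp_type in BP_TYPES:
        for lo, hi in bands + [(3.0, 13.0)]:
            sub = rows[(rows["age"] >= lo) & (rows["age"] < hi)]
            if len(sub) == 0:
                continue
            thr_b = np.concatenate([
                np.atleast_1d(model_b.bp_at_percentile(sex, bp_type,
                                                       sub.loc[sub["sex"] == sex, "age"].to_numpy(),
                                                       sub.loc[sub["sex"] == sex, "height_z"].to_numpy(),
                                                       threshold_pct))
                for sex in ("M", "F") if (sub["sex"] == sex).any()
            ])
            thr_a = np.concatenate([
                np.atleast_1d(model_a.bp_at_percentile(sex, bp_type,
                                                       sub.loc[sub["sex"] == sex, "age"].to_numpy(),
                                                       sub.loc[sub["sex"] == sex, "height_z"].to_numpy(),
                                                       threshold_pct))
                for sex in ("M", "F") if (sub["sex"] == sex).any()
            ])
            obs = np.concatenate([
                sub.loc[sub["sex"] == sex, bp_type].to_numpy()
                for sex in ("M", "F") if (sub["sex"] == sex).any()
            ])
            above_b = obs >= thr_b
            n_above = int(above_b.sum())
            if n_above == 0:
                continue  # empty stratum reported as absent, not zero
            frac = float((obs[above_b] < thr_a[above_b]).mean())
            recs.append({"bp_type": bp_type, "age_lo": lo, "age_hi": hi,
                         "band": "overall" if (lo, hi) == (3.0, 13.0) else f"[{lo:g},{hi:g})",
                         "n_above_comparator": n_above,
                         "fraction_reclassified_down": frac})
    return pd.DataFrame(recs)


def calendar_drift(rows: pd.DataFrame, model: ReferenceModel) -> pd.DataFrame:
    """OLS slope of BP Z-score on calendar year, per BP type (Z units/year).

    Standard errors are cluster-robust by child when a ``child_id`` column is
    present (repeat measurements of a child share its random effects, so
    i.i.d. standard errors would overstate precision).
    """
    if rows["calendar_year"].nunique() < 2:
        raise ValueError("calendar drift needs at least two distinct calendar years")
    z = _z_by_type(rows, model)
    year = rows["calendar_year"].to_numpy(dtype=float)
    fit_kw = {}
    if "child_id" in rows.columns:
        fit_kw = {"cov_type": "cluster", "cov_kwds": {"groups": rows["child_id"].to_numpy()}}
    recs = []
    for bp_type in BP_TYPES:
        res = sm.OLS(z[bp_type].to_numpy(), sm.add_constant(year)).fit(**fit_kw)
        recs.append({"bp_type": bp_type, "slope_per_year": float(res.params[1]),
                     "slope_se": float(res.bse[1]), "p_value": float(res.pvalues[1])})
    return pd.DataFrame(recs)


DEFAULT_Z_GRID = np.round(np.arange(-4.0, 4.0001, 0.05), 4)


def subgroup_ecdf(rows: pd.DataFrame, model: ReferenceModel, grouping: str,
                  z_grid=DEFAULT_Z_GRID) -> pd.DataFrame:
    """Empirical CDF of Z on a fixed grid, per subgroup and BP type."""
    if grouping not in rows.columns:
        raise ValueError(f"grouping column {grouping!r} not present")
    z = _z_by_type(rows, model)
    recs = []
    for value, idx in rows.groupby(grouping).groups.items():
        if len(idx) == 0:
            warnings.warn(f"empty subgroup {value!r} dropped")
            continue
        for bp_type in BP_TYPES:
            zs = np.sort(z.loc[idx, bp_type].to_numpy())
            ecdf = np.searchsorted(zs, z_grid, side="right") / len(zs)
            for g, e in zip(z_grid, ecdf):
                recs.append({grouping: value, "bp_type": bp_type, "z": float(g), "ecdf": float(e)})
    return pd.DataFrame(recs)
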