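"""Quantile-regression centiles as a consistency check on the mixed model.

Each conditional quantile tau is fitted directly by minimising the pinball
(tilted absolute) loss over the same polynomial design as the mixed model
(full eight terms, no AIC pruning), separately by sex and BP type.  Under
the mixed model's Gaussian assumption the tau-quantile curve should track
``mu(age, h) + z_tau * sigma(age, h)``; :func:`compare_to_mixed` quantifies
the discrepancy on an age x height grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.regression.quantile_regression import QuantReg

from ._design import POLY_TERMS, check_stratum, design_matrix
from .reference import CoefficientSet, ReferenceModel

DEFAULT_TAUS = (0.50, 0.75, 0.90, 0.95)
MIN_ROWS = 500

#: default comparison grid: ages 3-17, height Z at the 5th..95th percentiles
GRID_AGES = np.arange(3.0, 17.01, 0.5)
GRID_HEIGHT_Z = np.array([-1.6449, -1.2816, -0.6745, 0.0, 0.6745, 1.2816, 1.6449])


@dataclass(frozen=True)
class QuantileFit:
    sex: str
    bp_type: str
    tau: float
    coefficients: CoefficientSet
    terms: tuple[str, ...]
    n_rows: int

    def predict(self, age, height_z):
        return self.coefficients.evaluate(np.asarray(age, dtype=float) - 10.0, height_z)


def pinball_loss(y, yhat, tau: float) -> float:
    """Mean tilted absolute loss; what quantile regression minimises."""
    r = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    return float(np.mean(np.where(r >= 0, tau * r, (tau - 1.0) * r)))


def fit_quantile(rows: pd.DataFrame, sex: str, bp_type: str, tau: float,
                 terms=POLY_TERMS) -> QuantileFit:
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    sex, bp_type = check_stratum(sex, bp_type)
    sub = rows[rows["sex"] == sex]
    if len(sub) < MIN_ROWS:
        raise ValueError(f"need at least {MIN_ROWS} rows for quantile regression; got {len(sub)}")
    a10 = sub["age10"].to_numpy(dtype=float) if "age10" in sub else sub["age"].to_numpy(dtype=float) - 10.0
    X = design_matrix(a10, sub["height_z"].to_numpy(dtype=float), terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate (rank-deficient) quantile design")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = QuantReg(sub[bp_type].to_numpy(dtype=float), X).fit(q=tau, max_iter=2000)
    coef = CoefficientSet(intercept=float(res.params[0]),
                          coeffs={t: float(b) for t, b in zip(terms, res.params[1:])})
    return QuantileFit(sex=sex, bp_type=bp_type, tau=tau, coefficients=coef,
                       terms=tuple(terms), n_rows=len(sub))


def fit_quantile_set(rows: pd.DataFrame, sex: str, bp_type: str,
                     taus=DEFAULT_TAUS, terms=POLY_TERMS) -> list[QuantileFit]:
    return [fit_quantile(rows, sex, bp_type, tau, terms) for tau in sorted(taus)]


def crossing_fraction(fits: list[QuantileFit], ages=GRID_AGES, heights=GRID_HEIGHT_Z) -> float:
    """Fraction of grid cells where curves for tau1 < tau2 cross (flagged, not repaired)."""
    fits = sorted(fits, key=lambda f: f.tau)
    aa, hh = np.meshgrid(ages, heights, indexing="ij")
    curves = np.stack([f.predict(aa.ravel(), hh.ravel()) for f in fits])
    return float(np.mean(np.any(np.diff(curves, axis=0) < 0, axis=0)))


def compare_to_mixed(fits: list[QuantileFit], model: ReferenceModel,
                     ages=GRID_AGES, heights=GRID_HEIGHT_Z) -> pd.DataFrame:
    """Per-tau max/mean absolute gap (mmHg) between quantile-regression curves
    and the mixed model's Gaussian centiles on the evaluation grid."""
    aa, hh = np.meshgrid(ages, heights, indexing="ij")
    recs = []
    for f in fits:
        qr = f.predict(aa.ravel(), hh.ravel())
        mu = model.expected_bp(f.sex, f.bp_type, aa.ravel(), hh.ravel())
        sd = model.conditional_sd(f.sex, f.bp_type, aa.ravel(), hh.ravel())
        mm = mu + norm.ppf(f.tau) * sd
        diff = np.abs(qr - mm)
        recs.append({"sex": f.sex, "bp_type": f.bp_type, "tau": f.tau,
                     "max_abs_diff": float(diff.max()),
                     "mean_abs_diff": float(diff.mean())})
    return pd.DataFrame(recs)
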