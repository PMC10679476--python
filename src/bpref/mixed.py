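"""Sex- and BP-type-stratified mixed-effects polynomial models.

Two forms are fitted by maximum likelihood (not REML, so AIC and
likelihood-ratio comparisons across random-effect structures are valid):

* random intercept — a per-child intercept plus i.i.d. residual; reported
  with the pooled total SD ``sqrt(sigma_int^2 + sigma_obs^2)`` and the ICC
  ``sigma_int^2 / (sigma_int^2 + sigma_obs^2)``;
* random slopes — per-child random intercept and random coefficients on
  (age - 10) and height Z with an unstructured 3x3 covariance, the form
  behind the age/height-dependent conditional SD.

Backward AIC elimination over the eight polynomial terms (:func:`prune_by_aic`)
never drops linear age or linear height, and permits non-hierarchical gaps
(e.g. keeping heightZ^4 without heightZ^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from ._design import POLY_TERMS, PROTECTED_TERMS, check_stratum, design_matrix
from .reference import CoefficientSet, RandomEffectSpec, ReferenceModel, Stratum

MIN_CHILDREN = 50
_OPTIMIZERS = ("lbfgs", "bfgs", "cg")


@dataclass
class FitSummary:
    log_likelihood: float
    aic: float
    n_children: int
    n_rows: int
    converged: bool
    r2_train: float
    r2_test: float | None = None
    icc: float | None = None
    #: fixed-effect 95% confidence intervals, index = ["intercept", terms...]
    conf_int: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)


@dataclass
class MixedFit:
    """A fitted stratum model (either variance form)."""

    sex: str
    bp_type: str
    terms: tuple[str, ...]
    coefficients: CoefficientSet
    summary: FitSummary
    sigma_total: float | None = None          # random-intercept form
    sigma_intercept: float | None = None
    sigma_observation: float | None = None
    random_effects: RandomEffectSpec | None = None  # random-slopes form

    @property
    def form(self) -> str:
        return "random_intercept" if self.random_effects is None else "random_slopes"

    def to_stratum(self) -> Stratum:
        meta = {"form": self.form, "n_children": self.summary.n_children,
                "n_rows": self.summary.n_rows, "converged": self.summary.converged}
        if self.summary.icc is not None:
            meta["icc"] = self.summary.icc
        if self.form == "random_intercept":
            return Stratum(fixed=self.coefficients, sigma=self.sigma_total, metadata=meta)
        return Stratum(fixed=self.coefficients, random_effects=self.random_effects, metadata=meta)


def split_train_test(rows: pd.DataFrame, fraction: float = 0.7, seed: int = 0):
    """Split by child (all rows of a child land on one side)."""
    if len(rows) == 0:
        raise ValueError("cannot split an empty table")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    children = np.sort(rows["child_id"].unique())
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(children))
    n_train = int(round(fraction * len(children)))
    train_ids = set(children[perm[:n_train]])
    mask = rows["child_id"].isin(train_ids)
    return rows[mask].reset_index(drop=True), rows[~mask].reset_index(drop=True)


def _prepare(rows: pd.DataFrame, sex: str, bp_type: str, terms):
    sex, bp_type = check_stratum(sex, bp_type)
    sub = rows[rows["sex"] == sex]
    n_children = sub["child_id"].nunique()
    if n_children < MIN_CHILDREN:
        raise ValueError(
            f"need at least {MIN_CHILDREN} children to fit stratum ({sex}, {bp_type}); got {n_children}")
    y = sub[bp_type].to_numpy(dtype=float)
    a10 = sub["age10"].to_numpy(dtype=float) if "age10" in sub else sub["age"].to_numpy(dtype=float) - 10.0
    hz = sub["height_z"].to_numpy(dtype=float)
    X = design_matrix(a10, hz, terms)
    return sex, bp_type, sub, y, a10, hz, X


def _fixed_r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def _test_r2(coef: CoefficientSet, test: pd.DataFrame | None, sex, bp_type):
    if test is None:
        return None
    sub = test[test["sex"] == sex]
    if len(sub) == 0:
        return None
    a10 = sub["age10"].to_numpy(dtype=float) if "age10" in sub else sub["age"].to_numpy(dtype=float) - 10.0
    yhat = coef.evaluate(a10, sub["height_z"].to_numpy(dtype=float))
    return _fixed_r2(sub[bp_type].to_numpy(dtype=float), yhat)


def _start_params(y, X, q):
    """Warm start: OLS fixed effects plus a modest random-effect covariance.

    Greatly improves convergence speed and reliability of the profiled-ML
    optimisation relative to statsmodels' default identity start.
    """
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    # variance ratios relative to the residual scale
    diag = [0.35, 0.005, 0.02][:q]
    return MixedLMParams.from_components(fe_params=beta, cov_re=np.diag(diag))


def _fit_mixedlm(y, X, groups, exog_re):
    """ML fit with an optimizer fallback chain; returns (result, converged)."""
    last_exc = None
    start = _start_params(y, X, exog_re.shape[1])
    for method, sp in [(m, s) for s in (start, None) for m in _OPTIMIZERS]:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = MixedLM(y, X, groups=groups, exog_re=exog_re).fit(
                    reml=False, method=method, maxiter=500, start_params=sp)
            if res.converged:
                return res, True
            if last_exc is None or not hasattr(last_exc, "converged"):
                last_exc = res
        except (np.linalg.LinAlgError, ValueError) as exc:  # singular covariance etc.
            if last_exc is None:
                last_exc = exc
    if hasattr(last_exc, "converged"):
        warnings.warn("mixed-model fit did not converge; estimates are flagged")
        return last_exc, False
    raise RuntimeError(f"mixed-model fit failed: {last_exc}")


def _conf_int(res, names):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ci = res.conf_int()
    ci = np.asarray(ci)[: len(names)]
    return pd.DataFrame(ci, index=names, columns=["lower", "upper"])


def fit_random_intercept(rows: pd.DataFrame, sex: str, bp_type: str,
                         terms=POLY_TERMS, test: pd.DataFrame | None = None) -> MixedFit:
    """Constant-SD mixed model: fixed polynomial + per-child intercept."""
    sex, bp_type, sub, y, a10, hz, X = _prepare(rows, sex, bp_type, terms)
    groups = sub["child_id"].to_numpy()
    res, converged = _fit_mixedlm(y, X, groups, exog_re=np.ones((len(y), 1)))
    fe = np.asarray(res.fe_params)
    coef = CoefficientSet(intercept=float(fe[0]),
                          coeffs={t: float(b) for t, b in zip(terms, fe[1:])})
    var_int = float(res.cov_re[0, 0]) if np.ndim(res.cov_re) else float(res.cov_re)
    var_obs = float(res.scale)
    summary = FitSummary(
        log_likelihood=float(res.llf), aic=float(res.aic),
        n_children=sub["child_id"].nunique(), n_rows=len(sub), converged=converged,
        r2_train=_fixed_r2(y, coef.evaluate(a10, hz)),
        r2_test=_test_r2(coef, test, sex, bp_type),
        icc=var_int / (var_int + var_obs),
        conf_int=_conf_int(res, ["intercept", *terms]),
    )
    return MixedFit(sex=sex, bp_type=bp_type, terms=tuple(terms), coefficients=coef,
                    summary=summary, sigma_total=float(np.sqrt(var_int + var_obs)),
                    sigma_intercept=float(np.sqrt(var_int)),
                    sigma_observation=float(np.sqrt(var_obs)))


def fit_random_slopes(rows: pd.DataFrame, sex: str, bp_type: str,
                      terms=POLY_TERMS, test: pd.DataFrame | None = None) -> MixedFit:
    """Random intercept + random (age-10) and height-Z slopes, full covariance."""
    sex, bp_type, sub, y, a10, hz, X = _prepare(rows, sex, bp_type, terms)
    per_child = sub.groupby("child_id").size()
    if (per_child >= 2).sum() == 0:
        raise ValueError("random slopes are not identifiable: no child has two or more rows")
    groups = sub["child_id"].to_numpy()
    exog_re = np.column_stack([np.ones(len(y)), a10, hz])
    res, converged = _fit_mixedlm(y, X, groups, exog_re=exog_re)
    fe = np.asarray(res.fe_params)
    coef = CoefficientSet(intercept=float(fe[0]),
                          coeffs={t: float(b) for t, b in zip(terms, fe[1:])})
    cov = np.asarray(res.cov_re, dtype=float)
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.outer(sd, sd)
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    spec = RandomEffectSpec(
        sigma_intercept=float(sd[0]), sigma_age=float(sd[1]), sigma_height=float(sd[2]),
        rho_intercept_age=float(corr[0, 1]), rho_intercept_height=float(corr[0, 2]),
        rho_age_height=float(corr[1, 2]), sigma_observation=float(np.sqrt(res.scale)))
    summary = FitSummary(
        log_likelihood=float(res.llf), aic=float(res.aic),
        n_children=sub["child_id"].nunique(), n_rows=len(sub), converged=converged,
        r2_train=_fixed_r2(y, coef.evaluate(a10, hz)),
        r2_test=_test_r2(coef, test, sex, bp_type),
        conf_int=_conf_int(res, ["intercept", *terms]),
    )
    return MixedFit(sex=sex, bp_type=bp_type, terms=tuple(terms), coefficients=coef,
                    summary=summary, random_effects=spec,
                    sigma_observation=spec.sigma_observation)


def icc(sigma_intercept: float, sigma_observation: float) -> float:
    """Intraclass correlation of the random-intercept model."""
    v = sigma_intercept**2
    return v / (v + sigma_observation**2) if v + sigma_observation**2 > 0 else 0.0


def random_effect_lrt_chain(rows: pd.DataFrame, sex: str, bp_type: str,
                            terms=POLY_TERMS) -> pd.DataFrame:
    """Likelihood-ratio chain: intercept-only -> +age slope -> +height slope.

    Each step adds random-effect (co)variance parameters; naive chi-square
    reference distributions are used (boundary effects make them
    conservative), alongside the AICs.
    """
    from scipy.stats import chi2

    sex, bp_type, sub, y, a10, hz, X = _prepare(rows, sex, bp_type, terms)
    groups = sub["child_id"].to_numpy()
    designs = {
        "intercept_only": np.ones((len(y), 1)),
        "plus_age_slope": np.column_stack([np.ones(len(y)), a10]),
        "plus_height_slope": np.column_stack([np.ones(len(y)), a10, hz]),
    }
    recs = []
    prev_llf = None
    prev_k = None
    for name, exog_re in designs.items():
        res, converged = _fit_mixedlm(y, X, groups, exog_re=exog_re)
        q = exog_re.shape[1]
        k = X.shape[1] + q * (q + 1) // 2 + 1
        llf = float(res.llf)
        lrt = p = None
        if prev_llf is not None:
            lrt = 2.0 * (llf - prev_llf)
            p = float(chi2.sf(lrt, df=k - prev_k))
        recs.append({"model": name, "loglik": llf, "aic": float(res.aic),
                     "n_params": k, "lrt_vs_previous": lrt, "p_value": p,
                     "converged": converged})
        prev_llf, prev_k = llf, k
    return pd.DataFrame(recs)


def prune_by_aic(rows: pd.DataFrame, sex: str, bp_type: str, fit_fn=fit_random_intercept,
                 terms=POLY_TERMS, test: pd.DataFrame | None = None):
    """Greedy backward elimination over the polynomial terms by AIC.

    At each round the candidate drop with the lowest AIC is taken if it
    improves on the current AIC; linear age and linear height are never
    dropped.  Returns ``(fit, history)`` where history lists
    ``(dropped_term, aic_after)``.
    """
    terms = list(terms)
    current = fit_fn(rows, sex, bp_type, terms=tuple(terms), test=test)
    history: list[tuple[str, float]] = []
    while True:
        candidates = [t for t in terms if t not in PROTECTED_TERMS]
        best = None
        for t in candidates:
            trial_terms = tuple(x for x in terms if x != t)
            trial = fit_fn(rows, sex, bp_type, terms=trial_terms, test=test)
            if best is None or trial.summary.aic < best[1].summary.aic:
                best = (t, trial)
        if best is None or best[1].summary.aic >= current.summary.aic:
            return current, history
        terms.remove(best[0])
        current = best[1]
        history.append((best[0], current.summary.aic))


def to_reference_model(fits: dict, name: str = "fitted", version: str = "") -> ReferenceModel:
    """Assemble fitted strata into an evaluable ReferenceModel."""
    strata = {check_stratum(*key): fit.to_stratum() for key, fit in fits.items()}
    return ReferenceModel(strata, name=name, version=version)


def fit_all_strata(train: pd.DataFrame, form: str = "random_slopes",
                   terms=POLY_TERMS, test: pd.DataFrame | None = None) -> dict:
    """Convenience: fit every sex x BP-type stratum with one form."""
    fit_fn = {"random_intercept": fit_random_intercept, "random_slopes": fit_random_slopes}[form]
    return {(sex, bp): fit_fn(train, sex, bp, terms=terms, test=test)
            for sex in ("M", "F") for bp in ("sbp", "dbp")}
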