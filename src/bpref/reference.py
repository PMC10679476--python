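"""Reference-model engine: expected BP, conditional SD, Z-scores, percentiles.

A :class:`ReferenceModel` bundles, for each sex x BP-type stratum, a fixed
polynomial in centred age (``age - 10``) and height Z-score together with a
variance description.  Two variance forms are supported:

* random-intercept form — a single total SD ``sigma`` (between-child
  intercept variance plus measurement noise pooled), constant over the
  covariate domain;
* random-slopes form — a full 3x3 random-effect covariance over
  (intercept, age-10 slope, height-Z slope) plus a residual SD, giving a
  conditional SD that varies with age and height:

  ``sigma(age, h) = sqrt(sigma_obs**2 + v' Sigma v)``, ``v = (1, age-10, h)``.

A child's BP Z-score is ``(observed - mu) / sigma`` at their age, sex and
height Z, and the percentile is the standard-normal CDF of the Z.  Two
read-only bundles transcribed from a large EHR-derived reference (one per
variance form) ship with the package, see :func:`load_bundled_model`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.stats import norm

from ._design import BP_TYPES, POLY_TERMS, SEXES, check_stratum, term_values

AGE_DOMAIN = (3.0, 18.0)
HEIGHT_Z_DOMAIN = (-5.0, 5.0)

#: Ordinal category labels, most lenient to most severe.
BANKER5_LABELS = ("low", "normal", "elevated", "stage1", "stage2")
AAP4_LABELS = ("normal", "elevated", "stage1", "stage2")

# Fixed adult-style cutoffs (mmHg) applied at ages >= 13: the category is the
# highest whose lower bound the observed BP reaches.
ADULT_CUTOFFS = {"sbp": (120.0, 130.0, 140.0), "dbp": (80.0, 80.0, 90.0)}


@dataclass(frozen=True)
class CoefficientSet:
    """Fixed-effect polynomial: intercept + sum over included terms.

    ``coeffs`` maps canonical term names (``age1``..``age4``,
    ``height1``..``height4``) to coefficients; terms absent from the mapping
    are exactly zero (pruned).
    """

    intercept: float
    coeffs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        bad = set(self.coeffs) - set(POLY_TERMS)
        if bad:
            raise ValueError(f"unknown polynomial terms: {sorted(bad)}")
        if not 40.0 <= self.intercept <= 160.0:
            raise ValueError(f"intercept {self.intercept} outside plausible BP range [40, 160]")

    @property
    def included_terms(self) -> tuple[str, ...]:
        return tuple(t for t in POLY_TERMS if t in self.coeffs)

    def coefficient(self, term: str) -> float:
        return float(self.coeffs.get(term, 0.0))

    def evaluate(self, age10, height_z):
        out = np.full(np.broadcast(np.asarray(age10), np.asarray(height_z)).shape, self.intercept, dtype=float)
        for term, beta in self.coeffs.items():
            out = out + beta * term_values(term, age10, height_z)
        return out if out.shape else float(out)


@dataclass(frozen=True)
class RandomEffectSpec:
    """Random-effect SDs/correlations over (intercept, age-10, height-Z) plus residual SD."""

    sigma_intercept: float
    sigma_age: float
    sigma_height: float
    rho_intercept_age: float = 0.0
    rho_intercept_height: float = 0.0
    rho_age_height: float = 0.0
    sigma_observation: float = 0.0

    def __post_init__(self):
        for name in ("sigma_intercept", "sigma_age", "sigma_height", "sigma_observation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("rho_intercept_age", "rho_intercept_height", "rho_age_height"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"{name} must lie in [-1, 1]")
        # PSD check: eigenvalues of the correlation matrix (tiny negative
        # values from printed rounding are tolerated).
        if np.linalg.eigvalsh(self.covariance()).min() < -1e-8:
            raise ValueError("random-effect covariance is not positive semi-definite")

    def covariance(self) -> np.ndarray:
        """3x3 covariance Sigma_ij = rho_ij * sigma_i * sigma_j."""
        s = np.array([self.sigma_intercept, self.sigma_age, self.sigma_height])
        rho = np.array(
            [
                [1.0, self.rho_intercept_age, self.rho_intercept_height],
                [self.rho_intercept_age, 1.0, self.rho_age_height],
                [self.rho_intercept_height, self.rho_age_height, 1.0],
            ]
        )
        return rho * np.outer(s, s)

    def conditional_sd(self, age10, height_z):
        """Marginal SD of a new measurement at covariates v = (1, age-10, h)."""
        sig = self.covariance()
        a = np.asarray(age10, dtype=float)
        h = np.asarray(height_z, dtype=float)
        quad = (
            sig[0, 0]
            + a**2 * sig[1, 1]
            + h**2 * sig[2, 2]
            + 2 * a * sig[0, 1]
            + 2 * h * sig[0, 2]
            + 2 * a * h * sig[1, 2]
        )
        out = np.sqrt(self.sigma_observation**2 + quad)
        return out if out.shape else float(out)


@dataclass(frozen=True)
class Stratum:
    """One sex x BP-type reference: fixed polynomial + variance description."""

    fixed: CoefficientSet
    sigma: float | None = None
    random_effects: RandomEffectSpec | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if (self.sigma is None) == (self.random_effects is None):
            raise ValueError("exactly one of sigma (scalar) or random_effects must be given")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def form(self) -> str:
        return "random_intercept" if self.sigma is not None else "random_slopes"


@dataclass(frozen=True)
class BPAssessment:
    expected_bp: float
    sd: float
    z: float
    percentile: float
    category: str | None = None


class ReferenceModel:
    """Sex- and BP-type-stratified BP reference with Z/percentile evaluation."""

    def __init__(self, strata: Mapping[tuple[str, str], Stratum], name: str = "", version: str = ""):
        self.strata = dict(strata)
        self.name = name
        self.version = version
        for key in self.strata:
            check_stratum(*key)

    def stratum(self, sex: str, bp_type: str) -> Stratum:
        key = check_stratum(sex, bp_type)
        try:
            return self.strata[key]
        except KeyError:
            raise KeyError(f"model {self.name!r} has no stratum {key}") from None

    @staticmethod
    def _check_domain(age, height_z):
        age = np.asarray(age, dtype=float)
        height_z = np.asarray(height_z, dtype=float)
        if np.any(age < AGE_DOMAIN[0]) or np.any(age >= AGE_DOMAIN[1]):
            raise ValueError(f"age must lie in [{AGE_DOMAIN[0]}, {AGE_DOMAIN[1]}) years")
        if np.any(np.abs(height_z) > HEIGHT_Z_DOMAIN[1]):
            raise ValueError(f"height Z must lie in [{HEIGHT_Z_DOMAIN[0]}, {HEIGHT_Z_DOMAIN[1]}]")
        return age, height_z

    def expected_bp(self, sex, bp_type, age, height_z):
        """Fixed-effect conditional mean BP (mmHg)."""
        age, height_z = self._check_domain(age, height_z)
        return self.stratum(sex, bp_type).fixed.evaluate(age - 10.0, height_z)

    def conditional_sd(self, sex, bp_type, age, height_z):
        """SD used for the Z-score at (age, height Z); scalar for the random-intercept form."""
        age, height_z = self._check_domain(age, height_z)
        st = self.stratum(sex, bp_type)
        if st.sigma is not None:
            out = np.broadcast_to(st.sigma, np.broadcast(age, height_z).shape).copy()
            return out if out.shape else float(st.sigma)
        return st.random_effects.conditional_sd(age - 10.0, height_z)

    def z_score(self, sex, bp_type, age, height_z, observed_bp):
        observed_bp = np.asarray(observed_bp, dtype=float)
        if np.any(observed_bp <= 0):
            raise ValueError("observed BP must be positive")
        mu = self.expected_bp(sex, bp_type, age, height_z)
        sd = self.conditional_sd(sex, bp_type, age, height_z)
        out = (observed_bp - mu) / sd
        return out if np.shape(out) else float(out)

    def percentile(self, sex, bp_type, age, height_z, observed_bp):
        return percentile_of_z(self.z_score(sex, bp_type, age, height_z, observed_bp))

    def bp_at_percentile(self, sex, bp_type, age, height_z, p):
        """BP (mmHg) at percentile ``p`` in (0, 100): mu + Phi^-1(p/100) * sigma."""
        p = np.asarray(p, dtype=float)
        if np.any(p <= 0) or np.any(p >= 100):
            raise ValueError("percentile must lie strictly between 0 and 100")
        mu = self.expected_bp(sex, bp_type, age, height_z)
        sd = self.conditional_sd(sex, bp_type, age, height_z)
        out = mu + norm.ppf(p / 100.0) * sd
        return out if np.shape(out) else float(out)

    def assess(self, sex, bp_type, age, height_z, observed_bp, scheme: str | None = None) -> BPAssessment:
        mu = float(self.expected_bp(sex, bp_type, age, height_z))
        sd = float(self.conditional_sd(sex, bp_type, age, height_z))
        z = (float(observed_bp) - mu) / sd
        cat = None
        if scheme is not None:
            cat = classify(self, sex, bp_type, age, height_z, observed_bp, scheme)
        return BPAssessment(mu, sd, z, percentile_of_z(z), cat)


def percentile_of_z(z):
    """Gaussian percentile (0-100 scale) of a Z-score."""
    out = 100.0 * norm.cdf(np.asarray(z, dtype=float))
    return out if out.shape else float(out)


def z_of_percentile(p):
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 100):
        raise ValueError("percentile must lie strictly between 0 and 100")
    out = norm.ppf(p / 100.0)
    return out if out.shape else float(out)


def height_percentile_to_z(height_pct):
    """Height percentile -> height Z at full double precision (90 -> 1.2816)."""
    return z_of_percentile(height_pct)


def z_from_mean_sd(observed_bp: float, expected_bp: float, sd: float) -> float:
    """Worked-example arithmetic: Z from an externally supplied mean and SD.

    Provided so published worked examples (which may pair a mean and an SD
    from different sources) can be reproduced verbatim; the engine itself
    always pairs a model's own mu and sigma.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    return (float(observed_bp) - float(expected_bp)) / float(sd)


def classify(model: ReferenceModel, sex, bp_type, age, height_z, observed_bp, scheme: str = "banker5") -> str:
    """Ordinal BP category of an observation under a reference model.

    ``banker5``: <10th, [10th, 90th), [90th, 95th), [95th, 95th + 12 mmHg),
    >= 95th-percentile BP + 12 mmHg (the +12 applied in mmHg to the child's
    95th-percentile BP).  ``aap4`` merges the bottom two (normal < 90th).
    ``adult_absolute`` applies fixed mmHg cutoffs and is only defined for
    ages >= 13.  Boundaries are lower-bound inclusive.
    """
    observed_bp = float(observed_bp)
    if scheme == "adult_absolute":
        if age < 13:
            raise ValueError("adult_absolute classification applies to ages >= 13 only")
        lo, mid, hi = ADULT_CUTOFFS[check_stratum(sex, bp_type)[1]]
        if observed_bp >= hi:
            return "stage2"
        if observed_bp >= mid:
            return "stage1"
        if observed_bp >= lo:
            return "elevated" if mid > lo else "stage1"
        return "normal"
    if scheme not in ("banker5", "aap4"):
        raise ValueError(f"unknown classification scheme {scheme!r}")
    p10, p90, p95 = (model.bp_at_percentile(sex, bp_type, age, height_z, p) for p in (10, 90, 95))
    if observed_bp >= p95 + 12.0:
        return "stage2"
    if observed_bp >= p95:
        return "stage1"
    if observed_bp >= p90:
        return "elevated"
    if scheme == "banker5" and observed_bp < p10:
        return "low"
    return "normal"


def category_codes(labels, scheme: str = "banker5") -> np.ndarray:
    order = BANKER5_LABELS if scheme == "banker5" else AAP4_LABELS
    lut = {lab: i for i, lab in enumerate(order)}
    return np.array([lut[l] for l in labels], dtype=int)


def percentile_table(
    model: ReferenceModel,
    sex,
    bp_type,
    ages=range(3, 18),
    height_percentiles=(5, 10, 25, 50, 75, 90, 95),
    bp_percentiles=(50, 75, 90, 95),
):
    """Reference table of BP (mmHg) by integer age x height percentile x BP percentile."""
    import pandas as pd

    rows = []
    for age in ages:
        for hp in height_percentiles:
            hz = float(height_percentile_to_z(hp))
            for bp_pct in bp_percentiles:
                rows.append(
                    {
                        "sex": check_stratum(sex, bp_type)[0],
                        "bp_type": check_stratum(sex, bp_type)[1],
                        "age": int(age),
                        "height_percentile": hp,
                        "height_z": hz,
                        "bp_percentile": bp_pct,
                        "bp_mmhg": float(model.bp_at_percentile(sex, bp_type, age, hz, bp_pct)),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundle (de)serialisation.  Coefficients are stored as strings so published
# values survive round-trips exactly as printed.

SCHEMA_VERSION = 1


def _stratum_to_dict(st: Stratum) -> dict:
    d: dict = {"fixed": {"intercept": repr(st.fixed.intercept)}}
    for t in st.fixed.included_terms:
        d["fixed"][t] = repr(st.fixed.coeffs[t])
    if st.sigma is not None:
        d["sigma"] = repr(st.sigma)
    else:
        re = st.random_effects
        d["random_effects"] = {
            "sigma_intercept": repr(re.sigma_intercept),
            "sigma_age": repr(re.sigma_age),
            "sigma_height": repr(re.sigma_height),
            "rho_intercept_age": repr(re.rho_intercept_age),
            "rho_intercept_height": repr(re.rho_intercept_height),
            "rho_age_height": repr(re.rho_age_height),
            "sigma_observation": repr(re.sigma_observation),
        }
    if st.metadata:
        d["metadata"] = dict(st.metadata)
    return d


def _stratum_from_dict(d: Mapping) -> Stratum:
    fixed = {k: float(v) for k, v in d["fixed"].items()}
    coef = CoefficientSet(intercept=fixed.pop("intercept"), coeffs=fixed)
    if "sigma" in d:
        return Stratum(fixed=coef, sigma=float(d["sigma"]), metadata=d.get("metadata", {}))
    re = {k: float(v) for k, v in d["random_effects"].items()}
    return Stratum(fixed=coef, random_effects=RandomEffectSpec(**re), metadata=d.get("metadata", {}))


def save_bundle(model: ReferenceModel, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": model.name,
        "version": model.version,
        "strata": {f"{s}:{b}": _stratum_to_dict(st) for (s, b), st in model.strata.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def _model_from_doc(doc: Mapping) -> ReferenceModel:
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported bundle schema_version {doc.get('schema_version')!r}")
    strata = {}
    for key, sd in doc["strata"].items():
        sex, bp_type = key.split(":")
        strata[check_stratum(sex, bp_type)] = _stratum_from_dict(sd)
    return ReferenceModel(strata, name=doc.get("name", ""), version=doc.get("version", ""))


def load_bundle(path) -> ReferenceModel:
    return _model_from_doc(json.loads(Path(path).read_text(encoding="utf-8")))


#: Names of the coefficient bundles shipped with the package.
BUNDLED_MODELS = ("ehr_random_intercept", "ehr_random_slopes")


def load_bundled_model(name: str = "ehr_random_slopes") -> ReferenceModel:
    """Load one of the shipped EHR-derived reference bundles.

    ``ehr_random_intercept`` is the constant-SD model (for comparison with
    the 2017 AAP CPG form); ``ehr_random_slopes`` is the final model with
    age/height-dependent SD.
    """
    if name not in BUNDLED_MODELS:
        raise ValueError(f"unknown bundled model {name!r}; choose from {BUNDLED_MODELS}")
    text = resources.files("bpref.data").joinpath(f"{name}.json").read_text(encoding="utf-8")
    return _model_from_doc(json.loads(text))
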