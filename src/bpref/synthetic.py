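"""Synthetic longitudinal office-BP encounter tables.

The generator emulates the structure the downstream analysis assumes: each
child carries a trivariate Gaussian random-effect vector per BP type
(intercept, age-10 slope, height-Z slope) drawn from a truth
:class:`~bpref.reference.ReferenceModel`, and every blood-pressure reading is

    BP = mu_fixed(age, heightZ) + b . (1, age - 10, heightZ) + eps,

with ``eps`` i.i.d. N(0, sigma_observation).  Visit ages are drawn on a
per-child window whose width matches the published span quartiles, and the
encounter-count distribution matches the published one.  Controlled
contamination records (overweight, chronic condition, medication exposure,
inpatient care, implausible BP, missing vitals) are injected at configured
rates and labelled with a hidden ``should_be_excluded_by`` tag so the
attrition cascade can be tested against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._design import BP_TYPES, check_stratum
from .reference import ReferenceModel, Stratum, load_bundled_model

QUALIFYING_PROVIDERS = ("general_pediatrics", "family_medicine", "aprn", "physician_assistant")
NON_QUALIFYING_PROVIDERS = ("cardiology", "orthopedics")

#: Contamination tags and the semantics of each (see GeneratorConfig).
CONTAMINATION_TAGS = (
    "overweight",
    "chronic_condition",
    "medication",
    "inpatient",
    "implausible_bp",
    "missing_vitals",
)

DEFAULT_RACE_FREQUENCIES = {
    "NH-White": 0.4833,
    "NH-Black": 0.1890,
    "Other-Unknown": 0.1328,
    "Hispanic": 0.1041,
    "NH-Asian-PI": 0.0675,
    "Multiple": 0.0233,
}

DEFAULT_SITES = tuple(f"site_{i:02d}" for i in range(1, 9))

COLUMNS = [
    "child_id",
    "sex",
    "site",
    "race_ethnicity",
    "encounter_id",
    "calendar_year",
    "age",
    "height_z",
    "bmi_ge_85_flag",
    "care_setting",
    "provider_type",
    "chronic_condition_flag",
    "bp_medication_flag",
    "reading_index",
    "sbp",
    "dbp",
    "should_be_excluded_by",
]


def _lognormal_params(quartiles: tuple[float, float, float]) -> tuple[float, float]:
    """(mu, sigma) of a log-normal matching the given (Q1, median, Q3)."""
    q1, med, q3 = quartiles
    if not 0 < q1 < med < q3:
        raise ValueError(f"quartiles must be positive and increasing, got {quartiles}")
    mu = math.log(med)
    sigma = (math.log(q3) - math.log(q1)) / (2 * norm.ppf(0.75))
    return mu, sigma


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the published final-cohort structure: encounter-count
    distribution {1: 27%, 2: 21%, 3: 14%, 4: 10%, 5: 7%, 6+: 21%} (with the
    6+ tail drawn as 6 + Poisson so the overall mean is ~3.7 BP encounters
    per child), per-child age spans log-normal with median 2.2 years (IQR
    1.2-4.4), height-Z spans with median 0.4 (IQR 0.2-0.7), ages 3-17,
    calendar years 2009-2021, 53% girls.
    """

    n_children: int = 2000
    seed: int = 0
    encounter_count_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.27, 2: 0.21, 3: 0.14, 4: 0.10, 5: 0.07, 6: 0.21}
    )
    #: mean of the Poisson tail added on top of 6 for the "6+" category
    six_plus_poisson_mean: float = 2.8
    age_range: tuple[float, float] = (3.0, 18.0)
    age_span_quartiles: tuple[float, float, float] = (1.2, 2.2, 4.4)
    heightz_span_quartiles: tuple[float, float, float] = (0.2, 0.4, 0.7)
    year_range: tuple[int, int] = (2009, 2021)
    contamination_rates: Mapping[str, float] = field(
        default_factory=lambda: {tag: 0.02 for tag in CONTAMINATION_TAGS}
    )
    readings_per_day_distribution: Mapping[int, float] = field(default_factory=lambda: {1: 1.0})
    female_fraction: float = 0.53
    site_frequencies: Mapping[str, float] = field(
        default_factory=lambda: {s: 1.0 / len(DEFAULT_SITES) for s in DEFAULT_SITES}
    )
    race_frequencies: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RACE_FREQUENCIES))

    def validate(self) -> None:
        if self.n_children <= 0:
            raise ValueError("n_children must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("empty age range")
        for name in ("encounter_count_distribution", "readings_per_day_distribution",
                     "site_frequencies", "race_frequencies"):
            probs = np.array(list(getattr(self, name).values()), dtype=float)
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        unknown = set(self.contamination_rates) - set(CONTAMINATION_TAGS)
        if unknown:
            raise ValueError(f"unknown contamination tags: {sorted(unknown)}")
        for tag, rate in self.contamination_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"contamination rate for {tag!r} must be in [0, 1]")
        if sum(self.contamination_rates.values()) > 1.0:
            raise ValueError("contamination rates sum to more than 1 (subsets are disjoint)")
        _lognormal_params(self.age_span_quartiles)
        _lognormal_params(self.heightz_span_quartiles)

    def without_contamination(self) -> "GeneratorConfig":
        return replace(self, contamination_rates={t: 0.0 for t in CONTAMINATION_TAGS})


def _re_covariance(stratum: Stratum) -> tuple[np.ndarray, float]:
    """Random-effect covariance and residual SD implied by a truth stratum.

    Random-slopes strata carry both directly.  Random-intercept strata carry a
    pooled total SD; an ``icc`` metadata entry (if present) splits it into
    between-child and residual parts, otherwise all variance is residual.
    """
    if stratum.random_effects is not None:
        re = stratum.random_effects
        return re.covariance(), re.sigma_observation
    icc = float(stratum.metadata.get("icc", 0.0))
    var_int = icc * stratum.sigma**2
    cov = np.zeros((3, 3))
    cov[0, 0] = var_int
    return cov, math.sqrt(stratum.sigma**2 - var_int)


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    w, u = np.linalg.eigh(cov)
    if w.min() < -1e-8:
        raise ValueError("truth random-effect covariance is not positive semi-definite")
    return u @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _draw_count(rng, dist: Mapping[int, float]) -> int:
    keys = list(dist.keys())
    return int(keys[rng.choice(len(keys), p=list(dist.values()))])


def _scalar_sd_proxy(stratum: Stratum, age_range: tuple[float, float]) -> float:
    """Population-average measurement SD under a truth stratum.

    Approximates the total SD a scalar-sigma (random-intercept) refit would
    estimate on this cohort, assuming ages ~ Uniform(age_range) and height Z
    ~ N(0, 1): E[v' Sigma v] = S00 + E[a^2] S11 + S22 + 2 E[a] S01 with
    a = age - 10.  Used to place implausible-BP contamination safely beyond
    the +/-5 Z plausibility bound of the preliminary filter model.
    """
    if stratum.sigma is not None:
        return float(stratum.sigma)
    re = stratum.random_effects
    sig = re.covariance()
    lo, hi = age_range[0] - 10.0, age_range[1] - 10.0
    mean_a = (lo + hi) / 2.0
    mean_a2 = (hi - lo) ** 2 / 12.0 + mean_a**2
    quad = sig[0, 0] + mean_a2 * sig[1, 1] + sig[2, 2] + 2 * mean_a * sig[0, 1]
    return math.sqrt(re.sigma_observation**2 + quad)


def simulate_cohort(config: GeneratorConfig, truth: ReferenceModel | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Generate an encounter table, one row per reading.

    Same config and seed give byte-identical tables.  Contaminated children/
    records carry exactly one ground-truth tag in ``should_be_excluded_by``.
    """
    config.validate()
    if truth is None:
        truth = load_bundled_model("ehr_random_slopes")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    # per-stratum generative pieces
    strata = {}
    for sex in ("M", "F"):
        for bp in BP_TYPES:
            st = truth.stratum(sex, bp)
            cov, sigma_obs = _re_covariance(st)
            strata[(sex, bp)] = (st.fixed, _psd_factor(cov), sigma_obs)

    n = config.n_children
    sexes = np.where(rng.random(n) < config.female_fraction, "F", "M")
    sites = rng.choice(list(config.site_frequencies), size=n, p=list(config.site_frequencies.values()))
    races = rng.choice(list(config.race_frequencies), size=n, p=list(config.race_frequencies.values()))

    # disjoint contamination assignment (order fixed by CONTAMINATION_TAGS)
    tags = np.array([""] * n, dtype=object)
    perm = rng.permutation(n)
    cursor = 0
    for tag in CONTAMINATION_TAGS:
        k = int(round(config.contamination_rates.get(tag, 0.0) * n))
        tags[perm[cursor:cursor + k]] = tag
        cursor += k

    a_mu, a_sig = _lognormal_params(config.age_span_quartiles)
    h_mu, h_sig = _lognormal_params(config.heightz_span_quartiles)
    age_lo, age_hi = config.age_range
    yr_lo, yr_hi = config.year_range

    rows: list[tuple] = []
    enc_counter = 0
    for i in range(n):
        sex = sexes[i]
        tag = tags[i]
        child_id = f"C{i:06d}"
        n_bp = _draw_count(rng, config.encounter_count_distribution)
        if n_bp >= 6:
            n_bp = 6 + int(rng.poisson(config.six_plus_poisson_mean))

        # visit ages: BP encounters span a window matching the span quartiles
        if n_bp == 1:
            bp_ages = np.array([rng.uniform(age_lo, age_hi - 0.001)])
        else:
            span = float(np.clip(rng.lognormal(a_mu, a_sig), 0.05, age_hi - age_lo - 0.1))
            start = rng.uniform(age_lo, age_hi - span - 0.001)
            inner = np.sort(rng.uniform(0.0, span, max(n_bp - 2, 0)))
            bp_ages = start + np.concatenate([[0.0], inner, [span]])
            # visits fall on distinct days (ages are recorded to ~a day)
            for j in range(1, len(bp_ages)):
                if bp_ages[j] - bp_ages[j - 1] < 0.003:
                    bp_ages[j] = bp_ages[j - 1] + 0.003
            bp_ages = np.minimum(bp_ages, age_hi - 0.001)

        bp_ages = np.round(bp_ages, 4)

        # qualifying non-BP care visits: guarantee >= 2 care visits and
        # <= 18-month gaps whenever the observation span exceeds 3 years
        extra_ages: list[float] = []
        if n_bp == 1:
            a = bp_ages[0]
            lo = max(age_lo, a - 1.4)
            hi = min(age_hi - 0.001, a + 1.4)
            extra_ages.append(round(float(rng.uniform(lo, hi)), 4))
        all_ages = np.sort(np.concatenate([bp_ages, extra_ages]))
        if all_ages[-1] - all_ages[0] > 3.0:
            filled = [all_ages[0]]
            for a in all_ages[1:]:
                while a - filled[-1] > 1.45:
                    filled.append(round(filled[-1] + 1.4, 4))
                filled.append(a)
            extra_ages.extend(x for x in filled if x not in all_ages)

        # height Z: baseline plus a linear within-child drift matching the span
        baseline_hz = float(np.clip(rng.standard_normal(), -3.5, 3.5))
        amin, amax = bp_ages.min(), bp_ages.max()
        if n_bp > 1:
            hz_span = float(rng.lognormal(h_mu, h_sig))
            direction = 1.0 if rng.random() < 0.5 else -1.0
        else:
            hz_span, direction = 0.0, 1.0

        def hz_at(a: float) -> float:
            frac = 0.0 if amax == amin else np.clip((a - amin) / (amax - amin), 0.0, 1.0)
            # kept inside the reference-model evaluation domain
            return round(float(np.clip(baseline_hz + direction * hz_span * (frac - 0.5), -4.9, 4.9)), 4)

        base_year = int(rng.integers(yr_lo, yr_hi + 1))
        first_age = min(all_ages[0], bp_ages[0])

        def year_at(a: float) -> int:
            return int(np.clip(base_year + math.floor(a - first_age), yr_lo, yr_hi))

        b = {bp: strata[(sex, bp)][1] @ rng.standard_normal(3) for bp in BP_TYPES}

        chronic = 1 if tag == "chronic_condition" else 0
        medicated = 1 if tag == "medication" else 0
        bmi_flag = 1 if tag == "overweight" else 0
        child_tag = tag if tag in ("overweight", "chronic_condition", "medication", "inpatient") else ""

        def child_mean(bp_type: str, age: float, hz: float) -> float:
            """Fixed + random-effect mean for this child (noise added per reading)."""
            fixed, _, _ = strata[(sex, bp_type)]
            v = np.array([1.0, age - 10.0, hz])
            return float(fixed.evaluate(age - 10.0, hz) + b[bp_type] @ v)

        def emit(age, hz, readings, care_setting="outpatient",
                 provider="general_pediatrics", row_tag=None):
            """Append one encounter; ``readings`` is a list of (sbp, dbp) pairs."""
            nonlocal enc_counter
            enc_counter += 1
            for ridx, (sbp, dbp) in enumerate(readings):
                rows.append(
                    (child_id, sex, sites[i], races[i], f"E{enc_counter:07d}", year_at(age),
                     float(age), np.nan if hz is None else float(hz),
                     bmi_flag, care_setting, provider, chronic, medicated, ridx,
                     sbp, dbp, child_tag if row_tag is None else row_tag)
                )

        for age in bp_ages:
            hz = hz_at(age)
            n_read = _draw_count(rng, config.readings_per_day_distribution)
            so_s = strata[(sex, "sbp")][2]
            so_d = strata[(sex, "dbp")][2]
            mu_s = child_mean("sbp", age, hz)
            mu_d = child_mean("dbp", age, hz)
            emit(age, hz, [(mu_s + rng.normal(0.0, so_s), mu_d + rng.normal(0.0, so_d))
                           for _ in range(n_read)])

        for age in sorted(extra_ages):
            emit(age, hz_at(age), [(np.nan, np.nan)])

        if tag == "inpatient":
            age = round(float(np.clip(bp_ages[0] + 0.1, age_lo, age_hi - 0.001)), 4)
            hz = hz_at(age)
            so_s = strata[(sex, "sbp")][2]
            so_d = strata[(sex, "dbp")][2]
            emit(age, hz, [(child_mean("sbp", age, hz) + rng.normal(0.0, so_s),
                            child_mean("dbp", age, hz) + rng.normal(0.0, so_d))],
                 care_setting="inpatient", row_tag="inpatient")
        elif tag == "implausible_bp":
            age = round(float(np.clip(bp_ages[0] + 0.05, age_lo, age_hi - 0.001)), 4)
            hz = hz_at(age)
            bad_type = "sbp" if rng.random() < 0.5 else "dbp"
            # direction chosen so the sbp > dbp ordering stays intact
            sign = 1.0 if bad_type == "sbp" else -1.0
            z_extreme = rng.uniform(5.5, 7.8)
            vals = {}
            for bp in BP_TYPES:
                st = truth.stratum(sex, bp)
                mu = float(st.fixed.evaluate(age - 10.0, hz))
                sd = _scalar_sd_proxy(st, config.age_range)
                vals[bp] = mu + sign * z_extreme * sd if bp == bad_type else mu
            emit(age, hz, [(vals["sbp"], vals["dbp"])], row_tag="implausible_bp")
        elif tag == "missing_vitals":
            age = round(float(np.clip(bp_ages[0] + 0.05, age_lo, age_hi - 0.001)), 4)
            emit(age, None, [(child_mean("sbp", age, baseline_hz),
                              child_mean("dbp", age, baseline_hz))],
                 row_tag="missing_vitals")

    df = pd.DataFrame(rows, columns=COLUMNS)
    df = df.sort_values(["child_id", "age", "encounter_id", "reading_index"], kind="mergesort")
    return df.reset_index(drop=True)


def inject_same_day_duplicates(table: pd.DataFrame, rate: float, inflation: float,
                               seed: int = 0) -> pd.DataFrame:
    """Give a fraction of BP child-days a second, inflated reading.

    Emulates digital-device first-reading overestimation: the duplicate reads
    ``first + inflation`` mmHg, so on those days the daily mean exceeds the
    daily minimum by ``inflation / 2``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if inflation < 0:
        raise ValueError("inflation must be non-negative")
    if rate == 0.0:
        return table.copy()
    rng = np.random.default_rng(seed)
    firsts = table[(table["reading_index"] == 0) & table["sbp"].notna()]
    chosen = firsts.index[rng.random(len(firsts)) < rate]
    dup = table.loc[chosen].copy()
    dup["reading_index"] = table.groupby("encounter_id")["reading_index"].transform("max").loc[chosen] + 1
    dup["sbp"] = dup["sbp"] + inflation
    dup["dbp"] = dup["dbp"] + inflation
    out = pd.concat([table, dup], ignore_index=True)
    out = out.sort_values(["child_id", "age", "encounter_id", "reading_index"], kind="mergesort")
    return out.reset_index(drop=True)


def write_encounters(table: pd.DataFrame, path) -> None:
    """Headered UTF-8 CSV, one row per reading; missing values as empty fields."""
    table.to_csv(Path(path), index=False, encoding="utf-8")


def read_encounters(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), encoding="utf-8")
    df["should_be_excluded_by"] = df["should_be_excluded_by"].fillna("")
    return df
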