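"""Cohort derivation: inclusion/exclusion cascade and measurement cleaning.

The cascade mirrors the selection of a general-paediatrics reference
population from raw encounter data: ages 3-17, BMI below the 85th
percentile, outpatient care only, at least two qualifying care visits with
no gap over 18 months when followed for more than 3 years, no chronic
conditions, no BP-altering medication, complete vitals, then same-day
averaging and a +/-5 Z-score plausibility screen against a preliminary
constant-SD model.  Each step's surviving child and measurement counts are
recorded in an :class:`AttritionReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import ReferenceModel
from .synthetic import QUALIFYING_PROVIDERS

#: Maximum allowed inter-visit gap (years) when the observation span exceeds 3 years.
MAX_VISIT_GAP_YEARS = 1.5
FOLLOWUP_SPAN_YEARS = 3.0
PLAUSIBILITY_BOUND = 5.0

#: Ground-truth contamination tag -> the attrition/cleaning step that must remove it.
EXCLUSION_STEP_FOR_TAG = {
    "overweight": "bmi_lt_85",
    "chronic_condition": "no_chronic_condition",
    "medication": "no_bp_medication",
    "inpatient": "outpatient_only",
    "missing_vitals": "vitals_present",
    "implausible_bp": "bp_plausibility",
}


@dataclass
class AttritionReport:
    """Ordered per-step counts of children and BP measurements surviving."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)
    #: step at which each input row was removed (index-aligned with the input
    #: table; NA for surviving rows) — lets tests check removals against
    #: generator ground-truth tags.
    removed_at: pd.Series | None = None

    def append(self, step_name: str, children: int, measurements: int) -> None:
        if self.steps:
            _, c0, m0 = self.steps[-1]
            if children > c0 or measurements > m0:
                raise ValueError("attrition counts may never increase")
        self.steps.append((step_name, int(children), int(measurements)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "children_remaining", "measurements_remaining"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def log_lines(self) -> list[str]:
        out = []
        for step, c, m in self.steps:
            out.append(f"{step:<24s} children={c:>9d}  measurements={m:>9d}")
        return out


def _counts(df: pd.DataFrame) -> tuple[int, int]:
    has_bp = df["sbp"].notna() | df["dbp"].notna()
    return df["child_id"].nunique(), int(has_bp.sum())


def _require_columns(df: pd.DataFrame, cols) -> None:
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"missing required column: {c!r}")


# --- rule implementations ---------------------------------------------------
# Each rule maps the current table to a boolean keep-mask over its rows.
# Child-level rules exclude every row of a failing child.


def _rule_dedup_exact(df):
    return ~df.duplicated(keep="first")


def _rule_age_window(df):
    return (df["age"] >= 3.0) & (df["age"] < 18.0)


def _rule_outpatient_only(df):
    bad_children = df.loc[df["care_setting"] != "outpatient", "child_id"].unique()
    return ~df["child_id"].isin(bad_children)


def _rule_min_care_visits(df):
    qualifying = df[df["provider_type"].isin(QUALIFYING_PROVIDERS) & (df["care_setting"] == "outpatient")]
    n_visits = qualifying.groupby("child_id")["encounter_id"].nunique()
    ok = set(n_visits.index[n_visits >= 2])
    return df["child_id"].isin(ok)


def _rule_continuity_18mo(df):
    qualifying = df[df["provider_type"].isin(QUALIFYING_PROVIDERS) & (df["care_setting"] == "outpatient")]
    visit_ages = qualifying.drop_duplicates(["child_id", "encounter_id"]).groupby("child_id")["age"]

    def ok(ages) -> bool:
        a = np.sort(np.asarray(ages, dtype=float))
        if a[-1] - a[0] <= FOLLOWUP_SPAN_YEARS:
            return True
        return bool(np.all(np.diff(a) <= MAX_VISIT_GAP_YEARS))

    good = {cid for cid, ages in visit_ages if ok(ages.to_numpy())}
    return df["child_id"].isin(good)


def _child_flag_rule(flag_col):
    def rule(df):
        bad = df.loc[df[flag_col] == 1, "child_id"].unique()
        return ~df["child_id"].isin(bad)

    return rule


def _rule_vitals_present(df):
    return df["height_z"].notna() & df["sbp"].notna() & df["dbp"].notna()


def _rule_valid_reading_values(df):
    return (df["sbp"] > 0) & (df["dbp"] > 0) & (df["sbp"] > df["dbp"])


def _rule_min_one_bp_day(df):
    has_bp = df["sbp"].notna() & df["dbp"].notna()
    ok = df.loc[has_bp, "child_id"].unique()
    return df["child_id"].isin(ok)


_RULES: dict[str, tuple] = {
    # name: (function, required columns)
    "dedup_exact": (_rule_dedup_exact, ()),
    "age_window": (_rule_age_window, ("age",)),
    "outpatient_only": (_rule_outpatient_only, ("child_id", "care_setting")),
    "min_care_visits": (_rule_min_care_visits, ("child_id", "encounter_id", "provider_type", "care_setting")),
    "continuity_18mo": (_rule_continuity_18mo, ("child_id", "encounter_id", "age", "provider_type", "care_setting")),
    "bmi_lt_85": (_child_flag_rule("bmi_ge_85_flag"), ("child_id", "bmi_ge_85_flag")),
    "no_chronic_condition": (_child_flag_rule("chronic_condition_flag"), ("child_id", "chronic_condition_flag")),
    "no_bp_medication": (_child_flag_rule("bp_medication_flag"), ("child_id", "bp_medication_flag")),
    "vitals_present": (_rule_vitals_present, ("height_z", "sbp", "dbp")),
    "valid_reading_values": (_rule_valid_reading_values, ("sbp", "dbp")),
    "min_one_bp_day": (_rule_min_one_bp_day, ("child_id", "sbp", "dbp")),
}

#: Default cascade.  With the leading "input" bookkeeping entry and the
#: downstream "bp_plausibility" screen (applied after same-day averaging by
#: :func:`plausibility_filter`) this is the shipped 13-step process.
DEFAULT_RULES = (
    "dedup_exact",
    "age_window",
    "outpatient_only",
    "min_care_visits",
    "continuity_18mo",
    "bmi_lt_85",
    "no_chronic_condition",
    "no_bp_medication",
    "vitals_present",
    "valid_reading_values",
    "min_one_bp_day",
)

DEFAULT_STEP_NAMES = ("input",) + DEFAULT_RULES + ("bp_plausibility",)

#: Rules whose pass/fail status for a child does not depend on other rules
#: having run first (used by the order-permutation invariance property).
INDEPENDENT_CHILD_RULES = ("outpatient_only", "bmi_lt_85", "no_chronic_condition", "no_bp_medication")


def apply_attrition(table: pd.DataFrame, rules=DEFAULT_RULES) -> tuple[pd.DataFrame, AttritionReport]:
    """Run the exclusion cascade in order, recording counts after every step."""
    for name in rules:
        if name not in _RULES:
            raise ValueError(f"unknown attrition rule: {name!r}")
        _require_columns(table, _RULES[name][1])
    _require_columns(table, ("child_id", "sbp", "dbp"))

    report = AttritionReport()
    removed_at = pd.Series(pd.NA, index=table.index, dtype="object")
    df = table
    report.append("input", *_counts(df))
    for name in rules:
        rule_fn, _ = _RULES[name]
        keep = rule_fn(df)
        removed_at.loc[df.index[~keep]] = name
        df = df[keep]
        report.append(name, *_counts(df))
    report.removed_at = removed_at
    return df.copy(), report


ROW_COLUMNS = ["child_id", "sex", "age", "age10", "height_z", "sbp", "dbp",
               "calendar_year", "site", "race_ethnicity"]


def average_same_day(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse readings to one analysis row per child-day (arithmetic means).

    Child-days missing either BP type are dropped (the analysis table pairs
    systolic and diastolic).  Idempotent: applied to an already-averaged
    table it is the identity.
    """
    _require_columns(table, ("child_id", "age", "sbp", "dbp"))
    agg = {"sbp": ("sbp", "mean"), "dbp": ("dbp", "mean")}
    for col in ("sex", "calendar_year", "site", "race_ethnicity", "height_z"):
        if col in table.columns:
            agg[col] = (col, "first")
    rows = table.groupby(["child_id", "age"], as_index=False, sort=True).agg(**agg)
    rows = rows[rows["sbp"].notna() & rows["dbp"].notna()]
    rows["age10"] = rows["age"] - 10.0
    cols = [c for c in ROW_COLUMNS if c in rows.columns]
    return rows[cols].reset_index(drop=True)


@dataclass(frozen=True)
class MeanVsMinResult:
    """Daily mean-vs-minimum diagnostic for repeat-reading days."""

    fraction_mean_gt_min: float          # child-days where mean > min for either BP type
    fraction_sbp: float
    fraction_dbp: float
    max_abs_diff_sbp: float              # mmHg
    max_abs_diff_dbp: float              # mmHg
    n_days: int


def mean_vs_min_diagnostic(table: pd.DataFrame) -> MeanVsMinResult:
    """Compare daily mean against daily minimum BP over raw readings."""
    _require_columns(table, ("child_id", "age", "sbp", "dbp"))
    bp = table[table["sbp"].notna() & table["dbp"].notna()]
    g = bp.groupby(["child_id", "age"])
    stats = g.agg(sbp_mean=("sbp", "mean"), sbp_min=("sbp", "min"),
                  dbp_mean=("dbp", "mean"), dbp_min=("dbp", "min"))
    if len(stats) == 0:
        return MeanVsMinResult(0.0, 0.0, 0.0, 0.0, 0.0, 0)
    ds = stats["sbp_mean"] - stats["sbp_min"]
    dd = stats["dbp_mean"] - stats["dbp_min"]
    eps = 1e-9
    return MeanVsMinResult(
        fraction_mean_gt_min=float(((ds > eps) | (dd > eps)).mean()),
        fraction_sbp=float((ds > eps).mean()),
        fraction_dbp=float((dd > eps).mean()),
        max_abs_diff_sbp=float(ds.abs().max()),
        max_abs_diff_dbp=float(dd.abs().max()),
        n_days=len(stats),
    )


def plausibility_filter(rows: pd.DataFrame, preliminary: ReferenceModel,
                        bound: float = PLAUSIBILITY_BOUND) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove analysis rows with |Z| > bound for either BP type.

    ``preliminary`` is a constant-SD (random-intercept form) model fitted
    once on the unfiltered rows; the screen is a single pass — fit once,
    filter once, refit downstream.
    """
    if bound <= 0:
        raise ValueError("plausibility bound must be positive")
    _require_columns(rows, ("sex", "age", "height_z", "sbp", "dbp"))
    keep = np.ones(len(rows), dtype=bool)
    for sex in ("M", "F"):
        m = (rows["sex"] == sex).to_numpy()
        if not m.any():
            continue
        sub = rows[m]
        for bp_type in ("sbp", "dbp"):
            z = preliminary.z_score(sex, bp_type, sub["age"].to_numpy(),
                                    sub["height_z"].to_numpy(), sub[bp_type].to_numpy())
            keep[m] &= np.abs(z) <= bound
    return rows[keep].reset_index(drop=True), rows[~keep].reset_index(drop=True)


def fit_preliminary_model(rows: pd.DataFrame) -> ReferenceModel:
    """Constant-SD model on the unfiltered rows, for the plausibility screen."""
    from .mixed import fit_random_intercept, to_reference_model

    fits = {}
    for sex in ("M", "F"):
        for bp_type in ("sbp", "dbp"):
            fits[(sex, bp_type)] = fit_random_intercept(rows, sex, bp_type)
    return to_reference_model(fits, name="preliminary_random_intercept")


def build_cohort(table: pd.DataFrame, rules=DEFAULT_RULES, plausibility: bool = True,
                 plausibility_bound: float = PLAUSIBILITY_BOUND):
    """Full cleaning pipeline: attrition -> same-day averaging -> plausibility.

    Returns ``(rows, report, removed_rows)`` where ``rows`` is the analysis
    table (one row per child-day) and ``removed_rows`` holds the plausibility
    removals (empty when ``plausibility=False``).
    """
    kept, report = apply_attrition(table, rules)
    rows = average_same_day(kept)
    removed = rows.iloc[0:0]
    if plausibility and len(rows):
        try:
            preliminary = fit_preliminary_model(rows)
        except ValueError as exc:
            warnings.warn(f"plausibility screen skipped: {exc}")
        else:
            rows, removed = plausibility_filter(rows, preliminary, plausibility_bound)
            report.append("bp_plausibility", rows["child_id"].nunique(), len(rows))
    return rows, report, removed
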