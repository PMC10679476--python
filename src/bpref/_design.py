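"""Polynomial design helpers shared by the mixed-effects and quantile models.

The fixed-effect design is an intercept plus first-through-fourth order
polynomials of centred age (``age - 10`` years) and of height Z-score.
Terms are addressed by the canonical names below so that pruned models,
coefficient bundles and fitted results all speak the same vocabulary.
"""

from __future__ import annotations

import numpy as np

AGE_TERMS = ("age1", "age2", "age3", "age4")
HEIGHT_TERMS = ("height1", "height2", "height3", "height4")
#: All non-intercept candidate terms, in canonical order.
POLY_TERMS = AGE_TERMS + HEIGHT_TERMS
#: Terms never removed by backward elimination (linear age and height).
PROTECTED_TERMS = ("age1", "height1")

SEXES = ("M", "F")
BP_TYPES = ("sbp", "dbp")
STRATA = tuple((s, b) for b in BP_TYPES for s in SEXES)


def term_power(term: str) -> int:
    return int(term[-1])


def term_values(term: str, age10, height_z):
    """Evaluate one design column at centred age / height Z."""
    k = term_power(term)
    if term.startswith("age"):
        return np.asarray(age10, dtype=float) ** k
    if term.startswith("height"):
        return np.asarray(height_z, dtype=float) ** k
    raise ValueError(f"unknown design term {term!r}")


def design_matrix(age10, height_z, terms=POLY_TERMS) -> np.ndarray:
    """Intercept-leading design matrix for the given term subset."""
    age10 = np.atleast_1d(np.asarray(age10, dtype=float))
    height_z = np.atleast_1d(np.asarray(height_z, dtype=float))
    cols = [np.ones(np.broadcast(age10, height_z).size)]
    for t in terms:
        cols.append(np.broadcast_to(term_values(t, age10, height_z), cols[0].shape))
    return np.column_stack(cols)


def check_stratum(sex: str, bp_type: str) -> tuple[str, str]:
    sex = str(sex).upper()[:1]
    bp_type = str(bp_type).lower()
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    if bp_type not in BP_TYPES:
        raise ValueError(f"bp_type must be one of {BP_TYPES}, got {bp_type!r}")
    return sex, bp_type
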