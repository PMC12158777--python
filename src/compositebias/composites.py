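"""Composite weight outcomes: BMI, change scores and relative changes.

All composite columns of a cohort are exact algebraic functions of their two
determinants.  Heights are carried in centimetres everywhere in this package;
the BMI computation owns the single cm -> m conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import names as N

RULES = ("bmi", "difference", "relative-difference")


@dataclass(frozen=True)
class CompositeSpec:
    """A named composite: two ordered determinants and a combination rule."""

    name: str
    determinants: tuple[str, str]
    rule: str

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown composite rule {self.rule!r}")
        if len(self.determinants) != 2:
            raise ValueError("a composite has exactly two determinants")

    def compute(self, first, second):
        if self.rule == "bmi":
            return compute_bmi(first, second)
        if self.rule == "difference":
            return change_score(first, second)
        return relative_change(first, second)


#: The six cohort composites.  Determinant order: (weight, height) for BMI,
#: (follow, base) for (relative) change scores.
COHORT_COMPOSITES = (
    CompositeSpec(N.BMI_BASE, (N.WEIGHT_BASE, N.HEIGHT_SELF), "bmi"),
    CompositeSpec(N.BMI_FOLLOW, (N.WEIGHT_FOLLOW, N.HEIGHT_MEASURED), "bmi"),
    CompositeSpec(N.WEIGHT_CHANGE, (N.WEIGHT_FOLLOW, N.WEIGHT_BASE), "difference"),
    CompositeSpec(N.BMI_CHANGE, (N.BMI_FOLLOW, N.BMI_BASE), "difference"),
    CompositeSpec(N.REL_WEIGHT_CHANGE, (N.WEIGHT_FOLLOW, N.WEIGHT_BASE),
                  "relative-difference"),
    CompositeSpec(N.REL_BMI_CHANGE, (N.BMI_FOLLOW, N.BMI_BASE),
                  "relative-difference"),
)


def compute_bmi(weight, height_cm):
    """Body mass index, kg/m^2, from weight in kg and height in cm."""
    weight = np.asarray(weight, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(weight <= 0):
        raise ValueError("weight must be positive (kg)")
    if np.any(height_cm <= 0):
        raise ValueError("height must be positive (cm)")
    out = weight / (height_cm / 100.0) ** 2
    return out if out.ndim else float(out)


def change_score(follow, base):
    """Follow-up minus baseline, in the units of the measure."""
    follow = np.asarray(follow, dtype=float)
    base = np.asarray(base, dtype=float)
    out = follow - base
    return out if out.ndim else float(out)


def relative_change(follow, base):
    """(follow - base) / base; dimensionless. Undefined at base = 0."""
    follow = np.asarray(follow, dtype=float)
    base = np.asarray(base, dtype=float)
    if np.any(base == 0):
        raise ValueError("relative change undefined at baseline value 0")
    out = (follow - base) / base
    return out if out.ndim else float(out)


def add_composite_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach (or refresh) the six composite columns, computed row-wise."""
    out = cohort.copy()
    for spec in COHORT_COMPOSITES:
        a, b = spec.determinants
        out[spec.name] = spec.compute(out[a].to_numpy(), out[b].to_numpy())
    return out


def bmi_variance_shares(
    cohort: pd.DataFrame, height_source: str = "self-report"
) -> dict[str, float]:
    """Decompose var(log BMI) into height, weight and covariance shares.

    log BMI = log weight - 2 log height gives the exact identity
    var(log BMI) = var(log W) + 4 var(log H) - 4 cov(log W, log H); each term
    is returned as a fraction of var(log BMI) (keys ``weight``, ``height``,
    ``covariance``), summing to 1.  The covariance share is negative when
    height and weight are positively correlated, as in human cohorts; under
    independence with 4 var(log H) = 2 var(log W) the height share is 2/3 —
    the familiar rule that BMI variation is about two-thirds height.
    """
    if height_source == "self-report":
        hcol, wcol = N.HEIGHT_SELF, N.WEIGHT_BASE      # baseline BMI
    elif height_source == "measured":
        hcol, wcol = N.HEIGHT_MEASURED, N.WEIGHT_FOLLOW  # follow-up BMI
    else:
        raise ValueError("height_source must be 'self-report' or 'measured'")
    if len(cohort) < 30:
        raise ValueError("need at least 30 records for a variance decomposition")
    h = cohort[hcol].to_numpy(dtype=float)
    w = cohort[wcol].to_numpy(dtype=float)
    if np.any(h <= 0) or np.any(w <= 0):
        raise ValueError("heights and weights must be positive")
    lh, lw = np.log(h), np.log(w)
    var_h, var_w = np.var(lh, ddof=1), np.var(lw, ddof=1)
    cov = np.cov(lw, lh, ddof=1)[0, 1]
    var_bmi = var_w + 4.0 * var_h - 4.0 * cov
    if var_bmi == 0 or (var_h == 0 and var_w == 0):
        raise ValueError("degenerate cohort: log BMI has zero variance")
    return {
        "height": 4.0 * var_h / var_bmi,
        "weight": var_w / var_bmi,
        "covariance": -4.0 * cov / var_bmi,
    }
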