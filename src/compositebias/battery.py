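"""DAG-informed linear-model battery across the six weight outcomes.

For a chosen exposure the battery fits ordinary least squares of each of the
six outcomes (follow-up weight, follow-up BMI, weight change, BMI change,
relative weight change, relative BMI change) on the exposure plus the
DAG-derived adjustment set for follow-up weight.  Baseline BMI is never a
covariate: the graph treats it as fully determined, so baseline height and
baseline weight are adjusted instead.  For birth exposures the adjustment
set contains no baseline body-size variable, because baseline weight mediates
a birth exposure.

Only the follow-up-weight model carries a causal interpretation (conditioning
on baseline weight isolates the part of follow-up weight not determined by
baseline weight); the other five are fitted to exhibit how composite outcomes
mislead.  Flags relative to the reliable reference mark estimates that are
sign-reversed, diluted, or near-null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import names as N
from .dag import COMPOSITE, CausalDag
from .scm import LinearScm, true_effect_by_intervention, true_total_effect

logger = logging.getLogger(__name__)

BIRTH_EXPOSURES = (N.ETHNICITY, N.SEX)
SENSITIVITY_VARIANTS = ("height-source-swap", "no-baseline-adjustment")


@dataclass(frozen=True)
class ModelSpec:
    """One linear model: outcome ~ exposure + covariates."""

    outcome: str
    exposure: str
    covariates: tuple[str, ...]
    height_source: str = "self-report"
    baseline_adjusted: bool = True

    def __post_init__(self) -> None:
        if self.exposure in self.covariates:
            raise ValueError("exposure may not appear among the covariates")
        if self.outcome in self.covariates or self.outcome == self.exposure:
            raise ValueError("outcome may not appear on the right-hand side")


@dataclass(frozen=True)
class TermEstimate:
    coef: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class FitResult:
    """OLS fit: per-term coefficient, SE and 95% t-based confidence interval."""

    spec: ModelSpec
    terms: dict[str, TermEstimate]
    n: int
    resid_var: float
    n_dropped: int = 0

    def term(self, name: str) -> TermEstimate:
        return self.terms[name]

    @property
    def exposure_term(self) -> TermEstimate:
        return self.terms[self.spec.exposure]


@dataclass
class BatteryReport:
    """Six-outcome grid of exposure estimates with optional truth and flags."""

    exposure: str
    covariates: tuple[str, ...]
    results: dict[str, FitResult]
    reference: float | None = None
    flags: dict[str, tuple[str, ...]] = field(default_factory=dict)
    dilution: dict[str, float] = field(default_factory=dict)
    label: str = "adjusted"

    def estimate(self, outcome: str) -> TermEstimate:
        return self.results[outcome].exposure_term

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for outcome in N.BATTERY_OUTCOMES:
            fit = self.results[outcome]
            est = fit.exposure_term
            rows.append({
                "exposure": self.exposure,
                "outcome": outcome,
                "estimate": est.coef,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n": fit.n,
                "covariates": ";".join(fit.spec.covariates),
                "truth": self.reference if self.reference is not None else np.nan,
                "flags": ";".join(self.flags.get(outcome, ())),
                "dilution_ratio": self.dilution.get(outcome, np.nan),
                "label": self.label,
            })
        return pd.DataFrame(rows)


def fit_linear(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Ordinary least squares with homoskedastic t-based 95% CIs.

    Complete-case: rows with a missing required column are dropped and the
    count logged.  A rank-deficient design is rejected naming the collinear
    columns.
    """
    needed = [spec.outcome, spec.exposure, *spec.covariates]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks required columns: {missing}")
    data = cohort[needed].apply(pd.to_numeric)
    complete = data.dropna()
    n_dropped = len(data) - len(complete)
    if n_dropped:
        logger.info("fit_linear(%s ~ %s): dropped %d incomplete rows of %d",
                    spec.outcome, spec.exposure, n_dropped, len(data))
    X = sm.add_constant(complete[[spec.exposure, *spec.covariates]], has_constant="add")
    y = complete[spec.outcome]
    p = X.shape[1]
    if len(complete) <= p:
        raise ValueError(
            f"need more than {p} complete rows to fit {p} terms; have {len(complete)}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # name the columns involved in the dependency
        dep = []
        cols = list(X.columns)
        for j in range(p):
            keep = [k for k in range(p) if k != j]
            if np.linalg.matrix_rank(X.to_numpy()[:, keep]) == rank:
                dep.append(cols[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {dep}")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    terms = {
        name: TermEstimate(
            coef=float(res.params[name]), se=float(res.bse[name]),
            ci_low=float(ci.loc[name, 0]), ci_high=float(ci.loc[name, 1]))
        for name in X.columns}
    return FitResult(spec=spec, terms=terms, n=int(res.nobs),
                     resid_var=float(res.scale), n_dropped=n_dropped)


def battery_covariates(
    dag: CausalDag,
    exposure: str,
    height_source: str = "self-report",
    exclude: frozenset[str] | set[str] = frozenset(),
) -> tuple[str, ...]:
    """DAG-derived covariates for the battery: the adjustment set of the
    exposure for follow-up weight, with the chosen height proxy."""
    prefer = {N.TRUE_HEIGHT: N.HEIGHT_SELF if height_source == "self-report"
              else N.HEIGHT_MEASURED}
    prefer = {k: v for k, v in prefer.items() if k in dag.nodes}
    zset = dag.adjustment_set(exposure, N.WEIGHT_FOLLOW,
                              prefer_proxy=prefer or None, exclude=exclude)
    return tuple(sorted(zset, key=lambda c: (dag.rank(c), c)))


def run_battery(
    cohort: pd.DataFrame,
    exposure: str,
    dag: CausalDag,
    scm: LinearScm | None = None,
    height_source: str = "self-report",
    exclude: frozenset[str] | set[str] = frozenset(),
    truth_n: int = 200_000,
    truth_seed: int = 0,
    flag_se_mult: float = 2.0,
    flag_dilution_ratio: float = 0.75,
    label: str = "adjusted",
) -> BatteryReport:
    """Fit the six-outcome battery for one exposure.

    When an ``scm`` is supplied, the reliable reference (interventional effect
    on follow-up weight: total effect for birth exposures, baseline-conditioned
    — identically the total — effect for post-baseline exposures) is computed
    and bias flags attached.
    """
    if exposure not in dag.nodes:
        raise ValueError(f"unknown exposure {exposure!r}")
    if dag.kind(exposure) == COMPOSITE:
        raise ValueError(
            f"composite variable {exposure!r} cannot be an exposure: its value "
            f"has a one-to-many relationship with its components")
    covariates = battery_covariates(dag, exposure, height_source, exclude)
    results: dict[str, FitResult] = {}
    for outcome in N.BATTERY_OUTCOMES:
        spec = ModelSpec(outcome=outcome, exposure=exposure,
                         covariates=covariates, height_source=height_source,
                         baseline_adjusted=N.WEIGHT_BASE in covariates)
        results[outcome] = fit_linear(cohort, spec)
    report = BatteryReport(exposure=exposure, covariates=covariates,
                           results=results, label=label)
    if scm is not None:
        reference = reliable_reference(scm, exposure, n=truth_n, seed=truth_seed)
        report = bias_flags(report, reference, se_mult=flag_se_mult,
                            dilution_ratio=flag_dilution_ratio)
    return report


def reliable_reference(scm: LinearScm, exposure: str,
                       n: int = 200_000, seed: int = 0) -> float:
    """Ground-truth effect of the exposure on follow-up weight.

    Binary exposures use the 0 -> 1 interventional contrast; continuous
    exposures use exact path tracing.
    """
    if scm.is_binary(exposure):
        eff = true_effect_by_intervention(scm, exposure, 0.0, 1.0, n=n, seed=seed)
        return eff[N.WEIGHT_FOLLOW].value
    if scm.dag.kind(exposure) == "proxy":
        # the proxy's causal content is its latent determinant(s)
        f = scm.dag.formula(exposure)
        return sum(true_total_effect(scm, d, N.WEIGHT_FOLLOW)
                   for d in f.determinants if not scm.is_binary(d))
    return true_total_effect(scm, exposure, N.WEIGHT_FOLLOW)


def bias_flags(
    report: BatteryReport,
    reference: float,
    se_mult: float = 2.0,
    dilution_ratio: float = 0.75,
) -> BatteryReport:
    """Attach sign-reversed / near-null / diluted flags against the reliable reference.

    ``near-null``: |estimate| below ``se_mult`` standard errors;
    ``sign-reversed``: opposite sign to the reference and distinguishable from
    zero; ``diluted``: same sign but magnitude below ``dilution_ratio`` of the
    reference.  A zero reference restricts flagging to near-null.  Thresholds
    are reporting conventions, not estimands.
    """
    flags: dict[str, tuple[str, ...]] = {}
    dilution: dict[str, float] = {}
    for outcome in N.BATTERY_OUTCOMES:
        est = report.results[outcome].exposure_term
        row: list[str] = []
        if abs(est.coef) < se_mult * est.se:
            row.append("near-null")
        if reference != 0.0:
            dilution[outcome] = est.coef / reference
            if est.coef * reference < 0 and abs(est.coef) >= se_mult * est.se:
                row.append("sign-reversed")
            elif est.coef * reference > 0 and abs(est.coef / reference) < dilution_ratio:
                row.append("diluted")
        flags[outcome] = tuple(row)
    return replace(report, reference=reference, flags=flags, dilution=dilution)


@dataclass(frozen=True)
class EquivalenceReport:
    """Coefficient discrepancies between change-score and follow-up models."""

    exposure_coef_difference: float
    baseline_coef_difference: float
    follow_fit: FitResult
    change_fit: FitResult


def equivalence_check(
    cohort: pd.DataFrame,
    exposure: str,
    baseline: str,
    follow: str,
    covariates: tuple[str, ...],
) -> EquivalenceReport:
    """Change-score and follow-up models with identical right-hand sides.

    With the baseline among the regressors, least squares is invariant to
    translating the outcome by a regressor: every coefficient of the
    change-score model equals its follow-up counterpart, except the baseline
    coefficient which is smaller by exactly 1.  Both discrepancies are
    reported (the second as the raw difference, expected -1).
    """
    if baseline not in covariates:
        raise ValueError(
            "the equivalence identity requires the baseline outcome among the "
            "covariates of both models")
    work = cohort.copy()
    change_col = "__change__"
    work[change_col] = work[follow] - work[baseline]
    follow_fit = fit_linear(work, ModelSpec(follow, exposure, covariates))
    change_fit = fit_linear(work, ModelSpec(change_col, exposure, covariates))
    return EquivalenceReport(
        exposure_coef_difference=(change_fit.term(exposure).coef
                                  - follow_fit.term(exposure).coef),
        baseline_coef_difference=(change_fit.term(baseline).coef
                                  - follow_fit.term(baseline).coef),
        follow_fit=follow_fit,
        change_fit=change_fit,
    )


def sensitivity_battery(
    cohort: pd.DataFrame,
    exposure: str,
    dag: CausalDag,
    variants: tuple[str, ...] = SENSITIVITY_VARIANTS,
    scm: LinearScm | None = None,
    **kw,
) -> list[BatteryReport]:
    """Labeled battery variants: measured-height swap, no baseline adjustment."""
    unknown = [v for v in variants if v not in SENSITIVITY_VARIANTS]
    if unknown:
        raise ValueError(
            f"unknown variants {unknown}; choose from {SENSITIVITY_VARIANTS}")
    reports = []
    for variant in variants:
        if variant == "height-source-swap":
            reports.append(run_battery(
                cohort, exposure, dag, scm=scm, height_source="measured",
                label=variant, **kw))
        else:  # no-baseline-adjustment
            drop = {N.WEIGHT_BASE, N.HEIGHT_SELF, N.HEIGHT_MEASURED}
            reports.append(run_battery(
                cohort, exposure, dag, scm=scm, exclude=drop,
                label=variant, **kw))
    return reports


def plot_battery(frames: pd.DataFrame, path: str | None = None):
    """Forest-style comparison of battery estimates across outcomes/exposures.

    ``frames`` is the tidy output of :meth:`BatteryReport.to_frame` (possibly
    concatenated over exposures).  Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    exposures = list(dict.fromkeys(frames["exposure"]))
    fig, axes = plt.subplots(
        1, len(exposures), figsize=(3.2 * len(exposures), 4.0),
        sharey=True, squeeze=False)
    ypos = np.arange(len(N.BATTERY_OUTCOMES))[::-1]
    for ax, exposure in zip(axes[0], exposures):
        sub = frames[frames["exposure"] == exposure].set_index("outcome")
        sub = sub.loc[list(N.BATTERY_OUTCOMES)]
        ax.errorbar(
            sub["estimate"], ypos,
            xerr=[sub["estimate"] - sub["ci_low"], sub["ci_high"] - sub["estimate"]],
            fmt="o", capsize=3)
        if sub["truth"].notna().any():
            ax.axvline(sub["truth"].iloc[0], color="tab:green", ls=":",
                       label="reliable reference")
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_title(exposure)
        ax.set_yticks(ypos)
        ax.set_yticklabels(N.BATTERY_OUTCOMES)
    fig.suptitle("Exposure estimates across weight outcomes")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
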