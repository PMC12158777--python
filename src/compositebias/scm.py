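"""Linear-Gaussian structural causal model over the cohort DAG.

Each probabilistic continuous node is ``intercept + sum(coef * parent) +
Gaussian noise``; each binary node is generated probit-style, thresholding a
latent Gaussian index ``sum(coef * parent) + N(0,1)``; deterministic nodes
(proxies and composites) are computed exactly from their formulas.  Sampling
is ancestral, vectorised over individuals, and fully determined by the seed.

Ground-truth causal effects come from two independent routes: path-coefficient
tracing (exact in the all-continuous part of the model) and Monte-Carlo
do-interventions with shared exogenous noise across arms (defined for any
node, including binary exposures and composite targets).

Default parameter values are package calibrations chosen to reproduce the
qualitative structure of an adult British cohort followed from age 23 to 33
(men taller/heavier than women, a modest ethnic height gap, strong tracking of
weight over time, small socio-economic and psychological effects).  They are
calibrated, documented values — not estimates from any real dataset.  See
``scripts/calibrate_defaults.py`` for the calibration.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import names as N
from .composites import COHORT_COMPOSITES
from .dag import COMPOSITE, LATENT, PROBABILISTIC, PROXY, CausalDag, ncds_dag


@dataclass
class ContinuousNode:
    """Structural equation of a continuous probabilistic/latent node."""

    intercept: float
    coefs: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0


@dataclass
class BinaryNode:
    """Probit-style binary node: value = 1 iff sum(coef*parent) + N(0,1) > threshold."""

    threshold: float
    coefs: dict[str, float] = field(default_factory=dict)


@dataclass
class LinearScm:
    """Structural equations attached to a :class:`CausalDag`."""

    dag: CausalDag
    continuous: dict[str, ContinuousNode] = field(default_factory=dict)
    binary: dict[str, BinaryNode] = field(default_factory=dict)

    def validate(self) -> None:
        """Raise if parameters do not match the DAG edge set exactly."""
        for node in self.dag.nodes:
            kind = self.dag.kind(node)
            if kind in (PROXY, COMPOSITE):
                if node in self.continuous or node in self.binary:
                    raise ValueError(
                        f"deterministic node {node!r} must not carry free parameters")
                continue
            if node in self.continuous and node in self.binary:
                raise ValueError(f"node {node!r} is both continuous and binary")
            if node not in self.continuous and node not in self.binary:
                raise ValueError(f"probabilistic node {node!r} has no parameters")
            params = self.continuous.get(node) or self.binary[node]
            parents = self.dag.parents(node)
            extra = set(params.coefs) - parents
            if extra:
                raise ValueError(
                    f"node {node!r} has coefficients for non-parents {sorted(extra)}")
            missing = parents - set(params.coefs)
            if missing:
                raise ValueError(
                    f"node {node!r} misses coefficients for parents {sorted(missing)}")
            if node in self.continuous and params.noise_sd < 0:
                raise ValueError(f"node {node!r} has negative noise SD")

    def is_binary(self, node: str) -> bool:
        return node in self.binary

    def with_overrides(self, overrides: dict[str, dict]) -> "LinearScm":
        """Copy with per-node parameter overrides.

        ``overrides`` maps node -> {"intercept"/"noise_sd"/"threshold": value,
        "coefs": {parent: value}}.
        """
        out = copy.deepcopy(self)
        for node, fields_ in overrides.items():
            params = out.continuous.get(node) or out.binary.get(node)
            if params is None:
                raise KeyError(f"override for unknown probabilistic node {node!r}")
            for key, value in fields_.items():
                if key == "coefs":
                    for parent, coef in value.items():
                        if parent not in params.coefs:
                            raise KeyError(
                                f"override {node!r}<-{parent!r} is not a DAG edge")
                        params.coefs[parent] = float(coef)
                elif hasattr(params, key):
                    setattr(params, key, float(value))
                else:
                    raise KeyError(f"unknown parameter {key!r} for node {node!r}")
        return out

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "dag": self.dag.to_dict(),
            "continuous": {
                n: {"intercept": p.intercept, "noise_sd": p.noise_sd,
                    "coefs": dict(sorted(p.coefs.items()))}
                for n, p in sorted(self.continuous.items())},
            "binary": {
                n: {"threshold": p.threshold,
                    "coefs": dict(sorted(p.coefs.items()))}
                for n, p in sorted(self.binary.items())},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LinearScm":
        dag = CausalDag.from_dict(data["dag"])
        continuous = {
            n: ContinuousNode(p["intercept"], dict(p["coefs"]), p["noise_sd"])
            for n, p in data.get("continuous", {}).items()}
        binary = {
            n: BinaryNode(p["threshold"], dict(p["coefs"]))
            for n, p in data.get("binary", {}).items()}
        return cls(dag, continuous, binary)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LinearScm":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
            else json.loads(text)
        return cls.from_dict(data)


@dataclass
class ScenarioConfig:
    """Cohort size, seed and parameter overrides for one simulation run."""

    n: int
    seed: int
    overrides: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size must be at least 2")

    def to_dict(self) -> dict:
        return {"n": self.n, "seed": self.seed, "overrides": self.overrides}

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        return cls(int(data["n"]), int(data["seed"]),
                   data.get("overrides", {}) or {})

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ScenarioConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
            else json.loads(text)
        return cls.from_dict(data)


@dataclass(frozen=True)
class EffectEstimate:
    """Monte-Carlo interventional contrast with its standard error."""

    value: float
    mc_se: float


# --------------------------------------------------------------------------
# default parameterization (package calibration; see scripts/calibrate_defaults.py)
# --------------------------------------------------------------------------

def default_ncds_scenario() -> LinearScm:
    """Default cohort model: a 1958-birth-cohort-like adult population.

    Qualitative targets of the calibration: men ~13 cm taller and heavier
    than women; the non-white group shorter with a modest weight difference;
    follow-up weight tracking baseline weight with coefficient near 1;
    small economic-status and malaise effects on follow-up weight;
    self-report error zero-mean.  The ethnicity coefficients on height and
    weight are additionally calibrated so that a large simulated cohort shows
    the composite-outcome discordance pattern: negative ethnic contrast on
    follow-up weight, near-null on follow-up BMI, positive on change scores.

    Body-size coefficients inside the binary status indices default to zero
    (statuses driven by birth variables and each other only); the DAG edges
    remain, and the coefficients are override hooks — see
    :func:`confounded_malaise_scenario`.
    """
    dag = ncds_dag()
    continuous = {
        N.TRUE_HEIGHT: ContinuousNode(
            intercept=163.0,
            coefs={N.ETHNICITY: -3.0, N.SEX: 13.0},
            noise_sd=6.5),
        N.SELF_REPORT_ERROR: ContinuousNode(intercept=0.0, coefs={}, noise_sd=2.0),
        N.WEIGHT_BASE: ContinuousNode(
            intercept=-45.0,
            coefs={N.TRUE_HEIGHT: 0.65, N.SEX: 6.0, N.ETHNICITY: -1.8},
            noise_sd=8.0),
        N.WEIGHT_FOLLOW: ContinuousNode(
            intercept=1.0,
            coefs={N.WEIGHT_BASE: 0.95, N.TRUE_HEIGHT: 0.06, N.SEX: 1.0,
                   N.ETHNICITY: 1.1, N.ECONOMIC_STATUS: 1.5, N.MALAISE: -1.0},
            noise_sd=5.0),
    }
    binary = {
        # P(non-white) ~ 0.10
        N.ETHNICITY: BinaryNode(threshold=1.2816, coefs={}),
        # P(male) = 0.50
        N.SEX: BinaryNode(threshold=0.0, coefs={}),
        # P(unemployed/inactive) ~ 0.10 in the reference group
        N.ECONOMIC_STATUS: BinaryNode(
            threshold=1.30,
            coefs={N.ETHNICITY: 0.3, N.SEX: -0.1,
                   N.TRUE_HEIGHT: 0.0, N.WEIGHT_BASE: 0.0}),
        # inverted coding: 1 = Normal (~0.89 in the reference group)
        N.MALAISE: BinaryNode(
            threshold=-1.25,
            coefs={N.ETHNICITY: -0.2, N.SEX: 0.1, N.ECONOMIC_STATUS: -0.5,
                   N.TRUE_HEIGHT: 0.0, N.WEIGHT_BASE: 0.0}),
    }
    scm = LinearScm(dag, continuous, binary)
    scm.validate()
    return scm


def confounded_malaise_scenario() -> LinearScm:
    """Default scenario with baseline weight confounding malaise.

    Adds a positive baseline-weight coefficient to the malaise index so that
    heavier individuals are (synthetically) more often classed Normal.  The
    adjusted malaise estimate on follow-up weight stays near the true -1 kg,
    while dropping baseline adjustment pushes the estimate positive —
    the sign-reversal stress case for the sensitivity battery.
    """
    return default_ncds_scenario().with_overrides(
        {N.MALAISE: {"coefs": {N.WEIGHT_BASE: 0.03}}})


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def _draw_noise(scm: LinearScm, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """One standard-normal draw per probabilistic node, in fixed node order."""
    noise = {}
    for node in scm.dag.topological_order():
        if node in scm.continuous or node in scm.binary:
            noise[node] = rng.standard_normal(n)
    return noise


def _propagate(
    scm: LinearScm,
    noise: dict[str, np.ndarray],
    clamp: dict[str, float] | None = None,
) -> pd.DataFrame:
    clamp = clamp or {}
    n = len(next(iter(noise.values())))
    values: dict[str, np.ndarray] = {}
    for node in scm.dag.topological_order():
        if node in clamp:
            values[node] = np.full(n, float(clamp[node]))
        elif node in scm.continuous:
            p = scm.continuous[node]
            v = np.full(n, p.intercept)
            for parent, coef in p.coefs.items():
                if coef != 0.0:
                    v = v + coef * values[parent]
            values[node] = v + p.noise_sd * noise[node]
        elif node in scm.binary:
            p = scm.binary[node]
            idx = noise[node].copy()
            for parent, coef in p.coefs.items():
                if coef != 0.0:
                    idx += coef * values[parent]
            values[node] = (idx > p.threshold).astype(float)
        else:  # deterministic
            f = scm.dag.formula(node)
            dets = [values[d] for d in f.determinants]
            if f.rule == "sum":
                values[node] = np.sum(dets, axis=0)
            else:
                spec = next(
                    (c for c in COHORT_COMPOSITES if c.name == node), None)
                if spec is not None:
                    values[node] = spec.compute(dets[0], dets[1])
                elif f.rule == "difference":
                    values[node] = dets[0] - dets[1]
                elif f.rule == "relative-difference":
                    values[node] = (dets[0] - dets[1]) / dets[1]
                else:  # bmi
                    values[node] = dets[0] / (dets[1] / 100.0) ** 2
    return pd.DataFrame(values)


def simulate(scm: LinearScm, config: ScenarioConfig) -> pd.DataFrame:
    """Ancestral sampling of a cohort table; identical seed, identical table."""
    scm = scm.with_overrides(config.overrides) if config.overrides else scm
    scm.validate()
    rng = np.random.default_rng(config.seed)
    noise = _draw_noise(scm, config.n, rng)
    table = _propagate(scm, noise)
    # present columns in cohort order, latents last
    ordered = [c for c in (*N.PRIMITIVE_COLUMNS, *N.COMPOSITE_COLUMNS)
               if c in table.columns]
    rest = [c for c in table.columns if c not in ordered]
    return table[ordered + rest]


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

def true_total_effect(scm: LinearScm, exposure: str, outcome: str) -> float:
    """Sum over directed paths of edge-coefficient products.

    Exact for continuous exposure and outcome connected through continuous
    nodes.  Coefficients into binary nodes live on the latent-index scale, so
    paths routed through a binary mediator are traced only approximately;
    the interventional oracle is the reference in that case.
    """
    dag = scm.dag
    for node, what in ((exposure, "exposure"), (outcome, "outcome")):
        if dag.kind(node) in (PROXY, COMPOSITE):
            raise ValueError(
                f"{what} {node!r} is deterministic; use true_effect_on_composite "
                f"for composite targets")
    if exposure == outcome:
        raise ValueError("exposure and outcome must differ")

    def coef_into(child: str, parent: str) -> float:
        params = scm.continuous.get(child) or scm.binary.get(child)
        return params.coefs.get(parent, 0.0)

    memo: dict[str, float] = {outcome: 1.0}

    def total_from(node: str) -> float:
        if node in memo:
            return memo[node]
        acc = 0.0
        for child in dag.children(node):
            if dag.kind(child) in (PROXY, COMPOSITE):
                continue
            acc += coef_into(child, node) * total_from(child)
        memo[node] = acc
        return acc

    return total_from(exposure)


def true_effect_by_intervention(
    scm: LinearScm,
    exposure: str,
    low: float,
    high: float,
    n: int = 100_000,
    seed: int = 0,
) -> dict[str, EffectEstimate]:
    """Paired do-intervention contrast per node, scaled by (high - low).

    Two cohorts share all exogenous noise; the exposure is clamped to ``low``
    in one and ``high`` in the other, and every descendant is re-propagated.
    Returns the mean per-node difference divided by (high - low) with its
    Monte-Carlo standard error, for every column except the exposure.
    """
    if low == high:
        raise ValueError("low and high must differ")
    if n < 1000:
        raise ValueError("need at least 1000 Monte-Carlo draws")
    if exposure not in scm.continuous and exposure not in scm.binary:
        raise ValueError(f"{exposure!r} is not a probabilistic node of the model")
    rng = np.random.default_rng(seed)
    noise = _draw_noise(scm, n, rng)
    lo = _propagate(scm, noise, clamp={exposure: low})
    hi = _propagate(scm, noise, clamp={exposure: high})
    span = high - low
    out: dict[str, EffectEstimate] = {}
    for col in lo.columns:
        if col == exposure:
            continue
        diff = (hi[col].to_numpy() - lo[col].to_numpy()) / span
        out[col] = EffectEstimate(
            value=float(diff.mean()),
            mc_se=float(diff.std(ddof=1) / np.sqrt(n)))
    return out


def true_effect_on_composite(
    scm: LinearScm,
    exposure: str,
    composite: str,
    n: int = 100_000,
    seed: int = 0,
    low: float = 0.0,
    high: float = 1.0,
) -> EffectEstimate:
    """Interventional contrast on a composite column.

    A descriptive quantity: a composite's one-to-many relationship with its
    components means this number does not identify any component's causal
    effect — it is reported to *exhibit* that mismatch, not to endorse it.
    """
    if scm.dag.kind(composite) != COMPOSITE:
        raise ValueError(f"{composite!r} is not a deterministic composite node")
    effects = true_effect_by_intervention(scm, exposure, low, high, n=n, seed=seed)
    return effects[composite]
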