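# Methods

## The problem being modelled

A longitudinal cohort measures body size twice (here: self-reported height and
weight at age 23; measured height and weight at age 33) together with birth
variables (ethnicity, sex) and post-baseline exposures (economic status,
malaise). Analysts then regress one of six "weight outcomes" on an exposure:
follow-up weight, follow-up BMI, weight change, BMI change, relative weight
change, relative BMI change. The last five are composites — exact algebraic
functions of two measurements — and a composite value corresponds one-to-many
to component values, so a regression coefficient on a composite outcome does
not, in general, estimate any interventional quantity. This package makes that
failure inspectable: it simulates cohorts whose true effects are known and
shows which analyses recover them.

## Graph model

Nodes carry one of four kinds. *Probabilistic* nodes have their own exogenous
noise; *latent* nodes (true height, self-report error) are probabilistic but
unobserved; *proxy* nodes are observed, fully determined combinations that
include at least one latent (self-reported height = true height + error;
measured height = true height exactly); *composite* nodes are fully determined
by observed variables (the six outcomes above).

Two structural rules are enforced by `CausalDag.validate()`: no edge may enter
a deterministic node except from its declared determinants, and no
deterministic node may feed the probabilistic layer (its causal content is
already carried by its determinants). A deterministic node *may* feed another
deterministic node that declares it — BMI change is determined by the two BMI
values, which are themselves composites; this is bookkeeping inside the
derived layer, not a causal arc, and the "no forward arcs" rule is about arcs
into probabilistic variables.

The factory graph `ncds_dag()` stores an explicit integer temporal rank per
node and connects every probabilistic variable to every later probabilistic
variable (the conservative "possible cause of all future variables"
convention). Economic status precedes malaise: socio-economic position
stabilises earlier and for longer than psychological state.

### Conditioning and identification

d-separation runs on the probabilistic/latent/proxy skeleton; composites are
not conditionable (graphical identification theory does not cover zero-noise
functions of observed variables) and attempts to condition on one are
rejected. Proxies *are* conditionable — they are what an analyst actually has —
and in role classification and backdoor checks a proxy stands in for its
latent determinants: self-reported height confounds wherever true height does.

`adjustment_set()` uses the all-observed-pretreatment-ancestors strategy
(every observed non-descendant of the exposure that is an ancestor of exposure
or outcome), substituting the temporally earliest eligible proxy for a latent
ancestor, rather than a minimal set. This reproduces the analysis sets used in
practice: {ethnicity, sex, self-reported height, baseline weight} for economic
status, plus economic status for malaise, {other birth variable} only for
birth exposures. The returned set is verified against the backdoor criterion
by d-separation on the exposure's-out-edges-removed graph, with proxies in the
conditioning set replaced by their latent determinants — i.e. closure is
verified "up to proxy measurement", which is exactly what adjusting for a
noisy height measure achieves. Strict d-separation cannot hold when only an
error-carrying proxy of a latent confounder is conditioned on; the residual
bias this leaves (attenuation through self-report error) is deliberately part
of the simulation and visible in the height-source sensitivity variant.

By default, birth-variable analyses mutually adjust (the ethnicity model
includes sex and vice versa); this falls out of the pretreatment-ancestors
rule. The other convention is available through the `exclude=` argument.
Deliberate exclusions skip backdoor verification, since they exist precisely
to study what breaks.

## Structural causal model

Continuous nodes follow `value = intercept + Σ coef·parent + σ·ε`,
`ε ~ N(0,1)`. Binary nodes are probit-style: `value = 1{Σ coef·parent + ε >
threshold}`, which keeps the joint distribution tractable and effects
monotone. Deterministic nodes are computed exactly from their formulas.
Sampling is ancestral and vectorised; a `ScenarioConfig` seed fixes all
randomness end-to-end. Noise SDs may be zero (degenerate, for exactness
checks); negative SDs are rejected.

Ground truth is computed two independent ways:

- **Path tracing** (`true_total_effect`): the sum over directed paths of edge
  coefficient products. Exact through continuous nodes; coefficients *into*
  binary nodes live on the latent-index scale, so tracing through a binary
  mediator is approximate. In the default scenario the body-size coefficients
  inside the binary indices are zero, making tracing exact where it is used.
- **Do-interventions** (`true_effect_by_intervention`): two cohorts share all
  exogenous noise, the exposure is clamped to `low`/`high`, descendants are
  re-propagated, and the paired mean difference is scaled by `high − low`.
  Defined for any node (including binary exposures, the 0→1 contrast) and any
  column (including composites, via `true_effect_on_composite` — reported as a
  descriptive quantity, not an endorsed estimand). Paired noise makes the
  Monte-Carlo standard errors very small at moderate n.

### Default parameterization

Defaults are package calibrations, not estimates of any real cohort. Units:
cm, kg. Height: 163 + 13·male − 3·non-white + N(0, 6.5²); self-report error
N(0, 2²) with a config hook for non-zero-mean bias; baseline weight
−45 + 0.65·height + 6·male − 1.8·non-white + N(0, 8²); follow-up weight
1 + 0.95·baseline weight + 0.06·height + 1·male + 1.1·non-white +
1.5·unemployed − 1·normal-malaise + N(0, 5²). Prevalences: non-white ≈ 0.10,
male 0.50, unemployed ≈ 0.10, Normal malaise ≈ 0.89 (malaise is inverted:
1 = Normal).

The ethnicity coefficients on height (−3 cm), baseline weight (−1.8 kg direct)
and follow-up weight (+1.1 kg direct) were calibrated — delta-method sketch
plus a 200 000-person simulation check, shipped as
`scripts/calibrate_defaults.py` — so that a large cohort reproduces the
qualitative discordance pattern: total ethnicity effect on follow-up weight
clearly negative (≈ −2.5 kg), follow-up BMI contrast near zero (the height gap
cancels the weight gap inside the ratio), change-score contrasts positive
(≈ +1.2 kg; the group lighter at baseline gains relatively more). The direct
positive follow-up coefficient is what creates the catch-up; the net effect
remains negative through the height and baseline-weight pathways.

`confounded_malaise_scenario()` adds a +0.03/kg baseline-weight coefficient to
the malaise index — a deliberately synthetic confounding stress case in which
heavier individuals are more often classed Normal — so that dropping baseline
adjustment flips the sign of the malaise estimate (≈ +5 kg versus the true
−1 kg).

### What the generator does and does not emulate

It emulates: the temporal structure, the deterministic composite layer, sex
and ethnicity gaps in body size, strong tracking of adult weight
(coefficient 0.95), self-report measurement error in baseline height, small
binary-exposure effects, and baseline-weight confounding on demand. It does
not emulate: non-linear or time-varying structural equations, skewed or
heavy-tailed anthropometry, informative loss to follow-up, item-level
questionnaire structure behind the binary statuses, or secular trends. Tests
passing here therefore show that the *analytical machinery* behaves as the
theory predicts under a linear-Gaussian cohort; they do not validate any
particular real-world effect size.

## Regression battery

`fit_linear` is ordinary least squares (statsmodels) with homoskedastic
t-based 95% CIs; complete-case with logged drop counts; rank-deficient designs
are rejected naming the collinear columns. Robust standard errors are not the
default anywhere; the literature's caveat that baseline-conditioned models
need care for valid standard errors is noted here and deliberately not
implemented. No multiple-testing adjustment is applied: the object of interest
is effect size, not significance.

`run_battery` fits all six outcomes on the exposure plus the DAG-derived
covariates for *follow-up weight* (never baseline BMI — baseline height and
weight are adjusted instead). Consequences checked by tests: for post-baseline
exposures the follow-up-weight and weight-change estimates are numerically
identical (both adjust baseline weight — the ANCOVA equivalence); for birth
exposures no baseline body-size variable is adjusted, so their change-score
rows are genuinely different, biased quantities.

`bias_flags` compares each outcome's estimate with the single reliable
reference (the interventional effect on follow-up weight): *near-null* if
|estimate| < 2 SE; *sign-reversed* if opposite in sign to the reference and
beyond 2 SE; *diluted* if same-signed but below 0.75 of the reference. The
2-SE and 0.75 thresholds are reporting conventions (configurable), not
estimands; a zero reference restricts flagging to near-null.

## Numerical and design choices

- The BMI variance decomposition is done on the log scale, where
  log BMI = log W − 2 log H makes it exact and additive; the familiar
  "two-thirds height" figure is an approximate population-level statement
  realised exactly under independence with 4 var(log H) = 2 var(log W).
- Heights are stored in cm everywhere; `compute_bmi` owns the single cm→m
  conversion. Non-positive weights/heights and zero baselines for relative
  change are rejected with unit-bearing messages.
- Equivalence check: translating the outcome by a regressor leaves the
  least-squares problem unchanged except for that regressor's coefficient,
  which drops by exactly 1; the check reports both discrepancies and requires
  the baseline among the covariates (the identity is false without it, and a
  test exhibits the counterexample).
- Binary truth is defined on the 0→1 interventional contrast, never on
  latent-index coefficients.
- Composite endpoints cannot be exposures, d-separation endpoints or members
  of conditioning sets; the error messages say why.
- Problem sizes used by the shipped checks: 100 random cohorts (equivalence),
  200 random DAGs of ≤ 6 nodes with every pair/subset query (~15 000 queries,
  against an exhaustive path-enumeration oracle), 500 replicates of n = 5000
  (CI coverage, expected 93–97%), n = 5000 with 200 000-draw truth (battery
  pattern), n = 100 000 (variance decomposition). These run in well under a
  minute each on one CPU.

## Known limitations

- Path tracing through non-degenerate binary mediators is approximate by
  construction; use the interventional oracle there.
- The adjustment-set strategy is maximal-pretreatment, not minimal; with a
  user DAG containing pretreatment colliders it can include unnecessary (but
  harmless under the backdoor check) covariates, and the backdoor verification
  treats proxies as their latents, so residual measurement-error confounding
  is possible and intended.
- External-cohort mode validates structure and encodings, not provenance; the
  real two-sweep cohort data are access-gated and never bundled, so analyses
  of them run only on the user's machine via the mapping recipe.
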