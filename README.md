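# compositebias

Diagnostics for **composite-outcome bias** in longitudinal weight research.

Obesity studies routinely analyse composite outcomes — BMI (weight/height²),
weight change (follow-up − baseline), BMI change, and relative changes — as if
they answered causal questions about body weight. They do not: a composite
value has a one-to-many relationship with its components, so a regression on a
composite outcome mixes the separate causal stories of each component. The
same exposure can look harmful on one weight outcome, null on a second and
protective on a third, in the same cohort. The reliable analysis is the
follow-up measure conditioned on its baseline — for exposures occurring after
baseline, ANCOVA-style adjustment for baseline weight; for birth exposures,
follow-up weight with **no** baseline body-size adjustment (baseline weight is
a mediator there).

`compositebias` packages that argument as runnable machinery:

- **`compositebias.dag`** — causal DAGs with deterministic (fully determined)
  nodes: validation of the composite rules (nothing points into BMI except
  height and weight; BMI feeds nothing), d-separation, covariate-role
  classification (confounder / mediator), and all-observed-pretreatment
  adjustment sets verified against the backdoor criterion. `ncds_dag()` builds
  the study graph for a two-sweep adult cohort (ages 23 and 33) with latent
  true height, a self-reported height proxy, and six composite outcomes.
- **`compositebias.scm`** — a linear-Gaussian structural causal model over that
  DAG. `simulate()` draws cohorts (heights in cm, weights in kg, probit-style
  binaries; malaise coded 1 = Normal); ground truth comes from exact
  path-coefficient tracing and from Monte-Carlo do-interventions with shared
  exogenous noise.
- **`compositebias.composites`** — BMI, change scores, relative changes, and
  the exact log-scale decomposition
  `var(log BMI) = var(log W) + 4 var(log H) − 4 cov(log W, log H)`.
- **`compositebias.battery`** — the six-outcome OLS battery per exposure with
  DAG-derived covariates, the change-score/ANCOVA equivalence check
  (coefficients identical; baseline coefficient shifted by exactly −1),
  sensitivity variants (measured-height swap, no baseline adjustment), and
  bias flags (sign-reversed / diluted / near-null) against the known truth.
- **`compositebias.cohort_io` / CLI** — cohort CSV I/O with a column-mapping
  layer for externally held extracts, plus `compositebias simulate | analyze |
  battery-all | equivalence | report | dag-validate`.

## Worked example

```python
import compositebias as cb
from compositebias import names as N

scm = cb.default_ncds_scenario()          # calibrated synthetic cohort model
dag = cb.ncds_dag()
cohort = cb.simulate(scm, cb.ScenarioConfig(n=5000, seed=11))

report = cb.run_battery(cohort, N.ETHNICITY, dag, scm=scm)
print(report.to_frame()[["outcome", "estimate", "se", "truth", "flags"]].round(3))
```

prints

```
          outcome  estimate    se  truth         flags
    weight_follow    -2.307 0.477 -2.506
       bmi_follow     0.030 0.153 -2.506     near-null
    weight_change     1.201 0.240 -2.506 sign-reversed
       bmi_change     0.534 0.090 -2.506 sign-reversed
rel_weight_change     0.025 0.004 -2.506 sign-reversed
   rel_bmi_change     0.025 0.004 -2.506 sign-reversed
```

One cohort, one exposure, six answers. The follow-up-weight estimate (−2.31 kg,
the only unflagged row) matches the interventional truth (−2.51 kg): the
non-white group is genuinely lighter at follow-up. Follow-up BMI is near-null —
the group's shorter stature cancels its lower weight inside the ratio — and
every change-score outcome is *positive* (the group starting lighter gains
relatively more), sign-reversed from the truth. A reader of any composite row
would conclude the opposite of what an intervention would show.

The `examples/` directory holds one short script per capability (DAG roles,
simulation, the battery, the equivalence identity, sensitivity analyses, the
BMI variance split). For an externally held cohort extract, edit
`examples/ncds_mapping.yaml` to your column names/encodings and run
`compositebias battery-all --cohort extract.csv --mapping mapping.yaml
--out battery.csv`.

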