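"""Change-score vs follow-up models: mathematically equivalent under
baseline adjustment.

Regressing (follow - baseline) on X is the same least-squares problem as
regressing follow on X whenever baseline is a column of X: every coefficient
matches, and the baseline coefficient just drops by exactly 1.  The numbers
agree, but only the follow-up model has a causal reading — the equivalence is
why 'weight change' analyses adjusted for baseline weight are really ANCOVA.
"""

import compositebias as cb
from compositebias import names as N

scm = cb.default_ncds_scenario()
dag = cb.ncds_dag()
cohort = cb.simulate(scm, cb.ScenarioConfig(n=5000, seed=13))

covariates = tuple(sorted(dag.adjustment_set(N.ECONOMIC_STATUS, N.WEIGHT_FOLLOW)))
rep = cb.equivalence_check(cohort, N.ECONOMIC_STATUS, N.WEIGHT_BASE,
                           N.WEIGHT_FOLLOW, covariates)

f = rep.follow_fit.term(N.ECONOMIC_STATUS)
c = rep.change_fit.term(N.ECONOMIC_STATUS)
print(f"follow-up weight model:  exposure coef {f.coef:.6f} (SE {f.se:.4f})")
print(f"weight-change model:     exposure coef {c.coef:.6f} (SE {c.se:.4f})")
print(f"exposure coef difference: {rep.exposure_coef_difference:.2e}")
print(f"baseline coef difference: {rep.baseline_coef_difference:.10f}  (exactly -1)")
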