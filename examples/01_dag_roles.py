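"""Build the study DAG, validate it, and derive covariate roles.

Shows how the graph rules for fully determined nodes work (nothing may point
into BMI except height and weight; BMI feeds nothing), and how the DAG
classifies candidate covariates and derives adjustment sets for each exposure.
"""

import compositebias as cb
from compositebias import names as N

dag = cb.ncds_dag()
print("violations in the study DAG:", dag.validate() or "none")

# break the composite rule on purpose: ethnicity may cause height and weight,
# but not BMI
broken = cb.ncds_dag()
broken.add_edge(N.ETHNICITY, N.BMI_BASE)
print("after adding ethnicity -> baseline BMI:", broken.validate())

print("\ncovariate roles for exposure = economic status, outcome = follow-up weight:")
for candidate in (N.ETHNICITY, N.SEX, N.HEIGHT_SELF, N.WEIGHT_BASE, N.MALAISE):
    role = dag.classify_role(N.ECONOMIC_STATUS, N.WEIGHT_FOLLOW, candidate)
    print(f"  {candidate:>16}: {role}")

print("\nDAG-derived adjustment sets (outcome = follow-up weight):")
for exposure in N.BATTERY_EXPOSURES:
    zset = sorted(dag.adjustment_set(exposure, N.WEIGHT_FOLLOW))
    print(f"  {exposure:>16}: {zset}")

# A mediator (malaise) is never in the economic-status set, and birth
# exposures get no baseline body-size covariates: baseline weight mediates
# them, so adjusting it would remove part of the effect being estimated.
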