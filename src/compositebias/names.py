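"""Canonical variable names for the longitudinal weight cohort.

Binary encodings follow the study conventions: ethnicity 0 = White,
1 = Non-white; sex 0 = Female, 1 = Male; economic status 0 = employed or in
full-time education, 1 = unemployed/economically inactive; malaise is
inverted, 1 = Normal, 0 = Depressed. Heights are stored in centimetres,
weights in kilograms.
"""

ETHNICITY = "ethnicity"
SEX = "sex"
TRUE_HEIGHT = "true_height"
SELF_REPORT_ERROR = "self_report_error"
HEIGHT_SELF = "height_self"
HEIGHT_MEASURED = "height_measured"
WEIGHT_BASE = "weight_base"
ECONOMIC_STATUS = "economic_status"
MALAISE = "malaise"
WEIGHT_FOLLOW = "weight_follow"

BMI_BASE = "bmi_base"
BMI_FOLLOW = "bmi_follow"
WEIGHT_CHANGE = "weight_change"
BMI_CHANGE = "bmi_change"
REL_WEIGHT_CHANGE = "rel_weight_change"
REL_BMI_CHANGE = "rel_bmi_change"

#: The six outcome columns of the model battery, in reporting order.
BATTERY_OUTCOMES = (
    WEIGHT_FOLLOW,
    BMI_FOLLOW,
    WEIGHT_CHANGE,
    BMI_CHANGE,
    REL_WEIGHT_CHANGE,
    REL_BMI_CHANGE,
)

#: Composite columns every cohort table carries.
COMPOSITE_COLUMNS = (
    BMI_BASE,
    BMI_FOLLOW,
    WEIGHT_CHANGE,
    BMI_CHANGE,
    REL_WEIGHT_CHANGE,
    REL_BMI_CHANGE,
)

#: Primitive (non-derived) cohort columns.
PRIMITIVE_COLUMNS = (
    ETHNICITY,
    SEX,
    HEIGHT_SELF,
    HEIGHT_MEASURED,
    WEIGHT_BASE,
    ECONOMIC_STATUS,
    MALAISE,
    WEIGHT_FOLLOW,
)

#: Variables that can play the exposure role in the battery.
BATTERY_EXPOSURES = (
    ETHNICITY,
    SEX,
    HEIGHT_SELF,
    WEIGHT_BASE,
    ECONOMIC_STATUS,
    MALAISE,
)
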