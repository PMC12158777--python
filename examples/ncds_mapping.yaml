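# Column-mapping template for an externally held longitudinal cohort extract
# (e.g. a UK Data Service birth-cohort extract with sweeps at ages 23 and 33).
#
# Edit the right-hand sides to match your CSV's column names and observed
# levels, then run:
#
#   compositebias battery-all --cohort your_extract.csv \
#       --mapping examples/ncds_mapping.yaml --out battery.csv
#
# Canonical conventions: heights in cm (declare 'm' below if recorded in
# metres), weights in kg; ethnicity 0=White 1=Non-white; sex 0=Female 1=Male;
# economic status 0=employed/full-time education 1=unemployed/inactive;
# malaise is inverted: 1=Normal (score 0-7), 0=Depressed (score 8-24).
columns:
  ethnicity: ethnic_group
  sex: sex_at_birth
  height_self: height_self_report_23
  height_measured: height_measured_33
  weight_base: weight_23
  weight_follow: weight_33
  economic_status: economic_activity_23
  malaise: malaise_group_23
encodings:
  ethnicity: {"white": 0, "non-white": 1}
  sex: {"female": 0, "male": 1}
  economic_status: {"employed": 0, "inactive": 1}
  malaise: {"normal": 1, "depressed": 0}
height_unit: cm
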