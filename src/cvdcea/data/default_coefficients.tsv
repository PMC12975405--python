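# source: cvdcea-default-cloglog-cvd
# version: 1.0
# horizon_years: 10
# note: proportional-hazards (complementary log-log) risk functions over the
# note: seven health-assessment factors. Per-event intercepts are calibrated so
# note: that the male/no-diabetes counterfactual reference profile (age 66.2,
# note: cholesterol 162 mg/dL, SBP 141 mmHg, medication 6%, smoking 27%)
# note: reproduces published annual first-event probabilities
# note: (stroke 0.0070, MI 0.0090, CHF 0.0100, non-CVD death 0.0198).
event_type	factor	coefficient
stroke	intercept	-10.188750
stroke	age	0.060
stroke	male	0.30
stroke	total_cholesterol	0.0020
stroke	diabetes	0.60
stroke	smoker	0.50
stroke	sbp	0.020
stroke	on_htn_medication	-0.30
mi	intercept	-9.533029
mi	age	0.048
mi	male	0.55
mi	total_cholesterol	0.0060
mi	diabetes	0.55
mi	smoker	0.70
mi	sbp	0.016
mi	on_htn_medication	-0.25
chf	intercept	-8.534064
chf	age	0.055
chf	male	0.35
chf	total_cholesterol	0.0010
chf	diabetes	0.75
chf	smoker	0.45
chf	sbp	0.014
chf	on_htn_medication	-0.20
death	intercept	-8.067006
death	age	0.085
death	male	0.40
death	total_cholesterol	0.0
death	diabetes	0.40
death	smoker	0.55
death	sbp	0.002
death	on_htn_medication	0.0
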