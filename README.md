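# cvdcea

Markov cohort cost-utility modelling of cardiovascular risk-factor change in
an older, community-dwelling population.

Community wellness programs for older adults (nurse coaching, blood-pressure
medication support, smoking cessation) change measurable cardiovascular risk
factors — systolic blood pressure (SBP), antihypertensive-medication use,
smoking — but their payoff arrives as events that never happen. `cvdcea`
quantifies that payoff with a five-state annual-cycle Markov cohort model
(healthy, stroke, myocardial infarction, congestive heart failure, death;
death absorbing, one cardiovascular event per lifetime) and compares an
*intervention* scenario built from observed exit risk factors against a
*counterfactual* that freezes the factors at baseline except for a projected
+12 mmHg SBP rise. It is written for health-economics analysts who need a
transparent, fully configurable pipeline rather than a spreadsheet.

## Model

Annual first-event probabilities come from multi-year risk functions in the
Framingham tradition. The packaged default uses a proportional-hazards form
with a complementary log-log link over the seven health-assessment factors
(age, sex, total cholesterol, diabetes, smoking, SBP, medication use):

```
R_t(x) = 1 − exp(−exp(β₀ + βᵀx)),      p_annual = 1 − (1 − R_t)^(1/t)
```

where the second step is the constant-hazard conversion of a t-year risk to
a one-year transition probability. The healthy row of the transition matrix
is assembled from the four annual event probabilities with the
stay-probability as their complement; post-event rows are configurable
stratum-independent inputs. Cohort occupancy `π_t` evolves as
`π_{t+1} = π_t P`, and discounted quality-adjusted life years accumulate as

```
QALY = Σ_{t=0}^{T−1} (π_t · u) (1 + r)^{−t}
```

with utilities `u = (0.85, 0.65, 0.70, 0.60, 0)` over the five states,
horizon `T = 20` years and discount rate `r = 3%` by default. Costs combine a
program-cost build-up from per-panel line items (33% fringe on wages, 10%
indirect on direct costs, 100 participants per panel → $1215 per
participant-year), state maintenance costs, acute-event transition costs and
a mortality cost; incremental cost-effectiveness ratios (ICER, cost per QALY
or life-year gained) compare the two scenarios per sex × diabetes stratum.

Because only stratum means and proportions of the underlying population are
public, a seeded synthetic-cohort generator reproduces the four published
strata (n = 1395 / 581 / 3091 / 1087) so the whole pipeline runs end to end
with no restricted data.

## Worked example

```sh
cat > demo.yaml <<'EOF'
schema_version: 1
seed: 7
cohort: {n_per_stratum: 2000}
costs: {allow_placeholder: true}
EOF
cvdcea run --config demo.yaml --seed 7 --out demo_out
```

`demo_out/table_results.tsv` then contains (excerpt):

```
	Base male	Male diabetes	Base female	Female diabetes
Discounted QALY with intervention	9.9	8.0	10.4	9.4
Discounted QALY without intervention	9.4	7.4	10.0	8.8
Gain in discounted QALYs	0.4	0.6	0.4	0.6
Incremental cost	$-1,051	$-970	$-956	$-1,434

# warning: cost schedule is a synthetic placeholder; totals are illustrative only
```

Reading: for 2000 synthetic male participants without diabetes, the observed
risk-factor improvements buy 0.4 discounted QALYs each over 20 years. The
negative incremental cost (intervention cheaper) is an artefact of the
bundled *placeholder* healthcare cost schedule — the literature-derived state
and event costs behind the published analysis are not public, so the shipped
schedule is a clearly flagged synthetic stand-in and every run that uses it
carries the warning shown above. Supply your own `costs.schedule` block for
real cost conclusions. The program-cost build-up, by contrast, is exact:
`cvdcea program-cost --out costs.tsv` reproduces every subtotal down to the
$1215 average per-participant cost.

The same library surface is available in Python
(`cvdcea.run_pipeline`, `cvdcea.build_transition_matrix`,
`cvdcea.run_cohort`, `cvdcea.icer`, …).

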