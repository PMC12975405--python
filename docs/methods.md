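# Methods

## Model structure

The model is a discrete-time Markov cohort simulation over five mutually
exclusive states: healthy, stroke, myocardial infarction (MI), congestive
heart failure (CHF), and death. Cycles are one year, the default horizon is
20 cycles, and the cohort starts entirely healthy. Death is absorbing. The
structural mask permits healthy → {any state}, stroke → {stroke, MI, CHF,
death}, MI → {MI, CHF, death} and CHF → {CHF, death}; no state returns to
healthy and no second stroke/MI occurs (a single-event model, which biases
effect estimates conservatively). The stroke → MI edge is permitted because
the published worked matrix contains it, although narrative descriptions of
such models often exclude it; the mask is configuration, not hard-coded.

## Risk functions

Annual first-event probabilities for the healthy row are derived from
multi-year risk functions evaluated at a stratum-average profile of seven
factors: age (years), sex, total cholesterol (mg/dL), diabetes, smoking,
systolic blood pressure (SBP, mmHg) and antihypertensive-medication use.
Binary factors are entered as cohort proportions, so the matrix describes an
average cohort member — one matrix per stratum and scenario, as in published
worked examples of this model class.

Coefficient sets are versioned, delimited-text parameter files the engine
treats as opaque. The packaged default is an own-authored proportional-
hazards table with a complementary log-log link,
`R_10(x) = 1 − exp(−exp(β₀ + βᵀx))`; it is **not** a transcription of any
published Framingham function, because the widely used general-CVD functions
require HDL cholesterol, which the health assessment modelled here does not
collect. Relative effects (per-unit log-hazards) are plausible
literature-scale values; the per-event intercepts are calibrated so that the
male/no-diabetes counterfactual reference profile (age 66.2, cholesterol
162 mg/dL, SBP 141 mmHg, 6% medicated, 27% smoking) reproduces the published
annual baseline probabilities (stroke 0.0070, MI 0.0090, CHF 0.0100,
non-CVD death 0.0198). Any other coefficient file with the same row format
can be substituted per event.

One deliberate deviation from the Framingham coefficient tradition: the
medication-use coefficient is *negative* (protective) for the three CVD
events. Published risk functions give treated blood pressure a slightly
higher coefficient because treatment marks diagnosed hypertension; in this
package's scenario logic, however, the medication-uptake increase is part of
the intervention effect and must lower risk, which matches how the effect is
described in the source analysis. Users who disagree can supply their own
table.

The 10-year risk is converted to an annual probability by the constant-
hazard formula `p = 1 − (1 − R)^(1/t)` — the standard actuarial choice; the
conversion is exact (its inverse reproduces the input to 1e-12 for horizons
of a year or more). Probabilities are clamped to [0, 1] after conversion
with a logged warning, never silently.

## Scenarios

* **Intervention**: exit medication and smoking proportions, exit
  cholesterol, and *baseline* SBP (the observed population showed no SBP
  deterioration; no exit SBP is published).
* **Counterfactual**: all factors frozen at baseline except SBP, which uses
  the projected no-intervention value (baseline + 12 mmHg, the published
  "estimated SBP" rule). Age is the entry age in both scenarios; the default
  matrix is time-homogeneous, evaluated once at entry age, matching the
  single published worked matrix.

## Matrix validation

Published post-event rows do not all sum to 1 (the healthy row of the worked
matrix leaves 0.0485 unexplained and the stroke row 0.3254 — possibly an
unprinted post-stroke state, possibly typos). Matrices therefore pass an
explicit validation step with four policies: `error` (reject), `renormalize`
(divide by the row sum; the default, with a mandatory logged warning),
`residual_to_self` (add the residual to the diagonal, honouring printed
stay-probabilities), and `residual_to_extra_state` (route residual mass to a
declared auxiliary state, e.g. `post_stroke`, which persists and carries
zero utility unless configured otherwise). After validation every row sums
to 1 within 1e-9. The published discounted counterfactual QALY total of 6.1
for males without diabetes is bracketed by these conventions (9.47 under
residual-to-self, 9.30 under renormalize, 6.76 under residual-to-extra-state
with cycle-start rewards); since the convention behind the published total
is unstated, the engine reports these as flagged diagnostics rather than
asserting any one of them.

## Rewards and discounting

Reward timing is explicit and configurable: `cycle-start` (default;
occupancy at the beginning of cycle *t* earns that cycle's reward,
discounted by `(1+r)^−t`, so the first cycle is undiscounted), `cycle-end`
(end-of-cycle occupancy, exponent `t+1`), and `half-cycle` (the mean of the
two accruals). Life-years count all non-death mass; QALYs weight occupancy
by state utilities (defaults 0.85 / 0.65 / 0.70 / 0.60 / 0; death exactly
0). The discount rate defaults to 3%/year. Occupancies are kept at full
floating precision; rounding happens only at report time. An independent
closed-form oracle (matrix powers applied to the start distribution) must
agree with the iterative engine to 1e-9; the test and acceptance suites
check this on 1000 random structurally valid matrices.

## Costs

The program-cost build-up follows the published arithmetic: fringe =
33% × wages, personnel = wages + fringe, direct = personnel + operating,
indirect = 10% × direct, per-participant = total / 100. The fringe line is
rounded to the whole dollar before aggregation (payroll convention,
configurable via `round_fringe_to_dollar`); with that convention every
published subtotal is reproduced exactly, including the $11,042.40 indirect
line and the $1215 per-participant average. (The published grand total of
$121,467 is sixty cents above the computed 121,466.40 and appears to be 100
× the rounded per-participant cost; it is not asserted.) All other currency
arithmetic is unrounded internally; display rounding is round-half-up to the
nearest dollar.

Healthcare costs per cycle are: occupancy × annual state maintenance cost +
transition flows × acute-event cost (+ a mortality cost on flows into
death) + alive mass × program cost per participant-year, discounted under
the engine's reward-timing convention. Program cost accrues per
participant-year alive by default; one-time and fixed-horizon modes exist
because the accrual convention of the source analysis is ambiguous. The
state/event cost values behind the published analysis were drawn from
literature sources and never printed, so the shipped schedule is a
synthetic placeholder: it is flagged as such, every run using it logs a
warning into the report footer, and the pipeline refuses it unless the
config sets `costs.allow_placeholder: true`.

ICERs divide incremental cost by incremental effect only when the effect
gain is positive; a positive cost with no gain is flagged
`dominated_or_undefined` and a non-positive cost with non-positive gain
`cost_saving`, never a raw division error. Of the eight published
incremental-cost ÷ gain ratios, seven reproduce the printed ICERs to the
nearest dollar; the female-diabetes cost-per-QALY computes to $4939 against
a printed $4938 and is documented rather than asserted. The long-term-care
break-even helper returns incremental cost / (monthly LTC cost × stay
months); with the published inputs ($8344; $2540/month) a single ~3.3-month
avoided stay fully offsets the incremental cost. The published "8.2
percentage points" break-even figure is not derivable from the printed
inputs and is not asserted.

## Synthetic cohorts

The generator emulates the four sex × diabetes strata of the study
population (n = 1395 / 581 / 3091 / 1087; total 6154) from their published
means and proportions. Continuous variables are truncated normals centred at
the stratum mean (age within [18, 110], SBP [70, 260], cholesterol
[80, 400]); no dispersions are published, so the defaults — age SD 8 y, SBP
SD 15 mmHg, cholesterol SD 35 mg/dL — are plausible population values chosen
once and fully configurable. Binary exit states move one-directionally
(smokers may quit, non-smokers never start; medication may start, never
stop), with conditional rates chosen so expected exit proportions hit the
targets exactly. Exit cholesterol is the baseline draw shifted by the
stratum mean change, preserving within-person correlation; exit SBP and age
are carried from baseline (the model consumes entry age, and enrollment
tenure is deliberately not modelled). One master seed spawns per-stratum
substreams keyed by (sex, diabetes), so adding or removing a stratum leaves
the others' draws byte-identical.

What the generator does *not* emulate: real covariance between risk factors
(a smoker's SBP distribution equals a non-smoker's), attrition and
enrollment dynamics, within-person longitudinal trajectories beyond two
timepoints, and any non-normal tail behaviour. Passing recovery tests
therefore demonstrates that the pipeline correctly propagates stratum-level
summaries — not that it would be unbiased on individual-level data with
realistic dependence structure.

## Problem sizes and numerical choices

The test suite runs the engine/oracle comparison on 1000 random matrices,
recovery on 100 seeds × 2000 records per stratum, and the full pipeline on
the published stratum sizes (6154 participants); the whole suite completes
in seconds. Tie and degenerate handling: zero-dispersion generation is exact
(no sampling), proportion targets of 0 or 1 produce deterministic binary
states, risk = 1 annualizes to 1, and a horizon of 1 cycle with cycle-start
rewards earns exactly the starting distribution's reward.

## Known limitations

Stratum-average (cohort-level) matrices ignore risk heterogeneity within
strata, which convexity of the risk function would otherwise surface; the
aging of the cohort over the horizon is off by default (time-homogeneous
matrix at entry age); utilities are time-invariant; no probabilistic
sensitivity analysis is implemented (the configuration surface leaves room
for a harness but none ships); and with the placeholder cost schedule all
cost outputs are illustrative only.
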