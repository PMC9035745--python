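# Methods

This note documents the models, conventions, and design choices behind
`afcea`, in the order the pipeline runs them.

## Synthetic claims generator

The generator emulates a national health-insurance extract: a patient table
(sex, birth date, death date), a visit table (date, ICD-10 code,
admission/outpatient setting, a brain-imaging flag), and a prescription
table (date, drug). It exists so that cohort construction, event detection
and incidence estimation can be validated against known truth; it is
first-class, tested code, not a test fixture.

**Study calendar.** All windows are half-open `[start, end)`. Defaults:
washout 2015-08-01 → 2016-08-01, enrollment 2016-08-01 → 2019-08-01.
Index dates are drawn at least 30 days into enrollment and early enough
that every patient has at least `followup_years` (default 2) of potential
follow-up; events are simulated through the study end regardless.

**Risk structure.** A configurable fraction (default 0.8) of patients is
constructed to sit exactly at the intermediate-risk threshold — men with
CHA₂DS₂-VASc 1, women with 2 — via either an age point (65–74, no
comorbidities) or exactly one single-point comorbidity at age < 65. The
rest draw age uniformly (optionally triangular around `age_mean`) and
comorbidities independently at the configured prevalences, so the risk
filter has genuine work to do. A small fraction (default 3%) additionally
receives an AF visit inside the washout year to exercise criterion 1.
Comorbidity visit dates are clipped to `[max(index − 365 d, enrollment
start), index)` so that lookback codes never leak into the washout year.

**Events.** Each patient-year is a categorical draw over the five event
types (at most one event per year, matching the estimator's counting
unit); the final partial year scales each probability by its length
fraction so fractional person-years remain unbiased. Events are emitted as
admissions with the corresponding ICD-10 code, strokes and intracranial
hemorrhages with the imaging flag set. A fatal draw (per-event case
fatality) places the death date within 30 days of the admission; dead
patients generate no further records.

**Default rates.** Per-drug ischemic-stroke probabilities default to the
published score-1 stratum estimates (0.75/1.07/1.50/4.55/1.33 %/yr for
warfarin, rivaroxaban, apixaban, dabigatran, edoxaban). The other events
are not published per drug; the package defaults — HF 4 %, MI 0.4 %,
ICH 0.15 %, GI 0.6 %/yr, equal across drugs — were chosen once to mirror
the relative magnitudes of the published event-count denominators
(HF 1,223, MI 61, IS 92, ICH 8, GI 54 events in a ~8,000-patient cohort).
Case-fatality defaults are the published raw-count ratios.

**What the generator does not emulate:** dose and adherence dynamics,
seasonality, miscoding, care-seeking correlation between comorbidity and
event ascertainment, deaths outside event admissions, and realistic fee
schedules. Passing recovery tests therefore demonstrates estimator
correctness under clean ascertainment, not robustness to real-world
coding noise.

## Cohort construction

Criteria are applied in a fixed order, each exclusion attributed to the
first failing criterion: (1) washout — any AF or outcome-event code in
the washout year; (2) index — first AF admission or second AF outpatient
visit inside enrollment, whichever is earlier; (3) age ≥ 18 at index
(completed years), at least one anticoagulant prescription, and exclusion
of patients prescribed both warfarin and a DOAC ("switchers"); (4) the
intermediate-risk filter keeps exactly (male, score 1) and (female,
score 2).

CHA₂DS₂-VASc scoring uses diagnosis codes in `[index − 365 d, index)`:
hypertension I10–I13, I15; heart failure I50; prior stroke I60–I64
(2 points); vascular disease I21, I22, I70, I71; age 65–74 → 1 point,
≥ 75 → 2 (mutually exclusive, the standard resolution of the boundary);
female sex → 1 point. Diabetes scores a point but has no published code
row; the package defaults to the conventional E10–E14 prefix set,
overridable in the code map.

## Incidence and case fatality

Outcome events are detected per index-anniversary year under "admission
≥ 1 or outpatient ≥ 2", with at least one matching visit flagged for brain
imaging required for IS/ICH; however often codes recur within a year, one
event of each type is counted. The event date is the date the rule was
met (first admission or second outpatient visit). Annual incidence per
(drug, score, event) divides first events by person-years at risk:
patients contribute whole years up to the first event of that type, death
or follow-up end, a partial final year contributing its fraction. Case
fatality divides deaths within 30 days of the event date by all detected
events of that type; the 30-day proxy stands in for unmodelled discharge
dates. Displayed percentages truncate toward zero at two decimals,
matching the convention evident in the source fatality table (4/1,223 →
0.32 %); full precision is kept internally.

## Markov cohort model

Seven states: healthy-with-AF, GI-bleed tunnel, post-HF, post-MI,
post-IS, post-ICH, death. From healthy, event `E ∈ {HF, MI, IS, ICH}`
moves `p_E(1−f_E)` to its post state and `p_E·f_E` to death; GI bleeding
moves `p_GI` into a one-cycle tunnel that returns `1−f_GI` to healthy.
Under the default `fatality_mode="annual_post_state"` the event's case
fatality also acts as the annual post-state death probability — the only
mortality figure the parameter tables provide; `acute_only` confines
death to the event year. There is no background (age-related) mortality.

Rewards attach to end-of-cycle occupancy, discounted by `(1+r)^−t` with
no half-cycle correction. Per cycle: every alive state accrues the annual
medication cost; the *incident* event fraction (including acute deaths,
who were hospitalized) is charged the per-event admission cost once; post
states accrue an annual post-event cost; utilities are the treatment-state
utility in healthy, the event-state utility in post states and the GI
tunnel. `utility_mode="multiply"` multiplies event-state utilities by the
treatment utility instead of replacing it. Post-event annual costs are
derived by subtraction from unpublished totals in the source analysis, so
the library defaults them to zero with a warning; the demo configuration
ships plausible nonzero placeholders (HF 1,500, MI 1,200, IS 2,400,
ICH 3,000 $/yr) because tornado diagrams are uninformative without them.

**A structural caveat.** Post-event states absorb: their occupants face
no further events. When an event has zero case fatality (MI, 0/61 in the
source counts), its post state becomes a sanctuary from all competing
hazards, and at high event probabilities total QALYs can *rise* with that
event's rate. QALY monotonicity in an event probability is therefore a
theorem only for single-hazard settings or events with excess mortality;
the test suite checks it in exactly that domain and documents the MI
shielding effect explicitly.

## CEA arithmetic

ICER = ΔCost/ΔQALY versus the reference (warfarin), with quadrant
classification: dominant (cheaper, more effective), dominated (costlier,
less effective), equal-effect decided by cost sign, and the south-west
quadrant judged by incremental net monetary benefit. Negative ratios are
never reported as bare ICERs — they always carry their dominance label,
since the same negative number can mean dominance or domination. NMB =
QALY × WTP − cost at WTP $32,000/QALY. The efficiency frontier (an
extension beyond the pairwise-vs-warfarin primary report) removes
strictly then extendedly dominated strategies and reports sequential
ICERs.

## Sensitivity analysis

**PSA.** Probabilities draw from Beta distributions — Jeffreys counts
(events + ½, n − events + ½) where raw counts exist, otherwise moment
fits; costs and treatment-state utilities draw from moment-fit Gamma
(shape 1/CV², scale mean·CV²), treatment utilities capped at 1.0 with cap
hits logged. No dispersion is published for costs or utilities, so the
package defaults are CV 0.2 for costs and event-state utilities and CV
0.005 for treatment-state utilities — the latter because those utilities
differ by only ~0.01–0.03 across anticoagulants and a 0.2 CV would imply
implausible treatment-state values below 0.7 with near-permanent cap
activation. All strategies share one parameter draw per iteration
(common random numbers), matching per-iteration comparison semantics;
draws whose event probabilities sum above 1 for any drug are rejected,
redrawn and counted (< 1 % under realistic inputs, ~0 in practice).
CEACs report both the pairwise probability of beating warfarin on NMB
(the headline, matching the published percentages, which exceed 100 %
summed) and the multi-way probability of being optimal (sums to 1); ties
split evenly. The default WTP grid is 0–100,000 by 1,000, always
including 32,000.

**DSA.** Each parameter is set to the 2.5th and 97.5th percentile of its
PSA distribution (±25 % for fixed parameters) holding the rest at base
case; the tornado records the induced ICER range per comparator, with the
incremental-NMB range as tie-breaker and fallback when a bound flips
dominance. Under the demo configuration the comparator's medication cost
produces the widest bar for rivaroxaban, apixaban and edoxaban; for
dabigatran — whose incremental QALY versus warfarin is smallest, making
its ICER hypersensitive — the warfarin stroke rate ranks first instead.

## Demo configuration

`demo_parameters()` (and `src/afcea/data/demo_params.yaml`) combine the
published utilities, medication costs, event costs and fatality counts
with the score-2 stroke-rate stratum (warfarin 1.52 %/yr versus 0.53–
0.64 %/yr under DOACs), which reproduces the published direction of
effect — DOACs more effective at higher drug cost; the score-1 stratum
would invert it. Incidence Beta counts assume 4,000 person-years per drug
cell (≈ 8,000 patients × ~2.3 years / 5 drugs). Because the post-event
costs and dispersion inputs are reconstructions, absolute demo outputs
are illustrative; the published base-case totals are not reproducible
without the unpublished supplementary inputs, and the package instead
verifies the published table's internal arithmetic.

## Problem sizes and numerics

The test suite and acceptance script use: 20,000-patient generator runs
(3 seeds) for parameter recovery against exact binomial 95 % intervals;
3 × 10,000-walker microsimulations pooled per strategy for trace
validation (within 3 SE per cycle and state); 10,000 random parameter
sets for row-stochasticity (tolerance 1e-12); 10,000 random pairs for
NMB/ICER decision equivalence; 1,000 random 5-strategy sets against a
brute-force frontier oracle; 2,000-iteration PSAs in the acceptance
script (the CLI default remains 10,000). Occupancy conservation is
enforced at 1e-9 per cycle. Seeds derive from one root seed via
`numpy.random.SeedSequence` splitting, and identical configuration plus
seed reproduces byte-identical outputs and manifests.
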