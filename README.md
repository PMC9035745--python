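# afcea — anticoagulant cost-effectiveness in atrial fibrillation

`afcea` is a reusable, fully tested implementation of a claims-based
cost-effectiveness analysis of direct oral anticoagulants (DOACs:
rivaroxaban, apixaban, dabigatran, edoxaban) versus warfarin in
non-valvular atrial-fibrillation (AF) patients at **intermediate stroke
risk** — CHA₂DS₂-VASc score 1 in men or 2 in women. It is written for
health-economics and pharmacoepidemiology researchers who want every stage
of such an analysis — cohort phenotyping, parameter estimation, the
decision model, and its sensitivity analyses — as inspectable, seedable
Python rather than a spreadsheet or a proprietary modelling tool.

The package covers the whole chain:

1. **Synthetic claims generator** (`afcea.synthetic`) — patients, dated
   ICD-10 visit records, and prescriptions with *known* ground-truth event
   rates, so every downstream stage is testable without access to any real
   national claims database.
2. **Cohort builder** (`afcea.cohort`) — one-year washout, the
   index-date rule (first AF admission or second AF outpatient visit),
   adult new users of exactly one anticoagulant class, and CHA₂DS₂-VASc
   scoring from ICD-10 history with the intermediate-risk filter.
3. **Event incidence** (`afcea.incidence`) — composite-outcome detection
   (heart failure, myocardial infarction, ischemic stroke, intracranial
   hemorrhage, gastrointestinal bleeding; admission ≥ 1 or outpatient ≥ 2,
   brain imaging required for strokes), annual incidence per drug and
   score stratum, and in-hospital case fatality.
4. **Markov cohort model** (`afcea.markov`) — seven states (healthy with
   AF, a one-cycle GI-bleed tunnel, four post-event states, death),
   one-year cycles, 20-cycle horizon, 4.5 %/yr discounting.
5. **CEA arithmetic** (`afcea.cea`) — ICERs with dominance classification,
   net monetary benefit, and an efficiency frontier.
6. **Sensitivity analysis** (`afcea.sensitivity`) — one-way deterministic
   (tornado) analysis and probabilistic sensitivity analysis with
   Beta/Gamma parameter distributions, cost-effectiveness acceptability
   curves, and scatter export.

## The model

For each strategy the healthy-with-AF cohort faces annual event
probabilities `p_E`; each event either kills acutely with case fatality
`f_E` or moves the patient to an absorbing post-event state (GI bleeding
instead passes through a one-year tunnel back to health). Discounted
cost and quality-adjusted survival accumulate per cycle `t = 1..20`:

    QALY  = Σ_t (1+r)^-t · Σ_s u(s) · occ_t(s)
    Cost  = Σ_t (1+r)^-t · [ c_med · alive_t + Σ_E c_E · incident_E,t
                             + Σ_E c_post,E · occ_t(post_E) ]

with `r = 0.045`. Strategies are compared pairwise against warfarin by
the incremental cost-effectiveness ratio `ICER = ΔCost/ΔQALY` at a
willingness-to-pay of $32,000 per QALY (costs in USD at a fixed 1,000
KRW/USD). The PSA redraws fatalities and incidence from Beta
distributions (Jeffreys counts where raw counts exist), costs and
treatment-state utilities from moment-fit Gamma distributions, using
common draws across strategies within each iteration.

## Worked example

```python
from afcea import run_base_case, demo_parameters

mp = demo_parameters()          # published utilities/costs/fatalities,
                                # score-2 stroke rates, demo post-event costs
table, traces = run_base_case(mp.strategies(), mp.settings, "warfarin")
cols = ["strategy", "cost", "qaly", "incremental_cost", "incremental_qaly", "icer"]
print(table[cols].round(2).to_string(index=False))
```

prints

```
   strategy     cost  qaly  incremental_cost  incremental_qaly     icer
   warfarin 10429.40 10.79               NaN               NaN      NaN
rivaroxaban 18864.35 11.25           8434.94              0.46 18160.23
   apixaban 14689.02 11.30           4259.61              0.51  8390.77
 dabigatran 19644.23 11.11           9214.82              0.32 29136.18
   edoxaban 17263.59 11.29           6834.19              0.50 13727.17
```

Each DOAC buys extra quality-adjusted survival (mostly through fewer
ischemic strokes and a higher treatment-state utility) at a higher drug
cost; apixaban delivers a QALY for about $8,400, well under the $32,000
threshold, while dabigatran is the least efficient alternative. Absolute
costs depend on the post-event annual cost inputs, which are placeholders
in the demo configuration (see `docs/methods.md`).

The same pipeline runs from a shell, end to end, against generated claims:

```sh
afcea run-all --out results/demo --seed 1
afcea run-psa --params src/afcea/data/demo_params.yaml --n 10000 --seed 1 --out results/psa
```

producing `cohort.csv`, `attrition.csv`, `incidence.csv`, `fatality.csv`,
`base_case.csv`, `psa_summary.csv`, `ceac.csv`, `tornado.csv` and a
reproducibility manifest.

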