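# Demonstration parameter set for the anticoagulant cost-effectiveness model.
# Utilities, medication costs, event costs and fatality follow the published
# base case; ischemic-stroke incidence uses the published score-2 stratum and
# the other event rates are the package's documented defaults. Post-event
# annual costs are placeholders (the source derives them by subtraction from
# unpublished totals). All currency in USD.
model:
  settings:
    n_cycles: 20
    discount_rate: 0.045
    wtp: 32000
  utilities:
    drug:
      warfarin: 0.987
      rivaroxaban: 0.994
      apixaban: 0.998
      dabigatran: 0.970
      edoxaban: 0.998
    event:
      HF: 0.69
      MI: 0.84
      IS: 0.41
      ICH: 0.56
      GI: 0.70
  costs:
    medication:
      warfarin: 19.490
      rivaroxaban: 795.426
      apixaban: 470.968
      dabigatran: 870.890
      edoxaban: 670.010
    event:
      HF: 2964.92
      MI: 7482.15
      IS: 4557.36
      ICH: 7108.77
      GI: 1583.03
    post_event:
      HF: 1500.0
      MI: 1200.0
      IS: 2400.0
      ICH: 3000.0
      GI: 0.0
  incidence:
    warfarin: {HF: 0.040, MI: 0.004, IS: 0.0152, ICH: 0.0015, GI: 0.006}
    rivaroxaban: {HF: 0.040, MI: 0.004, IS: 0.0064, ICH: 0.0015, GI: 0.006}
    apixaban: {HF: 0.040, MI: 0.004, IS: 0.0062, ICH: 0.0015, GI: 0.006}
    dabigatran: {HF: 0.040, MI: 0.004, IS: 0.0053, ICH: 0.0015, GI: 0.006}
    edoxaban: {HF: 0.040, MI: 0.004, IS: 0.0064, ICH: 0.0015, GI: 0.006}
generator:
  n_patients: 4000
psa:
  n_iter: 2000
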