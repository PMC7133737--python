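# AT-RvD1 in the adult human: 0.1 mg/kg IV bolus, 0-24 hr.
# fu_plasma = 0.05 is an ASSUMED value, flagged in all output metadata.
compound:
  fixture: at_rvd1
  fu_plasma: 0.05
physiology:
  species: human
clearance:
  mode: calibrated_total
  total_plasma_clearance_ml_min_kg: 14.02
dose:
  amount_mg_per_kg: 0.1
simulation:
  t_end_hr: 24.0
  grid_step_hr: 0.05
population:
  n: 100
  age_range_yr: [20, 80]
  sex_ratio_female: 0.5
  seed: 2020
sensitivity:
  doses_mg_per_kg: [0.1, 0.25, 0.5]
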