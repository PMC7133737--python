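{
  "description": "Piecewise-linear adult body weight (kg) by age and sex used to map sampled (age, sex) pairs to body weight in human virtual populations. Values are package defaults shaped like national survey means and anchored so that the population mean over uniform ages 20-80 with an equal sex split is 80.35 kg (the reference adult).",
  "age_yr": [20, 30, 40, 50, 60, 70, 80],
  "weight_kg": {
    "male":   [82.4, 87.4, 90.4, 91.4, 89.9, 85.9, 80.4],
    "female": [68.4, 72.4, 75.4, 76.4, 74.9, 71.4, 66.9]
  }
}
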