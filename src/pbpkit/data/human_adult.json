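{
  "species": "human_adult",
  "description": "Adult reference physiology (80.35 kg, BMI 25.22 kg/m2, 30-year-old population mean). Named organ volumes and the six printed blood flows follow the published parameterization; every other value is a package default flagged in assumed_parameters.",
  "body_weight_kg": 80.35,
  "bmi_kg_m2": 25.22,
  "hematocrit": 0.45,
  "saliva_volume_ml": 6.6,
  "arterial_volume_ml": 1855.0,
  "venous_volume_ml": 3445.0,
  "organs": {
    "lung":           {"volume_ml": 1210.12, "blood_flow_ml_min": 6250.0, "f_vas": 0.26, "f_water": 0.80, "f_lipid": 0.015, "f_protein": 0.15, "eor_abundance": 0.2},
    "heart":          {"volume_ml": 416.52,  "blood_flow_ml_min": 260.0,  "f_vas": 0.10, "f_water": 0.73, "f_lipid": 0.025, "f_protein": 0.16, "eor_abundance": 0.0},
    "brain":          {"volume_ml": 1509.06, "blood_flow_ml_min": 780.0,  "f_vas": 0.03, "f_water": 0.77, "f_lipid": 0.05,  "f_protein": 0.10, "eor_abundance": 0.0},
    "kidney":         {"volume_ml": 437.33,  "blood_flow_ml_min": 1320.0, "f_vas": 0.16, "f_water": 0.78, "f_lipid": 0.02,  "f_protein": 0.16, "eor_abundance": 0.5},
    "liver":          {"volume_ml": 2366.5,  "blood_flow_ml_min": 420.0,  "f_vas": 0.21, "f_water": 0.72, "f_lipid": 0.035, "f_protein": 0.18, "eor_abundance": 1.0},
    "spleen":         {"volume_ml": 206.38,  "blood_flow_ml_min": 170.0,  "f_vas": 0.28, "f_water": 0.78, "f_lipid": 0.015, "f_protein": 0.18, "eor_abundance": 0.0},
    "gut":            {"volume_ml": 1100.0,  "blood_flow_ml_min": 1100.0, "f_vas": 0.07, "f_water": 0.75, "f_lipid": 0.025, "f_protein": 0.15, "eor_abundance": 0.0},
    "muscle":         {"volume_ml": 29000.0, "blood_flow_ml_min": 900.0,  "f_vas": 0.03, "f_water": 0.76, "f_lipid": 0.015, "f_protein": 0.18, "eor_abundance": 0.0},
    "skin":           {"volume_ml": 3300.0,  "blood_flow_ml_min": 300.0,  "f_vas": 0.05, "f_water": 0.65, "f_lipid": 0.04,  "f_protein": 0.25, "eor_abundance": 0.0},
    "adipose":        {"volume_ml": 18200.0, "blood_flow_ml_min": 250.0,  "f_vas": 0.02, "f_water": 0.15, "f_lipid": 0.80,  "f_protein": 0.04, "eor_abundance": 0.0},
    "bone":           {"volume_ml": 10500.0, "blood_flow_ml_min": 250.0,  "f_vas": 0.04, "f_water": 0.40, "f_lipid": 0.07,  "f_protein": 0.20, "eor_abundance": 0.0},
    "gonads":         {"volume_ml": 35.0,    "blood_flow_ml_min": 20.0,   "f_vas": 0.10, "f_water": 0.80, "f_lipid": 0.01,  "f_protein": 0.15, "eor_abundance": 0.0},
    "pancreas":       {"volume_ml": 100.0,   "blood_flow_ml_min": 70.0,   "f_vas": 0.12, "f_water": 0.72, "f_lipid": 0.04,  "f_protein": 0.17, "eor_abundance": 0.0},
    "salivary_gland": {"volume_ml": 85.0,    "blood_flow_ml_min": 50.0,   "f_vas": 0.10, "f_water": 0.75, "f_lipid": 0.02,  "f_protein": 0.16, "eor_abundance": 0.0},
    "rest_of_body":   {"volume_ml": 5000.0,  "blood_flow_ml_min": 360.0,  "f_vas": 0.05, "f_water": 0.70, "f_lipid": 0.03,  "f_protein": 0.18, "eor_abundance": 0.0}
  },
  "assumed_parameters": [
    "tissue composition fractions f_water/f_lipid/f_protein (all organs): package defaults",
    "vascular space fractions f_vas (all organs): package defaults",
    "organ set beyond the six printed organs (gut, muscle, skin, adipose, bone, gonads, pancreas, salivary_gland, rest_of_body): package default volumes and flows; rest_of_body flow balances cardiac output",
    "arterial/venous blood pool volumes: package defaults (~5.3 L blood)",
    "eicosanoid oxidoreductase relative abundances: package defaults (liver 1.0, kidney 0.5, lung 0.2)"
  ]
}
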