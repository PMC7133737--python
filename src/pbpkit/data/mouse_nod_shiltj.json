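{
  "species": "mouse_nod_shiltj",
  "description": "NOD/ShiLtJ mouse reference physiology. Named organ volumes, the six printed organ blood flows, hematocrit, body weight and saliva volume follow the published strain parameterization; every other value is a package default flagged in assumed_parameters.",
  "body_weight_kg": 0.0275,
  "bmi_kg_m2": null,
  "hematocrit": 0.45,
  "saliva_volume_ml": 0.00226,
  "arterial_volume_ml": 0.75,
  "venous_volume_ml": 1.4,
  "organs": {
    "lung":           {"volume_ml": 0.13,  "blood_flow_ml_min": 7.11,  "f_vas": 0.26, "f_water": 0.80, "f_lipid": 0.015, "f_protein": 0.15, "eor_abundance": 0.2},
    "heart":          {"volume_ml": 0.12,  "blood_flow_ml_min": 0.366, "f_vas": 0.10, "f_water": 0.73, "f_lipid": 0.025, "f_protein": 0.16, "eor_abundance": 0.0},
    "brain":          {"volume_ml": 0.22,  "blood_flow_ml_min": 0.17,  "f_vas": 0.03, "f_water": 0.77, "f_lipid": 0.05,  "f_protein": 0.10, "eor_abundance": 0.0},
    "kidney":         {"volume_ml": 0.45,  "blood_flow_ml_min": 1.7,   "f_vas": 0.16, "f_water": 0.78, "f_lipid": 0.02,  "f_protein": 0.16, "eor_abundance": 0.5},
    "liver":          {"volume_ml": 1.70,  "blood_flow_ml_min": 0.458, "f_vas": 0.21, "f_water": 0.72, "f_lipid": 0.035, "f_protein": 0.18, "eor_abundance": 1.0},
    "spleen":         {"volume_ml": 0.13,  "blood_flow_ml_min": 0.18,  "f_vas": 0.28, "f_water": 0.78, "f_lipid": 0.015, "f_protein": 0.18, "eor_abundance": 0.0},
    "gut":            {"volume_ml": 1.5,   "blood_flow_ml_min": 1.5,   "f_vas": 0.07, "f_water": 0.75, "f_lipid": 0.025, "f_protein": 0.15, "eor_abundance": 0.0},
    "muscle":         {"volume_ml": 10.0,  "blood_flow_ml_min": 0.9,   "f_vas": 0.03, "f_water": 0.76, "f_lipid": 0.015, "f_protein": 0.18, "eor_abundance": 0.0},
    "skin":           {"volume_ml": 4.0,   "blood_flow_ml_min": 0.4,   "f_vas": 0.05, "f_water": 0.65, "f_lipid": 0.04,  "f_protein": 0.25, "eor_abundance": 0.0},
    "adipose":        {"volume_ml": 1.9,   "blood_flow_ml_min": 0.3,   "f_vas": 0.02, "f_water": 0.15, "f_lipid": 0.80,  "f_protein": 0.04, "eor_abundance": 0.0},
    "bone":           {"volume_ml": 2.7,   "blood_flow_ml_min": 0.25,  "f_vas": 0.04, "f_water": 0.40, "f_lipid": 0.07,  "f_protein": 0.20, "eor_abundance": 0.0},
    "gonads":         {"volume_ml": 0.10,  "blood_flow_ml_min": 0.05,  "f_vas": 0.10, "f_water": 0.80, "f_lipid": 0.01,  "f_protein": 0.15, "eor_abundance": 0.0},
    "pancreas":       {"volume_ml": 0.20,  "blood_flow_ml_min": 0.10,  "f_vas": 0.12, "f_water": 0.72, "f_lipid": 0.04,  "f_protein": 0.17, "eor_abundance": 0.0},
    "salivary_gland": {"volume_ml": 0.10,  "blood_flow_ml_min": 0.05,  "f_vas": 0.10, "f_water": 0.75, "f_lipid": 0.02,  "f_protein": 0.16, "eor_abundance": 0.0},
    "rest_of_body":   {"volume_ml": 1.60,  "blood_flow_ml_min": 0.686, "f_vas": 0.05, "f_water": 0.70, "f_lipid": 0.03,  "f_protein": 0.18, "eor_abundance": 0.0}
  },
  "assumed_parameters": [
    "tissue composition fractions f_water/f_lipid/f_protein (all organs): package defaults, never published for this strain",
    "vascular space fractions f_vas (all organs): package defaults",
    "organ set beyond the six printed organs (gut, muscle, skin, adipose, bone, gonads, pancreas, salivary_gland, rest_of_body): package default volumes and flows; rest_of_body flow balances cardiac output",
    "arterial/venous blood pool volumes: package defaults (~78 ml blood per kg)",
    "eicosanoid oxidoreductase relative abundances: package defaults (liver 1.0, kidney 0.5, lung 0.2)"
  ]
}
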