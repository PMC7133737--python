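{
  "name": "at_rvd1",
  "description": "Aspirin-triggered resolvin D1 (AT-RvD1, 17R-epimer of resolvin D1). Physicochemical values are the published QSPR-derived inputs; fu_plasma is deliberately null because the plasma free fraction has never been measured and must be supplied by the user (shipped example configs use 0.05, flagged as assumed).",
  "molecular_weight_g_mol": 376.493,
  "formula": "C22H32O5",
  "logP": 3.22,
  "pKa": 4.47,
  "solubility_pH74_mg_ml": 3.1,
  "fu_plasma": null,
  "binding_protein": "albumin",
  "assumed_parameters": [
    "binding_protein 'albumin': typical carrier for long-chain fatty-acid derivatives, not measured",
    "fu_plasma: required user input; no measured value exists"
  ]
}
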