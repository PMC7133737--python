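# Noisy mono-exponential profile for exercising the NCA stage standalone.
model: mono_exponential
c0_ng_ml: 100.0
ke_per_hr: 0.1
grid_hr:
  t_start_hr: 0.0
  t_end_hr: 24.0
  step_hr: 0.25
noise_cv: 0.1
seed: 42
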