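# Molar absorptivity from endpoint absorbances of exhausted assays
experiment_id: s5
scheme: {builder: deoxyarbutin, constants: s22}
protocol:
  kind: epsilon_endpoints
  epsilon: 2300.0
  path_cm: 1.0
  levels_M: [5.0e-5, 1.0e-4, 1.5e-4, 2.0e-4]
  enzyme_total_M: 2.0e-7
  initial_M: {H2O2: 5.0e-3, O2: 2.6e-4}
  duration_s: 14400.0
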