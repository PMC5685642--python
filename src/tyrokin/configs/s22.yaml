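# Simulated recordings at the printed substrate levels
experiment_id: s22
scheme: {builder: deoxyarbutin, constants: s22}
protocol:
  kind: substrate_series
  substrate: D-Arb
  observe: P
  enzyme_total_M: 7.0e-7
  initial_M: {H2O2: 1.25e-6, O2: 2.6e-4}
  duration_s: 60.0
  levels_M: [5.0e-5, 1.0e-4, 2.5e-4, 4.0e-4, 7.0e-4, 1.0e-3]
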