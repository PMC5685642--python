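# Rate vs enzyme concentration at fixed substrate
experiment_id: s24
scheme: {builder: deoxyarbutin, constants: s24}
protocol:
  kind: enzyme_series
  observe: P
  enzyme_levels_M: [0.0, 5.0e-8, 1.0e-7, 2.5e-7, 5.0e-7, 7.5e-7]
  initial_M: {D-Arb: 2.0e-4, H2O2: 1.25e-6, O2: 2.6e-4}
  duration_s: 60.0
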