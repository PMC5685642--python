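# Initial quinone-formation rate vs deoxyarbutin concentration
experiment_id: fig4a
scheme: {builder: deoxyarbutin, constants: fig4}
protocol:
  kind: substrate_series
  substrate: D-Arb
  observe: P
  enzyme_total_M: 3.0e-7
  initial_M: {H2O2: 1.25e-6, O2: 2.6e-4}
  duration_s: 60.0
  levels_M: [5.0e-6, 1.0e-5, 2.0e-5, 5.0e-5, 1.0e-4, 2.0e-4, 4.0e-4, 7.0e-4, 1.0e-3]
  fit: true
  effective_enzyme_fraction: 0.2
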