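# Progress of quinone formation until total oxygen consumption
experiment_id: fig4b
scheme: {builder: deoxyarbutin, constants: fig4}
protocol:
  kind: oxygen_exhaustion
  enzyme_total_M: 1.5e-6
  initial_M: {D-Arb: 4.0e-4, H2O2: 1.25e-6, O2: 2.6e-4}
  duration_s: 36000.0
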