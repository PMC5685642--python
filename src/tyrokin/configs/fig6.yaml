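# Activation after 1 min pre-incubation with H2O2
experiment_id: fig6
scheme: {builder: deoxyarbutin, constants: s23}
protocol:
  kind: preincubation
  agent: H2O2
  preincubation_s: 60.0
  values: [1.25e-6, 2.0e-6, 5.0e-6, 1.0e-5, 2.0e-5, 5.0e-5, 1.0e-4]
  enzyme_total_M: 5.0e-7
  initial_M: {D-Arb: 2.0e-4, O2: 2.6e-4, H2O2: 1.25e-6}
  duration_s: 60.0
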