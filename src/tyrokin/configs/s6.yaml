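# Inactivation by pre-incubation with catalase (first-order H2O2 sink)
experiment_id: s6
scheme: {builder: deoxyarbutin, constants: s6, catalase_k16: 6.6e-4}
protocol:
  kind: preincubation
  agent: catalase
  values: [0.0, 300.0, 900.0, 1800.0, 3600.0, 7200.0]
  enzyme_total_M: 5.0e-7
  initial_M: {D-Arb: 2.0e-4, O2: 2.6e-4, H2O2: 1.25e-6}
  duration_s: 60.0
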