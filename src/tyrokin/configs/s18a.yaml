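# Apparent inhibition of the monophenolase activity by D-Arb
experiment_id: s18a
scheme: {builder: monophenolase_competition, constants: s18a}
protocol:
  kind: inhibition
  substrate: M
  observe: Cr
  companion_ratio: {D: 0.042}
  enzyme_total_M: 7.0e-7
  initial_M: {O2: 2.6e-4}
  duration_s: 60.0
  substrate_levels_M: [2.0e-5, 5.0e-5, 1.0e-4, 2.0e-4, 4.0e-4, 7.0e-4, 1.0e-3]
  inhibitor_levels_M: [0.0, 2.0e-4]
  effective_enzyme_fraction: 0.2
  window: {mode: max_slope}
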