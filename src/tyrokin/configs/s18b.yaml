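# Apparent inhibition of the diphenolase activity by D-Arb
experiment_id: s18b
scheme: {builder: diphenolase_competition, constants: s18b}
protocol:
  kind: inhibition
  substrate: D
  observe: Cr
  enzyme_total_M: 7.0e-7
  initial_M: {O2: 2.6e-4}
  duration_s: 60.0
  substrate_levels_M: [5.0e-5, 1.0e-4, 2.0e-4, 5.0e-4, 1.0e-3, 2.0e-3]
  inhibitor_levels_M: [0.0, 2.0e-4]
  effective_enzyme_fraction: 0.2
  window: {mode: max_slope}
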