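# Release variant: D-ArbOH released, rebinds E_m and E_ox
experiment_id: s10
scheme: {builder: release_rebind, constants: s10}
protocol:
  kind: progress
  enzyme_total_M: 7.5e-7
  initial_M: {D-Arb: 4.0e-4, H2O2: 1.25e-6, O2: 2.6e-4}
  duration_s: 600.0
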