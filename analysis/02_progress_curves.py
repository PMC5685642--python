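"""Progress curves: oxygen exhaustion and simulated recordings.

Runs the oxygen-exhaustion experiment (product accumulates until O2 runs
out; 1:1 product-per-oxygen stoichiometry) and the substrate-series
recordings, converting the latter to 485 nm absorbance traces with
epsilon = 2300 M^-1 cm^-1.  Writes curves and summaries under results/.
"""
from pathlib import Path

from tyrokin import QUINONE_CHANNEL, absorbance_trace, run_experiment

outdir = Path("results")
res = run_experiment("fig4b", outdir=outdir)
s = res["summary"]
print(f"oxygen exhausted after {s['t_depleted_s']:.0f} s; "
      f"[P]_final = {s['P_final_M']*1e3:.3f} mM vs [O2]_0 = 0.26 mM; "
      f"P formed per O2 consumed = {s['P_per_O2']:.3f}")

res = run_experiment("s22", outdir=outdir)
rates = res["rates"]
print("substrate series (quinone channel):")
print(rates[["level_M", "v0_M_per_s"]].to_string(index=False))
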