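"""Bottom-up input sweep: gain modulation and LFP input-output curves.

Runs a reduced sweep of the bottom-up drive s over [0, 1] for both memory
conditions and prints, per level: mean e/i rates, the LFP peak frequency
and the LFP DC component. The DC change across the sweep summarizes how
strongly inhibitory network output grows with sensory drive in each
condition.
"""

import numpy as np

import wmosc

cfg = wmosc.SweepConfig(s_grid=wmosc.default_s_grid(6), duration_ms=10_000.0)
sweep, _ = wmosc.run_network_sweep(cfg, seed=42)

print(f"{'s':>6} | {'e-rate IN':>9} {'e-rate OUT':>10} | "
      f"{'i-rate IN':>9} {'i-rate OUT':>10} | {'Omega IN':>8} {'Omega OUT':>9} | "
      f"{'dc IN':>6} {'dc OUT':>6}")
for s in cfg.s_grid:
    row = {}
    for cond in ("IN", "OUT"):
        sub = sweep[(sweep.s == s) & (sweep.condition == cond)]
        row[cond] = (
            sub[sub.population == "e"]["rate"].mean(),
            sub[sub.population == "i"]["rate"].mean(),
            sub["omega"].iloc[0],
            sub["lfp_dc_mean"].iloc[0],
        )
    print(f"{s:6.2f} | {row['IN'][0]:9.2f} {row['OUT'][0]:10.2f} | "
          f"{row['IN'][1]:9.2f} {row['OUT'][1]:10.2f} | "
          f"{row['IN'][2]:8.1f} {row['OUT'][2]:9.1f} | "
          f"{row['IN'][3]:6.3f} {row['OUT'][3]:6.3f}")

d_in = wmosc.compute_delta_mean(sweep, "IN")
d_out = wmosc.compute_delta_mean(sweep, "OUT")
print(f"\nLFP dc-mean change over the sweep: IN {d_in:.3f}, OUT {d_out:.3f} a.u.")
print("e-cells respond to bottom-up drive with higher gain in the IN")
print("condition at low-to-mid s; i-cell rates stay elevated IN throughout,")
print("and the rhythm accelerates with drive in both conditions.")
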