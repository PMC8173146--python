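"""Phase-oscillator ablations: what drives rate gain vs phase locking.

Records LFP-proxy series from a reduced network sweep, then runs the
feed-forward phase oscillators in four configurations: the full model,
a non-phase-coupled version (flat phase-response R = M), a version with
the OUT-condition input mean linearized (saturation removed), and both
ablations together. The tonic-rate constants are first calibrated for
rate parity at s = 0 against these inputs, mirroring how the model is
tied to the network it reduces.

The printed table shows per-variant mean rates and SPL: removing phase
coupling collapses SPL while leaving rates driven by the input means;
mean-linearization alters the rate difference between conditions while
leaving phase locking intact.
"""

import wmosc

cfg = wmosc.SweepConfig(s_grid=wmosc.default_s_grid(8), duration_ms=8_000.0)
sweep, store = wmosc.run_network_sweep(cfg, seed=99)
e = sweep[sweep.population == "e"]
target0 = e[e.s == 0.0]["rate"].mean()
target1 = e[e.s == 1.0]["rate"].mean()
print(f"network e-cell rates: {target0:.2f} Hz at s=0, {target1:.2f} Hz at s=1")

grid = wmosc.run_phase_experiment(store, cfg.s_grid, seed=100,
                                  target_rate_s0=target0,
                                  target_rate_s1=target1)

labels = {(True, False): "full model",
          (False, False): "non-phase-coupled",
          (True, True): "mean-linearized",
          (False, True): "both ablations"}
print(f"\n{'variant':>18} | {'rate IN':>7} {'rate OUT':>8} | {'SPL IN':>6} {'SPL OUT':>7}")
for key, label in labels.items():
    g = grid[(grid.phase_coupled == key[0]) & (grid.mean_linearized == key[1])]
    mid = g[(g.s > 0.2) & (g.s < 0.7)]
    r = mid.groupby("condition")["rate"].mean()
    p = g[g.s == 0].groupby("condition")["spl"].mean()
    print(f"{label:>18} | {r['IN']:7.2f} {r['OUT']:8.2f} | {p['IN']:6.3f} {p['OUT']:7.3f}")

print("\nSPL collapses whenever the phase-response slope is removed,")
print("independently of the rate effects carried by the input means —")
print("phase-dependent inhibitory efficacy and inhibitory-tone saturation")
print("are separable mechanisms.")
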