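"""Field-potential plasticity analysis on synthetic recordings.

Generates noisy recordings with programmed LTP / LTD / no-change
outcomes, runs baseline QC, computes post/pre ratios, classifies each
recording, and finds the input-output half-max working point.
"""

import numpy as np

import dendromito as dm

outcomes = []
for outcome in ("LTP", "LTD", "no_change"):
    cfg = dm.FPSynthConfig(noise_sd=0.05, seed=3)
    rec = dm.generate_fp(cfg, outcome)
    res = dm.classify_outcome(rec)
    outcomes.append(res)
    print(f"programmed {outcome:9s} -> post/pre {res.post_pre_ratio:.3f}, "
          f"baseline r^2 {res.baseline_r2:.3f}, p {res.test_p:.2e}, "
          f"classified {res.classification.value}")

print("\ngroup summary:", dm.plasticity_summary(outcomes))

# a drifting baseline fails the stability QC (r^2 > 0.2 -> discard)
drifty = dm.generate_fp(dm.FPSynthConfig(noise_sd=0.02, drift_slope_per_min=0.02, seed=4), "no_change")
print(f"\ndrifting baseline r^2 = {dm.baseline_stability(drifty.pre_amplitudes):.2f} "
      f"-> kept: {dm.is_stable(drifty)}")

# input-output curve: half-max response and the stimulus producing it
s = np.arange(50.0, 455.0, 25.0)
amp = 3.0 / (1.0 + np.exp(-(s - 240.0) / 40.0))
half, stim = dm.io_halfmax(dm.IOCurve(s, amp))
print(f"IO half-max amplitude {half:.2f} at ~{stim:.0f} uA "
      "(the working stimulus intensity for conditioning experiments)")
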