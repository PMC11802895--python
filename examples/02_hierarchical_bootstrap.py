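"""Hierarchical bootstrap contrast of mitochondrial area, CTL vs cKO.

Generates a dataset with a configured 15% cKO median-area deficit,
resamples each group at all four hierarchy levels (3 animals x 3
sections x 50 tiles x 100 objects = 45,000 values per iteration), and
reports the proportion of iterations in which the CTL median exceeds the
cKO median.
"""

import numpy as np

import dendromito as dm

ds = dm.generate_morphology(dm.effect_config(area_deficit=0.15, seed=2))
dm.compute_metrics(ds)
ds, _ = dm.apply_size_filter(ds)

cfg = dm.BootstrapConfig(n_iterations=2000, seed=5)
ctl = dm.bootstrap_distribution(ds, ("CTL", "SLM"), "area", cfg)
cko = dm.bootstrap_distribution(ds, ("cKO", "SLM"), "area", cfg)
comp = dm.compare_groups(ctl, cko)

print(f"resampled median area, CTL SLM: {np.median(ctl.medians):.4f} um^2")
print(f"resampled median area, cKO SLM: {np.median(cko.medians):.4f} um^2")
print(f"p_greater(CTL > cKO) = {comp.p_greater:.3f}  ({comp.n_iterations} iterations)")
print(f"joint distribution: {len(comp.hist_a)} bins spanning "
      f"[{comp.bin_edges[0]:.4f}, {comp.bin_edges[-1]:.4f}] um^2")
print("\nA p_greater near 1 means the area deficit is detected in nearly every")
print("resample of the full hierarchy; near 0.5 would mean no evidence.")
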