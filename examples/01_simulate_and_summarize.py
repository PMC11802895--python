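"""Generate a synthetic nested EM dataset and print its summary table.

Builds a 2 genotype x 3 layer x 3 animal x 3 section hierarchy with 10
tiles per section, computes per-object shape metrics, applies the
mitochondrial size filter, and prints the median (sd) of each metric per
genotype x layer -- the package's equivalent of a study summary table.
"""

import pandas as pd

import dendromito as dm

cfg = dm.mito_config(seed=1, n_tiles_per_section=10)
ds = dm.generate_morphology(cfg)
dm.compute_metrics(ds)
ds, n_excluded = dm.apply_size_filter(ds)
dm.annotate_nn(ds)

print(f"{len(ds.objects)} objects in {len(ds.tiles)} tiles; "
      f"{n_excluded} excluded by the [0.01, 2.1] um^2 size filter\n")

tab = dm.summary_table(ds)
cols = ["genotype", "layer", "n_objects", "area_um2_median", "feret_um_median",
        "aspect_ratio_median", "nn_dist_um_median", "count_per_100um2_median"]
with pd.option_context("display.width", 160):
    print(tab[cols].round(3).to_string(index=False))

print("\nMedians track the generator's configured targets (e.g. CTL SLM area"
      "\n0.153 um^2, 19 mitochondria per 100 um^2) up to animal random effects;"
      "\ncKO areas are smaller and counts higher, the fragmentation signature.")
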