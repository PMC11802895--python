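# dendromito

Nested electron-microscopy morphometrics of dendritic mitochondria and
spine heads, hierarchical-bootstrap group comparisons, and evoked
field-potential plasticity metrics.

## The problem

2-D SEM morphometry of dendritic organelles yields thousands of
segmented objects per group, but the objects are nested — object ⊂
image tile ⊂ hippocampal section ⊂ animal ⊂ genotype — so they are far
from independent, and classical per-object tests wildly overstate
significance. This package is for researchers comparing organelle
morphology across genotypes and dendritic layers (e.g. a CA2-specific
knockout of the mitochondrial calcium uniporter, cKO, against controls
across SO/SR/SLM) who need statistics that respect the nesting, plus
the accompanying slice-electrophysiology readouts of synaptic
plasticity (LTP/LTD).

## What it computes

**Morphometrics** per polygon footprint (tile-local µm coordinates):
area $A$; maximum Feret's diameter
$F=\max_{p,q\in\mathrm{hull}}\lVert p-q\rVert$; aspect ratio
$\mathrm{AR} = \ell_{\text{long}}/\ell_{\text{short}} \ge 1$ of the
minimum-area rotated bounding rectangle; within-tile nearest-neighbor
centroid distance; per-tile count and total area per 100 µm²; the
mitochondrial size filter $A \in [0.01, 2.1]$ µm² (inclusive).

**Hierarchical bootstrap**: each iteration resamples, with replacement,
3 animals → 3 sections/animal → 50 tiles/section → 100 objects/tile
(45,000 pooled values; tile-level metrics stop at 450 tiles) and takes
the median of the resampled population; 10,000 iterations give a
population of medians per group. A contrast is summarized as

$$p_{\mathrm{greater}} = \frac{\#\{A_i > B_i\} + \tfrac12\#\{A_i = B_i\}}{n},$$

the proportion of iterations in which group A's median exceeds group
B's — a Bayesian-style evidence measure with exact label-swap symmetry.

**Plasticity**: baseline stability QC (discard if the linear fit of the
10-min baseline has r² > 0.2), 1-min binning (6 sweeps at 0.1 Hz),
post/pre ratio (last 5 min post ÷ last 5 min pre), LTD/no-change/LTP
classification (±10% change and Welch p < 0.05), and input–output
half-max interpolation.

**Synthetic generator**: the full nested design with known ground truth
— log-normal areas parameterized by median, negative-binomial per-tile
counts with exact configured medians, per-animal multiplicative random
effects, randomly rotated elliptical polygon footprints, and programmable
LTP/LTD/no-change FP recordings. `effect_config(deficit)` produces
common-random-number effect sweeps in which cKO areas scale exactly by
(1 − deficit).

## Worked example

```python
import dendromito as dm

ds = dm.generate_morphology(dm.effect_config(area_deficit=0.15, seed=2))
dm.compute_metrics(ds)
ds, _ = dm.apply_size_filter(ds)

cfg = dm.BootstrapConfig(n_iterations=2000, seed=5)
ctl = dm.bootstrap_distribution(ds, ("CTL", "SLM"), "area", cfg)
cko = dm.bootstrap_distribution(ds, ("cKO", "SLM"), "area", cfg)
print(dm.compare_groups(ctl, cko).p_greater)
```

Running `python examples/02_hierarchical_bootstrap.py` prints:

```
resampled median area, CTL SLM: 0.1542 um^2
resampled median area, cKO SLM: 0.1323 um^2
p_greater(CTL > cKO) = 1.000  (2000 iterations)
joint distribution: 100 bins spanning [0.1252, 0.1619] um^2
```

The configured 15% cKO area deficit is detected in essentially every
resample of the full hierarchy; an uninformative contrast would sit
near 0.5. The other scripts in `examples/` show the summary table
(medians per genotype × layer, e.g. CTL SLM area ≈ 0.153 µm² and 19
mitochondria per 100 µm² at the default targets), the tile-sampling
sensitivity analysis (oversampling 50 tiles per section reduces
run-to-run bootstrap spread), and the plasticity pipeline (noise-free
recordings recover their programmed outcome exactly).

A thin CLI mirrors the pipeline stages:

```sh
dendromito simulate --seed 1 --out data/
dendromito metrics --in data/objects.csv --out data/metrics.csv
dendromito bootstrap --in data/metrics.csv --metric area --layer SLM --out data/boot
dendromito plasticity --in data/fp_LTP.csv --out data/plasticity.json
dendromito report --in data/metrics.csv --out data/summary.csv
```

## Layout

```
src/dendromito/   model, io, morphometrics, spatial, synth, bootstrap,
                  plasticity, report, cli
examples/         one narrative script per capability
tests/            pytest suite (unit, property and end-to-end checks)
docs/methods.md   the model, parameters, numerical choices, limitations
```
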