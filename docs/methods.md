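# Methods

## The problem this package models

Quantitative 2-D EM morphometry of dendritic organelles produces deeply
nested data: segmented objects (dendritic mitochondria, spine heads) sit
inside ~100 µm² image tiles, tiles inside hippocampal sections, sections
inside animals, and animals inside genotype groups (here a control line,
CTL, and a CA2-specific knockout of the mitochondrial calcium uniporter,
cKO). Thousands of objects per group are *not* thousands of independent
observations; treating them as such inflates false positives. The
package therefore couples per-object morphometrics with a four-level
hierarchical bootstrap that propagates every level of variability into
the statistic of interest, and reports group contrasts as the proportion
of bootstrap iterations in which one group's resampled median exceeds
the other's (`p_greater`), a Bayesian-style evidence measure rather than
a frequentist p-value. A companion module analyses evoked field-potential
(FP) recordings of synaptic plasticity (LTP/LTD) from the same system.

## Data model

`HierarchicalDataset` stores four tables — animals (with genotype),
sections, tiles (layer ∈ {SO, SR, SLM}, nominal 12.2 × 8.2 µm ≈ 100 µm²)
and objects. An object is a simple polygon footprint in tile-local µm
coordinates (origin lower-left, counter-clockwise, closing edge
implicit), resolution-independent and directly consumable by the
geometry operations. Validation enforces the enum domains, referential
integrity of the object → tile → section → animal chain, tile-geometry
consistency (area = width × height within 1e-6), in-bounds footprints
and polygon simplicity. Pixel calibration defaults to 2 nm/px;
conversions are `µm = px · nm_per_px / 1000` and its square for areas.
The on-disk format is a flat CSV (one row per object, vertices JSON-
encoded in one column, tile geometry carried alongside), written in
canonical object-id order at full double precision so that
write → load → write is byte-stable.

## Morphometrics

* **Area**: shoelace area of the footprint (via GEOS), orientation- and
  start-vertex-invariant.
* **Maximum Feret's diameter**: the longest caliper distance, computed
  as the maximum pairwise distance between convex-hull vertices. It is
  checked against an O(n²) all-pairs oracle in the tests.
* **Aspect ratio**: long/short side of the minimum-area rotated bounding
  rectangle, reported ≥ 1 (1 = round). A bounding rectangle rather than
  an ellipse fit keeps the measure deterministic and assumption-free.
  Field summaries of elongation quote values like 1.6–1.9 with "closer
  to 1" meaning rounder, which fixes the long/short orientation of the
  ratio even where prose sometimes says "short axis divided by long".
* **Size filter**: mitochondrial objects with area outside the inclusive
  interval [0.01, 2.1] µm² are excluded before any statistics — the
  conventional plausibility band for single mitochondrial profiles;
  boundary values survive because the exclusion rule is "smaller
  than"/"larger than".
* **Nearest-neighbor distance**: centroid-to-centroid Euclidean distance
  to the nearest other object of the same class *within the same tile*
  (tiles are non-adjacent samples from a systematic sampling scheme, so
  cross-tile distances are not meaningful). Tiles with fewer than two
  objects contribute no distances — no sentinels, which would bias
  medians. Search uses a k-d tree and agrees with brute force to
  1 part in 10¹².
* **Per-tile densities**: object count and summed object area rescaled
  to a 100 µm² reference tile. Tiles with zero objects count as zeros.
* **Normalization**: for presentation, values are divided by the overall
  control mean, making the normalized control mean exactly 1.

## Hierarchical bootstrap

One iteration draws, with replacement: `n_animals` animals from the
group (default 3), `n_sections` sections per drawn animal (3), `n_tiles`
tiles per drawn section (50 — deliberate oversampling), and for
object-level metrics `n_objects` objects per drawn tile (100), pooling
3 × 3 × 50 × 100 = 45,000 values; tile-level metrics stop at tiles
(450 values). The statistic is the median of the pooled resampled
population (not a median-of-medians). The default 10,000 iterations give
a population of resampled medians per group.

Contrasts pair iteration *i* with iteration *i* and report
`p_greater = [#(Aᵢ > Bᵢ) + ½·#(Aᵢ = Bᵢ)] / n`. Half-weighted ties make
label-swap symmetry exact (`p(A,B) + p(B,A) = 1`) and give a clean 0.5
when comparing identical populations; with independent streams,
index-pairing equals unpaired comparison in distribution. Joint
distributions bin both median populations on shared equal-width linear
bins spanning the pooled min–max (100 bins for object-level metrics,
10 for tile-level counts); a degenerate range collapses to a single bin.
Level sizes can differ per group (e.g. spine-head designs with 2 control
and 3 knockout animals) as long as the iteration counts match.

Reproducibility: one seed spawns a child RNG stream per
(group, metric, stream index) via `SeedSequence` spawn keys (PCG64), so
groups are independent yet individually reproducible, and the same
group can be resampled on several independent streams.

Implementation note: the hierarchy is flattened into offset/length
arrays and iterations are drawn in vectorized batches, so a
10,000-iteration object-level run takes seconds on one core.

### Sampling-size sensitivity

`sampling_sensitivity` reruns the bootstrap several times per tile
sampling size (20 = undersampling, 32 ≈ the typical per-group tile
count, 50 = oversampling), summarizes each run by the median of its
resampled medians, and reports the sd of that summary across runs.
Oversampling tiles reduces this run-to-run variability. Two numerical
choices matter when *demonstrating* the effect: (i) the across-run sd
also contains an animal/section-resampling component that is independent
of tile sampling, so the calibration dataset is generated with
`animal_effect_sd = 0` and a large (100-tile) per-section pool, which
makes the tile-sampling component dominant; (ii) the per-tile *count*
median is integer-valued and its across-run sd collapses to ties, so the
continuous total-area-per-tile metric is used for the demonstration
(the function's default remains the count metric).

## Synthetic data generator

The generator emulates the study design — 2 genotypes × 3 layers ×
3 animals × 3 sections × 50 tiles — with known ground truth. Default
targets reproduce the magnitudes typical of CA2 dendritic layers (e.g.
CTL SLM median mitochondrial area 0.153 µm² with 19 objects per 100 µm²
tile; cKO SLM 0.145 µm² and 23 per tile; aspect-ratio medians 1.6–1.9).

* **Areas** are log-normal, parameterized by the median (µ = ln median).
  The log-sd σ is derived from a (median, sd) target pair in closed
  form: with r = sd/median, e^{σ²} = (1 + √(1 + 4r²))/2. Right-skewed
  with sd ≳ median, matching real object-area distributions.
* **Per-tile counts** are negative binomial (overdispersed), with the
  mean numerically inverted so the distribution's median equals the
  integer target exactly; Poisson is the fallback when the target sd
  implies underdispersion.
* **Animal random effect**: a per-animal multiplicative log-normal
  effect (log-sd `animal_effect_sd`, default 0.1) scales the area median
  and the count mean. 0.1 represents modest between-animal variability
  of inbred mice; setting it to 0 makes animals exchangeable, and ~0.2
  emulates the larger heterogeneity real cohorts show.
* **Footprints** are randomly rotated 24-gon ellipses rescaled to the
  drawn area exactly, with the drawn bounding-box aspect ratio, placed
  uniformly inside the tile (an object too large to fit raises a
  generation error naming the tile). Objects are placed independently —
  no hard-core repulsion — so nearest-neighbor structure is induced
  solely through density. This is the simplest model consistent with
  the measured quantities and a known limitation: real mitochondria are
  spatially organized along dendrites.
* **Common random numbers for effect sweeps**: `effect_config(deficit)`
  scales only the cKO area medians relative to the shared-null
  configuration while holding σ, counts and all RNG streams fixed
  (one child stream per genotype × layer × animal, fixed draw counts
  per object). For a fixed seed the cKO areas of the generated dataset
  scale *exactly* by (1 − deficit), so `p_greater` is monotone in the
  configured deficit by construction and effect-size sweeps are free of
  generator noise.

FP recordings are a constant noisy baseline (60 samples, 10 min at
0.1 Hz), a conditioning gap (metadata only), and a post phase
(360 samples, 60 min) ramping linearly over 10 min to a plateau at
`plasticity_multiplier` × baseline (LTP 1.5, LTD 0.8, no-change 1.0 by
convention). The plateau is exact, so with `noise_sd = 0` the post/pre
ratio equals the multiplier exactly. Noise is i.i.d. Gaussian with sd
expressed as a fraction of baseline; an optional linear drift exercises
the baseline-stability filter.

What the generator does **not** emulate: pixel-level images and
segmentation errors, spatial correlation of objects along dendrites,
section-level random effects, ER contacts or "stacked" mitochondrial
arrangements, and FP waveform shape (only evoked peak amplitudes).
Passing tests therefore validate the *analysis machinery* under a known
generative model, not the biology of any real dataset.

## Plasticity analysis

* **Baseline QC**: r² of the OLS fit of baseline amplitude vs time;
  recordings with r² > 0.2 are discarded as unstable. A perfectly flat
  baseline has an undefined regression r²; it is defined as 0
  (maximally stable).
* **Binning**: non-overlapping 1-min bins of 6 sweeps at 0.1 Hz;
  trailing partial bins are dropped so every plotted point represents
  exactly one minute.
* **Post/pre ratio**: mean of the last 5 min (30 sweeps) post divided by
  the mean of the last 5 min pre; scale-invariant by construction.
* **Classification**: LTD iff ratio < 0.9 *and* Welch's two-sample test
  on the raw sweeps of the two 5-min windows gives p < 0.05; LTP iff
  ratio > 1.1 and p < 0.05; otherwise no change. Welch's variant is
  used because it is the robust default for unequal variances. On
  zero-variance windows (noise-free synthetic traces) the degenerate
  Welch statistic is assigned p = 0 for unequal means and p = 1 for
  equal means, so noise-free recovery is exact. Recordings too short
  for the windows classify as no-change with an
  `insufficient_samples` flag.
* **Input–output curves**: the working point is 50% of the maximal FP
  response; the corresponding stimulus is linearly interpolated between
  the bracketing intensities, and extrapolation below the first
  measured amplitude is refused.

## Calibration behaviour and design choices under uncertainty

* **Null calibration.** When one group's data are resampled on two
  independent RNG streams and compared, `p_greater` is 0.5 up to pure
  Monte-Carlo noise (≈ 0.005 sd at 10,000 iterations); this is the
  machinery calibration the test suite asserts at ±0.02. Comparing two
  *independently generated* groups with identical parameters is a
  different experiment: there the bootstrap spread of each group's
  median is of the same order as the sampling difference between the
  groups' empirical medians, so per-dataset `p_greater` is widely
  dispersed around 0.5 (roughly uniform), exactly as a correct
  bootstrap should behave under a null. Users should therefore read a
  single `p_greater` as evidence about *this* dataset, not as a
  calibrated error rate.
* **Effect recovery.** With the default modest animal effect (0.1), a
  30% configured area deficit at paper-scale n is detected essentially
  always (p_greater ≈ 1), and the 0/5/15/30% sweep is monotone by the
  common-random-numbers construction. With the larger between-animal
  heterogeneity real cohorts show (animal effect ≈ 0.2), a 15% deficit
  yields intermediate probabilities (≈ 0.8–1.0 per dataset,
  ≈ 0.94 on average in the test suite) — above chance, short of
  certainty — which is the qualitative regime real studies report for
  deficits of that size.

## Problem sizes used by tests and the acceptance script

Bootstrap runs use the full 10,000 iterations at paper-scale level
sizes (3, 3, 50, 100). Synthetic datasets are generated at the study's
own scale (≈ 40,000 objects over 2,700 tiles; seconds per dataset); the
sampling-sensitivity calibration uses 100 repeats of 300-iteration runs,
and the generator law-of-large-numbers checks use ≈ 14,000 objects per
group. These sizes were chosen so every calibration has comfortable
statistical margin while a full test run stays in the minutes range on
one core.

## Known limitations

2-D profiles systematically undercount and under-measure 3-D
mitochondria (a profile is often a slice of a larger organelle); the
package inherits this interpretation caveat from the imaging geometry.
The generator's independence assumptions (no spatial interaction, no
section effects) mean nearest-neighbor contrasts under density changes
are driven purely by count. The bootstrap treats the configured level
sizes as the inferential design; it does not estimate variance
components.
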