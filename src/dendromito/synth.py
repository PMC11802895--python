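"""Synthetic nested datasets with known ground truth.

The generator emulates the structure of a systematically sampled SEM
morphometry study: 2 genotypes (CTL, cKO) x 3 dendritic layers
(SO, SR, SLM), each with 3 animals x 3 sections x ~50 tiles of
~100 um^2, containing right-skewed object areas and overdispersed
per-tile counts.  Ground truth is the config itself, so every analysis
stage can be checked against configured targets.

Distributional choices (ours; the real data are empirical):

* object areas ~ log-normal parameterized by its median
  (mu = ln median), scaled by a per-animal multiplicative log-normal
  random effect — medians in real data are right-skewed with
  std > median;
* per-tile counts ~ negative binomial, median-parameterized by numeric
  inversion — real per-tile counts are overdispersed;
* footprints are randomly rotated 24-gon ellipses placed uniformly
  inside the tile; objects are placed independently (no hard-core
  repulsion), so nearest-neighbor structure is induced solely by
  density.

Field-potential recordings are generated as a noisy constant baseline
followed by a ramp to a configurable post-conditioning asymptote, giving
programmable LTP / LTD / no-change outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    TILE_HEIGHT_UM,
    TILE_WIDTH_UM,
    GenerationError,
    Genotype,
    HierarchicalDataset,
    Layer,
)

# ---------------------------------------------------------------------------
# parameterization helpers
# ---------------------------------------------------------------------------


def lognormal_sigma(median: float, sd: float) -> float:
    """Log-scale sigma of a log-normal with the given median and sd.

    With r = sd/median, e^{sigma^2} solves u(u-1) = r^2, so
    u = (1 + sqrt(1 + 4 r^2)) / 2 and sigma = sqrt(ln u).
    """
    if median <= 0 or sd <= 0:
        raise ValueError("median and sd must be positive")
    r2 = (sd / median) ** 2
    u = (1.0 + math.sqrt(1.0 + 4.0 * r2)) / 2.0
    return math.sqrt(math.log(u))


def _count_median(mu: float, sd: float) -> float:
    """Median of the per-tile count law at mean ``mu`` and sd ``sd``."""
    var = sd * sd
    if var > mu:  # negative binomial (overdispersed)
        k = mu * mu / (var - mu)
        return float(stats.nbinom.median(k, k / (k + mu)))
    return float(stats.poisson.median(mu))


def count_mean_for_median(median: int, sd: float) -> float:
    """Invert the count law numerically: mean whose median equals ``median``.

    The median is a step function of the mean; we bisect for the step onto
    ``median`` and the step past it and return the midpoint, so the
    generated counts have exactly the configured median.
    """
    if median < 1:
        raise ValueError("count median must be >= 1")

    def first_mu_with_median_ge(m: float) -> float:
        lo, hi = 0.01, max(4.0 * median, median + 6.0 * sd)
        if _count_median(hi, sd) < m:
            raise ValueError("count median target unreachable")
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if _count_median(mid, sd) >= m:
                hi = mid
            else:
                lo = mid
        return hi

    lo = first_mu_with_median_ge(median)
    hi = first_mu_with_median_ge(median + 1)
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupParams:
    """Generative targets for one genotype x layer cell."""

    median_area_um2: float
    area_log_sd: float  # sigma of the log-normal area law
    aspect_median: float
    count_median: int  # per-tile object count, median
    count_sd: float

    def __post_init__(self):
        if self.median_area_um2 <= 0 or self.area_log_sd <= 0:
            raise ValueError("area parameters must be positive")
        if self.aspect_median < 1:
            raise ValueError("aspect_median must be >= 1")
        if self.count_median < 1 or self.count_sd <= 0:
            raise ValueError("count parameters must be positive")


@dataclass(frozen=True)
class SynthConfig:
    """Full morphology-generator configuration.

    ``groups`` maps ``(genotype, layer)`` value pairs to
    :class:`GroupParams`.  ``animal_effect_sd`` is the log-scale sd of a
    per-animal multiplicative random effect applied to the area median
    and the count mean (0 makes animals exchangeable).
    """

    groups: dict = field(default_factory=dict)
    n_animals: int = 3
    n_sections_per_animal: int = 3
    n_tiles_per_section: int = 50
    animal_effect_sd: float = 0.1
    aspect_log_sd: float = 0.4
    tile_width_um: float = TILE_WIDTH_UM
    tile_height_um: float = TILE_HEIGHT_UM
    object_class: str = "mitochondrion"
    n_vertices: int = 24
    seed: int = 0

    def __post_init__(self):
        if min(self.n_animals, self.n_sections_per_animal, self.n_tiles_per_section) < 1:
            raise ValueError("hierarchy sizes must be >= 1")
        if self.animal_effect_sd < 0:
            raise ValueError("animal_effect_sd must be >= 0")


# Default targets for the mitochondria generator: median (sd) of object
# area in um^2, aspect-ratio median, and per-tile count median (sd), per
# genotype x layer, chosen to match the kind of layer/genotype structure
# seen in CA2 SEM morphometry (e.g. CTL SLM area 0.153 um^2, 19 per tile).
_MITO_TARGETS = {
    ("CTL", "SO"): dict(area=(0.155, 0.16), aspect=1.6, count=(10, 4.4)),
    ("CTL", "SR"): dict(area=(0.134, 0.15), aspect=1.9, count=(10, 4.0)),
    ("CTL", "SLM"): dict(area=(0.153, 0.19), aspect=1.9, count=(19, 6.5)),
    ("cKO", "SO"): dict(area=(0.131, 0.15), aspect=1.6, count=(13, 5.3)),
    ("cKO", "SR"): dict(area=(0.112, 0.14), aspect=1.8, count=(13, 4.6)),
    ("cKO", "SLM"): dict(area=(0.145, 0.19), aspect=1.9, count=(23, 5.6)),
}

# Spine-head targets (areas are narrower and less skewed; densities lower).
_SPINE_TARGETS = {
    ("CTL", "SO"): dict(area=(0.146, 0.07), aspect=1.3, count=(11, 4.0)),
    ("CTL", "SR"): dict(area=(0.138, 0.07), aspect=1.3, count=(12, 3.9)),
    ("CTL", "SLM"): dict(area=(0.145, 0.07), aspect=1.3, count=(15, 5.8)),
    ("cKO", "SO"): dict(area=(0.131, 0.06), aspect=1.3, count=(11, 4.6)),
    ("cKO", "SR"): dict(area=(0.126, 0.06), aspect=1.3, count=(12, 5.2)),
    ("cKO", "SLM"): dict(area=(0.134, 0.06), aspect=1.3, count=(15, 5.2)),
}


def _build_groups(targets: dict) -> dict:
    out = {}
    for key, t in targets.items():
        med, sd = t["area"]
        cmed, csd = t["count"]
        out[key] = GroupParams(
            median_area_um2=med,
            area_log_sd=lognormal_sigma(med, sd),
            aspect_median=t["aspect"],
            count_median=cmed,
            count_sd=csd,
        )
    return out


def mito_config(seed: int = 0, **overrides) -> SynthConfig:
    """Default mitochondria generator (summary-table-like targets)."""
    return SynthConfig(groups=_build_groups(_MITO_TARGETS), seed=seed, **overrides)


def spine_config(seed: int = 0, **overrides) -> SynthConfig:
    """Default spine-head generator."""
    return SynthConfig(
        groups=_build_groups(_SPINE_TARGETS),
        object_class="spine_head",
        seed=seed,
        **overrides,
    )


def null_config(seed: int = 0, animal_effect_sd: float = 0.0, **overrides) -> SynthConfig:
    """Both genotypes share the CTL parameters (exchangeable null)."""
    groups = _build_groups(_MITO_TARGETS)
    for layer in Layer:
        groups[("cKO", layer.value)] = groups[("CTL", layer.value)]
    return SynthConfig(groups=groups, seed=seed, animal_effect_sd=animal_effect_sd, **overrides)


def effect_config(area_deficit: float, seed: int = 0, **overrides) -> SynthConfig:
    """Null config with cKO median areas reduced by ``area_deficit`` (0..1).

    Only the cKO area medians change; sigmas, counts and all RNG streams
    are shared with :func:`null_config`, so for a fixed seed the cKO areas
    of the generated dataset scale exactly by ``1 - area_deficit``
    (common-random-numbers design for effect-size sweeps).
    """
    if not 0 <= area_deficit < 1:
        raise ValueError("area_deficit must be in [0, 1)")
    cfg = null_config(seed=seed, **overrides)
    groups = dict(cfg.groups)
    for layer in Layer:
        p = groups[("cKO", layer.value)]
        groups[("cKO", layer.value)] = replace(
            p, median_area_um2=p.median_area_um2 * (1.0 - area_deficit)
        )
    return replace(cfg, groups=groups)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def generate_polygon(area: float, aspect: float, rng: np.random.Generator, n_vertices: int = 24) -> np.ndarray:
    """Randomly rotated n-gon approximating an ellipse of given area/aspect.

    Returns an ``(n, 2)`` vertex array centered on the origin,
    counter-clockwise.  The polygon area matches ``area`` exactly (the
    inscribed n-gon is rescaled), and the min-area bounding-box aspect
    ratio is within a few percent of ``aspect``.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    if aspect < 1:
        raise ValueError("aspect must be >= 1")
    r_short = math.sqrt(area / (math.pi * aspect))
    r_long = aspect * r_short
    t = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    pts = np.column_stack([r_long * np.cos(t), r_short * np.sin(t)])
    # inscribed n-gon area = n/2 * a*b * sin(2 pi / n); rescale to exact area
    poly_area = 0.5 * n_vertices * r_long * r_short * math.sin(2.0 * np.pi / n_vertices)
    pts *= math.sqrt(area / poly_area)
    theta = rng.uniform(0.0, np.pi)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return pts @ rot.T


# ---------------------------------------------------------------------------
# morphology generator
# ---------------------------------------------------------------------------


def _group_stream(seed: int, gi: int, li: int, ai: int) -> np.random.Generator:
    # one child stream per (genotype, layer, animal): changing one group's
    # parameter values never desynchronizes another group's draws
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(gi, li, ai)))


def generate_morphology(cfg: SynthConfig) -> HierarchicalDataset:
    """Generate a full hierarchical dataset from ``cfg`` (seed-deterministic)."""
    genotypes = [g.value for g in Genotype]
    layers = [l.value for l in Layer]
    for g in genotypes:
        for l in layers:
            if (g, l) not in cfg.groups:
                raise ValueError(f"config missing group parameters for {(g, l)}")

    count_means = {
        key: count_mean_for_median(p.count_median, p.count_sd)
        for key, p in cfg.groups.items()
    }

    animals, sections, tiles, obj_rows = [], [], [], []
    W, H = cfg.tile_width_um, cfg.tile_height_um
    prefix = "m" if cfg.object_class == "mitochondrion" else "s"

    for gi, g in enumerate(genotypes):
        for ai in range(cfg.n_animals):
            animal_id = f"{g}-a{ai}"
            animals.append((animal_id, g))
            for si in range(cfg.n_sections_per_animal):
                sections.append((f"{animal_id}-s{si}", animal_id))
        for li, l in enumerate(layers):
            p = cfg.groups[(g, l)]
            mu_count = count_means[(g, l)]
            var = p.count_sd ** 2
            for ai in range(cfg.n_animals):
                rng = _group_stream(cfg.seed, gi, li, ai)
                amult = float(np.exp(rng.normal(0.0, cfg.animal_effect_sd))) if cfg.animal_effect_sd > 0 else 1.0
                # animal random effect scales area median and count mean
                a_median = p.median_area_um2 * amult
                a_mu_count = mu_count * amult
                animal_id = f"{g}-a{ai}"
                for si in range(cfg.n_sections_per_animal):
                    section_id = f"{animal_id}-s{si}"
                    for ti in range(cfg.n_tiles_per_section):
                        tile_id = f"{section_id}-{l}-t{ti:03d}"
                        tiles.append((tile_id, section_id, l, W, H, W * H))
                        if var > a_mu_count:
                            k = a_mu_count ** 2 / (var - a_mu_count)
                            m = int(rng.negative_binomial(k, k / (k + a_mu_count)))
                        else:
                            m = int(rng.poisson(a_mu_count))
                        if m == 0:
                            continue
                        z_area = rng.normal(0.0, 1.0, m)
                        z_aspect = rng.normal(0.0, 1.0, m)
                        thetas = rng.uniform(0.0, np.pi, m)
                        cfrac = rng.uniform(0.0, 1.0, (m, 2))
                        areas = a_median * np.exp(p.area_log_sd * z_area)
                        aspects = 1.0 + (p.aspect_median - 1.0) * np.exp(cfg.aspect_log_sd * z_aspect)
                        pts = _ellipse_ngons(areas, aspects, thetas, cfg.n_vertices)
                        r = np.linalg.norm(pts, axis=2).max(axis=1)
                        if np.any((2 * r > W) | (2 * r > H)):
                            big = float(areas[(2 * r > W) | (2 * r > H)].max())
                            raise GenerationError(
                                f"object of area {big:.3g} um^2 cannot fit in tile {tile_id}"
                            )
                        centers = np.column_stack(
                            [r + cfrac[:, 0] * (W - 2 * r), r + cfrac[:, 1] * (H - 2 * r)]
                        )
                        pts = pts + centers[:, None, :]
                        for oi in range(m):
                            obj_rows.append(
                                (
                                    g,
                                    animal_id,
                                    section_id,
                                    l,
                                    tile_id,
                                    f"{tile_id}-{prefix}{oi:03d}",
                                    cfg.object_class,
                                    pts[oi],
                                )
                            )

    ds = HierarchicalDataset(
        animals=pd.DataFrame(animals, columns=["animal_id", "genotype"]).drop_duplicates(ignore_index=True),
        sections=pd.DataFrame(sections, columns=["section_id", "animal_id"]).drop_duplicates(ignore_index=True),
        tiles=pd.DataFrame(tiles, columns=["tile_id", "section_id", "layer", "width_um", "height_um", "area_um2"]),
        objects=pd.DataFrame(obj_rows, columns=["genotype", "animal_id", "section_id", "layer", "tile_id", "object_id", "object_class", "vertices"]),
        provenance={"generator": "dendromito.synth.generate_morphology", "seed": cfg.seed,
                    "object_class": cfg.object_class},
    )
    return ds


def _ellipse_ngons(areas, aspects, thetas, n_vertices: int) -> np.ndarray:
    """Batch of rotated ellipse n-gons, shape (m, n_vertices, 2)."""
    areas = np.asarray(areas, dtype=float)
    aspects = np.asarray(aspects, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    r_short = np.sqrt(areas / (np.pi * aspects))
    r_long = aspects * r_short
    t = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    # rescale the inscribed n-gon (area = n/2 * a*b*sin(2pi/n)) to exact area
    scale = np.sqrt(areas / (0.5 * n_vertices * r_long * r_short * math.sin(2.0 * np.pi / n_vertices)))
    x = (scale * r_long)[:, None] * np.cos(t)[None, :]
    y = (scale * r_short)[:, None] * np.sin(t)[None, :]
    c, s = np.cos(thetas), np.sin(thetas)
    pts = np.empty((len(areas), n_vertices, 2))
    pts[:, :, 0] = c[:, None] * x - s[:, None] * y
    pts[:, :, 1] = s[:, None] * x + c[:, None] * y
    return pts


# ---------------------------------------------------------------------------
# field-potential generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FPSynthConfig:
    """Evoked field-potential generator settings.

    ``noise_sd`` and ``drift_slope_per_min`` are fractions of the
    baseline amplitude; ``plasticity_multiplier`` is the
    post-conditioning asymptote relative to baseline (``None`` picks a
    conventional value per outcome: LTP 1.5, LTD 0.8, no-change 1.0).
    """

    baseline_amplitude: float = 1.0
    noise_sd: float = 0.05
    drift_slope_per_min: float = 0.0
    plasticity_multiplier: float | None = None
    pre_duration_min: float = 10.0
    post_duration_min: float = 60.0
    sampling_hz: float = 0.1
    ramp_min: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_amplitude <= 0:
            raise ValueError("baseline_amplitude must be positive")
        if self.pre_duration_min <= 0 or self.post_duration_min <= 0 or self.sampling_hz <= 0:
            raise ValueError("durations and sampling rate must be positive")
        if self.plasticity_multiplier is not None and self.plasticity_multiplier <= 0:
            raise ValueError("plasticity_multiplier must be positive")


OUTCOME_MULTIPLIERS = {"LTP": 1.5, "LTD": 0.8, "no_change": 1.0}

#: Conditioning gap between pre and post phases (three 100 Hz/1 s trains
#: separated by two 10-min rests); metadata only, no samples generated.
CONDITIONING_GAP_S = 1200.0


def generate_fp(cfg: FPSynthConfig, outcome: str = "no_change"):
    """Generate an :class:`~dendromito.plasticity.FPRecording`.

    60 pre samples and 360 post samples at the default 0.1 Hz; the
    expected post/pre ratio equals the plasticity multiplier (the ramp to
    the asymptote is complete well before the last 5 min of the post
    phase).  Seed-deterministic.
    """
    from .plasticity import FPRecording  # local import to avoid a cycle

    if outcome not in OUTCOME_MULTIPLIERS:
        raise ValueError(f"unknown outcome: {outcome!r}")
    mult = cfg.plasticity_multiplier if cfg.plasticity_multiplier is not None else OUTCOME_MULTIPLIERS[outcome]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(hash(outcome) % (2**31),)))

    dt = 1.0 / cfg.sampling_hz
    n_pre = int(round(cfg.pre_duration_min * 60.0 * cfg.sampling_hz))
    n_post = int(round(cfg.post_duration_min * 60.0 * cfg.sampling_hz))
    pre_t = dt * (np.arange(n_pre) + 1)
    post_rel = dt * (np.arange(n_post) + 1)
    post_t = pre_t[-1] + CONDITIONING_GAP_S + post_rel

    A = cfg.baseline_amplitude
    drift = cfg.drift_slope_per_min / 60.0  # per second, fractional
    pre = A * (1.0 + drift * pre_t) + A * cfg.noise_sd * rng.normal(size=n_pre)
    ramp = 1.0 + (mult - 1.0) * np.minimum(1.0, post_rel / (cfg.ramp_min * 60.0))
    post = A * ramp + A * cfg.noise_sd * rng.normal(size=n_post)

    return FPRecording(
        pre_t=pre_t,
        pre_amplitudes=pre,
        post_t=post_t,
        post_amplitudes=post,
        sampling_hz=cfg.sampling_hz,
        meta={"outcome": outcome, "multiplier": mult, "seed": cfg.seed},
    )
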