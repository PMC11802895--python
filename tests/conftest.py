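import numpy as np
import pandas as pd
import pytest

import dendromito as dm


@pytest.fixture(scope="session")
def small_ds():
    """Small full-pipeline dataset: metrics, size filter and NN computed."""
    cfg = dm.mito_config(seed=42, n_tiles_per_section=6)
    ds = dm.generate_morphology(cfg)
    dm.compute_metrics(ds)
    ds, _ = dm.apply_size_filter(ds)
    dm.annotate_nn(ds)
    return ds


@pytest.fixture(scope="session")
def paper_scale_ds():
    """Paper-scale dataset (3 animals x 3 sections x 50 tiles per layer)."""
    ds = dm.generate_morphology(dm.mito_config(seed=7))
    dm.compute_metrics(ds)
    ds, _ = dm.apply_size_filter(ds)
    return ds


@pytest.fixture(scope="session")
def sensitivity_ds():
    """Calibration dataset for tile-sampling sensitivity.

    No animal random effect and a large (100-tile) per-section pool, so
    run-to-run bootstrap variability is dominated by the tile-sampling
    noise the sensitivity analysis probes.
    """
    ds = dm.generate_morphology(
        dm.null_config(seed=5, animal_effect_sd=0.0, n_tiles_per_section=100)
    )
    dm.compute_metrics(ds)
    ds, _ = dm.apply_size_filter(ds)
    return ds


def make_flat_dataset(values_by_tile, genotype="CTL", layer="SLM", metric="area_um2"):
    """Hand-built dataset whose object metric values are given per tile.

    ``values_by_tile`` maps (animal, section, tile) index tuples to lists
    of metric values.  Footprints are small squares (geometry irrelevant
    for bootstrap tests).
    """
    animals, sections, tiles, objects = set(), set(), [], []
    rows = []
    for (ai, si, ti), vals in values_by_tile.items():
        animal_id = f"{genotype}-a{ai}"
        section_id = f"{animal_id}-s{si}"
        tile_id = f"{section_id}-{layer}-t{ti:03d}"
        animals.add((animal_id, genotype))
        sections.add((section_id, animal_id))
        tiles.append((tile_id, section_id, layer, 12.2, 8.2, 12.2 * 8.2))
        for oi, v in enumerate(vals):
            x = 0.5 + 0.1 * oi
            sq = [(x, 0.5), (x + 0.05, 0.5), (x + 0.05, 0.55), (x, 0.55)]
            rows.append(
                {
                    "genotype": genotype,
                    "animal_id": animal_id,
                    "section_id": section_id,
                    "layer": layer,
                    "tile_id": tile_id,
                    "object_id": f"{tile_id}-m{oi:03d}",
                    "object_class": "mitochondrion",
                    "vertices": sq,
                    metric: float(v),
                }
            )
    return dm.HierarchicalDataset(
        animals=pd.DataFrame(sorted(animals), columns=["animal_id", "genotype"]),
        sections=pd.DataFrame(sorted(sections), columns=["section_id", "animal_id"]),
        tiles=pd.DataFrame(
            tiles, columns=["tile_id", "section_id", "layer", "width_um", "height_um", "area_um2"]
        ),
        objects=pd.DataFrame(rows),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
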