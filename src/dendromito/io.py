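"""Flat-file object tables and config files.

The object table is one CSV row per segmented object with the hierarchy
keys, the polygon vertex list JSON-encoded in a single column, and any
metric columns appended by the pipeline.  The schema is this package's
own (segmentation-platform exports are not standardized); tile geometry
travels in ``tile_width_um``/``tile_height_um`` columns so a table is
self-contained.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    METRIC_COLUMNS,
    TILE_HEIGHT_UM,
    TILE_WIDTH_UM,
    HierarchicalDataset,
    SchemaError,
)

CSV_COLUMNS = [
    "genotype",
    "animal_id",
    "section_id",
    "layer",
    "tile_id",
    "object_id",
    "object_class",
    "vertices_json",
    "tile_width_um",
    "tile_height_um",
]


def load_objects(path, schema: str = "object_table") -> HierarchicalDataset:
    """Read an object-table CSV into a validated :class:`HierarchicalDataset`.

    Raises
    ------
    SchemaError
        if a required column is absent (the error names the column).
    IntegrityError / ValidationError
        propagated from dataset validation (dangling keys, bad enums,
        degenerate polygons).
    """
    if schema != "object_table":
        raise SchemaError(f"unknown schema: {schema!r}")
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip",
                     dtype={"genotype": str, "animal_id": str, "section_id": str,
                            "layer": str, "tile_id": str, "object_id": str,
                            "object_class": str})
    for col in CSV_COLUMNS[:8]:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    if "tile_width_um" not in df.columns:
        df["tile_width_um"] = TILE_WIDTH_UM
    if "tile_height_um" not in df.columns:
        df["tile_height_um"] = TILE_HEIGHT_UM

    objects = df[["genotype", "animal_id", "section_id", "layer", "tile_id",
                  "object_id", "object_class"]].copy()
    objects["vertices"] = [
        [tuple(v) for v in json.loads(s)] for s in df["vertices_json"]
    ]
    for c in METRIC_COLUMNS:
        if c in df.columns:
            objects[c] = df[c].to_numpy(float)

    animals = (
        df[["animal_id", "genotype"]].drop_duplicates().sort_values("animal_id", ignore_index=True)
    )
    sections = (
        df[["section_id", "animal_id"]].drop_duplicates().sort_values("section_id", ignore_index=True)
    )
    tiles = df[["tile_id", "section_id", "layer", "tile_width_um", "tile_height_um"]].drop_duplicates(
        subset="tile_id"
    )
    tiles = tiles.rename(columns={"tile_width_um": "width_um", "tile_height_um": "height_um"})
    tiles["area_um2"] = tiles["width_um"] * tiles["height_um"]
    tiles = tiles.sort_values("tile_id", ignore_index=True)

    return HierarchicalDataset(
        animals=animals,
        sections=sections,
        tiles=tiles,
        objects=objects.sort_values("object_id", ignore_index=True),
        provenance={"source": str(path)},
    )


def write_objects(dataset: HierarchicalDataset, path) -> None:
    """Write a dataset back to the object-table CSV (canonical row order).

    ``write_objects(load_objects(f), g)`` reproduces ``f`` byte-for-byte for
    tables this package wrote, because rows are sorted by ``object_id`` and
    floats are serialized at full double precision.
    """
    path = Path(path)
    ds = dataset.sorted_copy()
    geno = ds.objects["animal_id"].map(ds.animals.set_index("animal_id")["genotype"])
    tiles = ds.tiles.set_index("tile_id")
    out = pd.DataFrame(
        {
            "genotype": geno.to_numpy(),
            "animal_id": ds.objects["animal_id"],
            "section_id": ds.objects["section_id"],
            "layer": ds.objects["tile_id"].map(tiles["layer"]).to_numpy(),
            "tile_id": ds.objects["tile_id"],
            "object_id": ds.objects["object_id"],
            "object_class": ds.objects["object_class"],
            "vertices_json": [
                json.dumps([[float(x), float(y)] for x, y in verts], separators=(",", ":"))
                for verts in ds.objects["vertices"]
            ],
            "tile_width_um": ds.objects["tile_id"].map(tiles["width_um"]).to_numpy(float),
            "tile_height_um": ds.objects["tile_id"].map(tiles["height_um"]).to_numpy(float),
        }
    )
    for c in METRIC_COLUMNS:
        if c in ds.objects.columns:
            out[c] = ds.objects[c].to_numpy(float)
    out.to_csv(path, index=False)


def load_fp_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Read a field-potential CSV (``time_s, amplitude, phase``).

    Returns ``(pre_t, pre_amp, post_t, post_amp)``.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "amplitude", "phase"):
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    pre = df[df["phase"] == "pre"]
    post = df[df["phase"] == "post"]
    return (
        pre["time_s"].to_numpy(float),
        pre["amplitude"].to_numpy(float),
        post["time_s"].to_numpy(float),
        post["amplitude"].to_numpy(float),
    )


def load_config(path) -> dict:
    """Load a YAML/JSON config (calibration, thresholds, bootstrap, seeds)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
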