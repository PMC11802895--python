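"""Per-tile densities, nearest-neighbor distances, control normalization.

Counts and total object area are rescaled to a 100 um^2 reference tile
so that partial tiles remain comparable.  Nearest-neighbor search is
confined within each tile: tiles are non-adjacent samples from a
systematic sampling scheme, so cross-tile distances are not meaningful.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import HierarchicalDataset

logger = logging.getLogger(__name__)


def nn_distances(centroids) -> np.ndarray:
    """Each object's Euclidean distance to its nearest neighbor (same tile).

    ``centroids`` is an ``(n, 2)`` array with n >= 2.  Uses a k-d tree;
    equals the O(n^2) brute force exactly.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need an (n>=2, 2) array of centroids")
    dist, _ = cKDTree(pts).query(pts, k=2)
    return dist[:, 1]


def annotate_nn(dataset: HierarchicalDataset, object_class: str | None = None) -> HierarchicalDataset:
    """Append ``nn_dist_um`` per object; tiles with <2 objects are skipped.

    Distances are centroid-to-centroid within a tile and within one
    object class.  Skipped tiles contribute NaN (no sentinel values).
    """
    obj = dataset.objects
    if "centroid_x" not in obj.columns:
        raise ValueError("annotate_nn requires computed centroids (run compute_metrics)")
    nn = np.full(len(obj), np.nan)
    classes = [object_class] if object_class else obj["object_class"].unique()
    n_skipped = 0
    for cls in classes:
        cls_mask = obj["object_class"] == cls
        for tile_id, sub in obj[cls_mask].groupby("tile_id", sort=False):
            if len(sub) < 2:
                n_skipped += 1
                continue
            pts = sub[["centroid_x", "centroid_y"]].to_numpy(float)
            nn[sub.index.to_numpy()] = nn_distances(pts)
    dataset.objects["nn_dist_um"] = nn
    if n_skipped:
        logger.info("nearest-neighbor: skipped %d tiles with <2 objects", n_skipped)
    return dataset


def tile_summary(tile_area_um2: float, n_objects: int, total_object_area_um2: float) -> dict:
    """Count and total area rescaled per 100 um^2 of tile."""
    if tile_area_um2 <= 0:
        raise ValueError("tile area must be positive")
    scale = 100.0 / tile_area_um2
    return {
        "count_per_100um2": n_objects * scale,
        "total_area_per_100um2": total_object_area_um2 * scale,
    }


def tile_summaries(dataset: HierarchicalDataset, object_class: str = "mitochondrion") -> pd.DataFrame:
    """One row per tile: genotype, layer, count and total area per 100 um^2.

    Tiles with zero objects of the class are included with zeros — a
    sampled tile with nothing in it is still an observation.
    """
    obj = dataset.objects
    sub = obj[obj["object_class"] == object_class]
    if "area_um2" not in obj.columns:
        raise ValueError("tile_summaries requires computed area_um2")
    per_tile = sub.groupby("tile_id").agg(
        n_objects=("object_id", "size"), total_area=("area_um2", "sum")
    )
    tiles = dataset.tiles.set_index("tile_id")
    geno = dataset.sections.merge(dataset.animals, on="animal_id").set_index("section_id")["genotype"]
    out = pd.DataFrame(index=tiles.index)
    out["layer"] = tiles["layer"]
    out["genotype"] = tiles["section_id"].map(geno)
    out["section_id"] = tiles["section_id"]
    out["animal_id"] = tiles["section_id"].map(dataset.sections.set_index("section_id")["animal_id"])
    n = per_tile["n_objects"].reindex(tiles.index).fillna(0).to_numpy(float)
    a = per_tile["total_area"].reindex(tiles.index).fillna(0.0).to_numpy(float)
    scale = 100.0 / tiles["area_um2"].to_numpy(float)
    out["count_per_100um2"] = n * scale
    out["total_area_per_100um2"] = a * scale
    return out.reset_index()


def normalize_to_control(values, control_pool) -> np.ndarray:
    """Divide values by the mean of the control pool (mean of control -> 1)."""
    control = np.asarray(control_pool, dtype=float)
    if control.size == 0:
        raise ValueError("control pool is empty")
    m = control.mean()
    if not np.isfinite(m) or m <= 0:
        raise ValueError("control mean must be positive and finite")
    return np.asarray(values, dtype=float) / m
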