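"""Per-object shape descriptors and the mitochondrial size filter.

Metrics follow the conventions of 2-D EM morphometry:

* area of the polygon footprint (um^2),
* maximum Feret's diameter — the longest caliper distance across the
  object, computed as the maximum pairwise distance between convex-hull
  vertices (um),
* aspect ratio — long/short side of the minimum-area rotated bounding
  rectangle, so 1 means round and larger means elongated.

Objects outside the plausible mitochondrial size range
[0.01, 2.1] um^2 are excluded before any statistics, mirroring standard
QC of automated segmentations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
from scipy.spatial.distance import pdist
from shapely.geometry import MultiPoint, Polygon

from .model import HierarchicalDataset, ValidationError

logger = logging.getLogger(__name__)

#: Inclusive mitochondrial area bounds (um^2) used by :func:`size_filter`.
MIN_AREA_UM2 = 0.01
MAX_AREA_UM2 = 2.1


def _as_polygon(footprint) -> Polygon:
    if isinstance(footprint, Polygon):
        poly = footprint
    else:
        try:
            poly = Polygon(footprint)
        except ValueError as err:
            raise ValidationError(f"polygon needs at least 3 vertices: {err}") from err
    if len(poly.exterior.coords) < 4:  # closed ring: n vertices + repeat
        raise ValidationError("polygon needs at least 3 vertices")
    if not poly.is_valid:
        raise ValidationError("self-intersecting (non-simple) polygon")
    return poly


def polygon_area(footprint) -> float:
    """Shoelace area of a simple polygon, independent of orientation."""
    return float(_as_polygon(footprint).area)


def centroid(footprint) -> tuple[float, float]:
    c = _as_polygon(footprint).centroid
    return (float(c.x), float(c.y))


def max_feret(footprint) -> float:
    """Maximum Feret's diameter: longest distance between convex-hull points.

    Accepts any point set with >= 2 distinct vertices (degenerate segments
    are measured as their length).
    """
    pts = np.asarray(
        footprint.exterior.coords if isinstance(footprint, Polygon) else footprint,
        dtype=float,
    )
    pts = np.unique(pts, axis=0)
    if len(pts) < 2:
        raise ValidationError("degenerate geometry: all vertices identical")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    coords = np.asarray(getattr(hull, "exterior", hull).coords, dtype=float)
    return float(pdist(np.unique(coords, axis=0)).max())


def aspect_ratio(footprint) -> float:
    """Long/short side ratio of the minimum-area rotated bounding rectangle.

    Reported >= 1 so that 1 is round; rotation- and translation-invariant.
    """
    poly = _as_polygon(footprint)
    rect = poly.minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords, dtype=float)
    e1 = np.linalg.norm(coords[1] - coords[0])
    e2 = np.linalg.norm(coords[2] - coords[1])
    short, long_ = sorted((e1, e2))
    if short <= 0:
        raise ValidationError("degenerate (zero-width) polygon")
    return float(long_ / short)


def object_metrics(footprint) -> dict:
    """All shape metrics for a single footprint."""
    poly = _as_polygon(footprint)
    cx, cy = centroid(poly)
    return {
        "area_um2": polygon_area(poly),
        "feret_um": max_feret(poly),
        "aspect_ratio": aspect_ratio(poly),
        "centroid_x": cx,
        "centroid_y": cy,
    }


def _max_pairwise_grouped(vertex_lists) -> np.ndarray:
    """Max pairwise vertex distance per object, vectorized by vertex count.

    The max pairwise distance over all vertices equals the max over
    convex-hull vertices, so no hull is needed.
    """
    counts = np.array([len(v) for v in vertex_lists])
    out = np.empty(len(vertex_lists))
    for k in np.unique(counts):
        idx = np.nonzero(counts == k)[0]
        pts = np.stack([np.asarray(vertex_lists[i], dtype=float) for i in idx])
        for lo in range(0, len(idx), 4000):
            sl = slice(lo, lo + 4000)
            p = pts[sl]
            d2 = ((p[:, :, None, :] - p[:, None, :, :]) ** 2).sum(-1)
            out[idx[sl]] = np.sqrt(d2.reshape(len(p), -1).max(1))
    return out


def compute_metrics(dataset: HierarchicalDataset) -> HierarchicalDataset:
    """Append area/Feret/aspect/centroid columns to ``dataset.objects``.

    Vectorized over objects (shapely ufuncs); returns the same dataset
    (modified in place) for chaining.
    """
    verts = list(dataset.objects["vertices"])
    geoms = np.array([Polygon(v) for v in verts], dtype=object)
    bad = ~shapely.is_valid(geoms)
    if bad.any():
        ids = dataset.objects["object_id"].to_numpy()[bad][:10]
        raise ValidationError(f"self-intersecting polygon(s): {list(ids)}")
    obj = dataset.objects
    obj["area_um2"] = shapely.area(geoms)
    cent = shapely.get_coordinates(shapely.centroid(geoms))
    obj["centroid_x"], obj["centroid_y"] = cent[:, 0], cent[:, 1]
    env = shapely.oriented_envelope(geoms)
    coords = shapely.get_coordinates(env)
    if len(coords) == 5 * len(geoms):
        c = coords.reshape(-1, 5, 2)
        e1 = np.linalg.norm(c[:, 1] - c[:, 0], axis=1)
        e2 = np.linalg.norm(c[:, 2] - c[:, 1], axis=1)
        short = np.minimum(e1, e2)
        if np.any(short <= 0):
            raise ValidationError("degenerate (zero-width) polygon")
        obj["aspect_ratio"] = np.maximum(e1, e2) / short
    else:  # some envelope degenerated to a segment/point
        obj["aspect_ratio"] = [aspect_ratio(v) for v in verts]
    obj["feret_um"] = _max_pairwise_grouped(verts)
    logger.info("computed shape metrics for %d objects", len(verts))
    return dataset


def size_filter(
    objects: pd.DataFrame,
    min_area: float = MIN_AREA_UM2,
    max_area: float = MAX_AREA_UM2,
) -> tuple[pd.DataFrame, int]:
    """Keep objects with ``min_area <= area_um2 <= max_area`` (inclusive).

    Returns ``(kept, n_excluded)``; the excluded count is also logged.
    """
    if "area_um2" not in objects.columns:
        raise ValidationError("size_filter requires computed area_um2")
    area = objects["area_um2"].to_numpy(float)
    keep = (area >= min_area) & (area <= max_area)
    n_excluded = int((~keep).sum())
    logger.info("size filter [%g, %g] um^2 excluded %d of %d objects",
                min_area, max_area, n_excluded, len(objects))
    return objects[keep].copy(), n_excluded


def apply_size_filter(
    dataset: HierarchicalDataset,
    min_area: float = MIN_AREA_UM2,
    max_area: float = MAX_AREA_UM2,
    object_class: str = "mitochondrion",
) -> tuple[HierarchicalDataset, int]:
    """Size-filter one object class of a dataset, leaving other classes alone."""
    obj = dataset.objects
    is_class = obj["object_class"] == object_class
    kept_class, n_excluded = size_filter(obj[is_class], min_area, max_area)
    dataset.objects = (
        pd.concat([kept_class, obj[~is_class]])
        .sort_values("object_id", ignore_index=True)
    )
    return dataset, n_excluded
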