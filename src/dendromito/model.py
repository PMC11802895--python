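"""Shared data model for the nested EM morphometry pipeline.

The dataset is a four-level hierarchy — animal (genotype) > hippocampal
section > image tile > segmented object — mirroring how systematically
sampled electron-microscopy tiles of CA2 neuropil are acquired and
segmented.  Objects are polygon footprints in tile-local micrometre
coordinates; everything downstream (morphometrics, per-tile densities,
the hierarchical bootstrap) consumes this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon


class SchemaError(ValueError):
    """An input table is missing a required column or has a bad dtype."""


class IntegrityError(ValueError):
    """A foreign key dangles or an enum/hierarchy invariant is violated."""


class ValidationError(ValueError):
    """A record-level invariant fails (e.g. a degenerate polygon)."""


class GenerationError(RuntimeError):
    """The synthetic generator cannot satisfy a geometric constraint."""


class Genotype(str, Enum):
    CTL = "CTL"
    CKO = "cKO"


class Layer(str, Enum):
    """CA2 dendritic layers: basal, proximal and distal dendrites."""

    SO = "SO"
    SR = "SR"
    SLM = "SLM"


class ObjectClass(str, Enum):
    MITOCHONDRION = "mitochondrion"
    SPINE_HEAD = "spine_head"


#: Nominal tile geometry: ~100 um^2 sampling units cut from larger ROIs.
TILE_WIDTH_UM = 12.2
TILE_HEIGHT_UM = 8.2


@dataclass(frozen=True)
class PixelCalibration:
    """Length-per-pixel calibration of the SEM images (default 2 nm/px)."""

    pixel_size_nm: float = 2.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")


def px_to_um(length_px, cal: PixelCalibration = PixelCalibration()):
    """Convert a pixel length to micrometres: px * nm_per_px / 1000."""
    length_px = np.asarray(length_px, dtype=float)
    if np.any(length_px < 0):
        raise ValueError("pixel lengths must be non-negative")
    return length_px * (cal.pixel_size_nm / 1000.0)


def px2_to_um2(area_px, cal: PixelCalibration = PixelCalibration()):
    """Convert a pixel area to um^2: px^2 * (nm_per_px / 1000)^2."""
    area_px = np.asarray(area_px, dtype=float)
    if np.any(area_px < 0):
        raise ValueError("pixel areas must be non-negative")
    return area_px * (cal.pixel_size_nm / 1000.0) ** 2


# Column schemas.  ``objects`` carries one row per segmented object with its
# polygon vertex list; metric columns are appended by the pipeline stages.
OBJECT_COLUMNS = [
    "genotype",
    "animal_id",
    "section_id",
    "layer",
    "tile_id",
    "object_id",
    "object_class",
    "vertices",
]
METRIC_COLUMNS = ["area_um2", "feret_um", "aspect_ratio", "centroid_x", "centroid_y", "nn_dist_um"]


@dataclass
class HierarchicalDataset:
    """Validated container for the animal > section > tile > object hierarchy.

    Attributes
    ----------
    animals : DataFrame with columns ``animal_id, genotype``.
    sections : DataFrame with columns ``section_id, animal_id``.
    tiles : DataFrame with columns
        ``tile_id, section_id, layer, width_um, height_um, area_um2``.
    objects : DataFrame with :data:`OBJECT_COLUMNS` (``vertices`` is a list of
        ``(x, y)`` tuples in tile-local um, counter-clockwise, closing edge
        implicit) plus any metric columns appended downstream.
    provenance : free-form record of where the data came from (synthetic
        config + seed, or an input path).
    """

    animals: pd.DataFrame
    sections: pd.DataFrame
    tiles: pd.DataFrame
    objects: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check enum values, referential integrity and polygon sanity."""
        for frame, cols in (
            (self.animals, ["animal_id", "genotype"]),
            (self.sections, ["section_id", "animal_id"]),
            (self.tiles, ["tile_id", "section_id", "layer", "width_um", "height_um", "area_um2"]),
            (self.objects, OBJECT_COLUMNS),
        ):
            for c in cols:
                if c not in frame.columns:
                    raise SchemaError(f"missing required column: {c!r}")

        valid_geno = {g.value for g in Genotype}
        bad = set(self.animals["genotype"]) - valid_geno
        if bad:
            raise IntegrityError(f"invalid genotype value(s): {sorted(bad)}")
        valid_layer = {l.value for l in Layer}
        bad = set(self.tiles["layer"]) - valid_layer
        if bad:
            raise IntegrityError(f"invalid layer value(s): {sorted(bad)}")
        valid_class = {c.value for c in ObjectClass}
        bad = set(self.objects["object_class"]) - valid_class
        if bad:
            raise IntegrityError(f"invalid object_class value(s): {sorted(bad)}")

        for name, ids in (
            ("animal_id", self.animals["animal_id"]),
            ("section_id", self.sections["section_id"]),
            ("tile_id", self.tiles["tile_id"]),
            ("object_id", self.objects["object_id"]),
        ):
            if ids.duplicated().any():
                raise IntegrityError(f"duplicate {name} values")

        # every section belongs to exactly one animal, etc.
        if not set(self.sections["animal_id"]) <= set(self.animals["animal_id"]):
            raise IntegrityError("section references unknown animal_id")
        if not set(self.tiles["section_id"]) <= set(self.sections["section_id"]):
            raise IntegrityError("tile references unknown section_id")
        if not set(self.objects["tile_id"]) <= set(self.tiles["tile_id"]):
            raise IntegrityError("object references unknown tile_id")

        area = self.tiles["area_um2"].to_numpy(float)
        wh = (self.tiles["width_um"] * self.tiles["height_um"]).to_numpy(float)
        if np.any(np.abs(area - wh) > 1e-6):
            raise IntegrityError("tile area_um2 inconsistent with width_um * height_um")

        if len(self.objects):
            oids = self.objects["object_id"].to_numpy()
            vert_lists = list(self.objects["vertices"])
            lens = np.array([len(v) for v in vert_lists])
            if np.any(lens < 3):
                bad = list(oids[lens < 3][:10])
                raise ValidationError(f"polygon with <3 vertices for object(s): {bad}")
            cat = np.concatenate([np.asarray(v, dtype=float) for v in vert_lists])
            starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
            xmin = np.minimum.reduceat(cat[:, 0], starts)
            xmax = np.maximum.reduceat(cat[:, 0], starts)
            ymin = np.minimum.reduceat(cat[:, 1], starts)
            ymax = np.maximum.reduceat(cat[:, 1], starts)
            w = self.objects["tile_id"].map(self.tiles.set_index("tile_id")["width_um"]).to_numpy(float)
            h = self.objects["tile_id"].map(self.tiles.set_index("tile_id")["height_um"]).to_numpy(float)
            oob = (xmin < -1e-9) | (ymin < -1e-9) | (xmax > w + 1e-9) | (ymax > h + 1e-9)
            if oob.any():
                raise ValidationError(
                    f"footprint outside tile bounds for object(s): {list(oids[oob][:10])}"
                )
            geoms = np.array([Polygon(v) for v in vert_lists], dtype=object)
            bad = ~shapely.is_valid(geoms)
            if bad.any():
                raise ValidationError(
                    f"self-intersecting (non-simple) polygon for object(s): {list(oids[bad][:10])}"
                )

    # -- convenience --------------------------------------------------------

    def object_table(self) -> pd.DataFrame:
        """Flat per-object table with hierarchy keys (copy)."""
        return self.objects.copy()

    def group_mask(self, genotype: str, layer: str) -> pd.Series:
        tiles_layer = self.tiles.set_index("tile_id")["layer"]
        geno = (
            self.objects["animal_id"]
            .map(self.animals.set_index("animal_id")["genotype"])
        )
        return (geno == str(genotype)) & (self.objects["tile_id"].map(tiles_layer) == str(layer))

    def n_objects(self) -> int:
        return len(self.objects)

    def sorted_copy(self) -> "HierarchicalDataset":
        """Canonically ordered copy (sorting never affects statistics)."""
        return HierarchicalDataset(
            animals=self.animals.sort_values("animal_id", ignore_index=True),
            sections=self.sections.sort_values("section_id", ignore_index=True),
            tiles=self.tiles.sort_values("tile_id", ignore_index=True),
            objects=self.objects.sort_values("object_id", ignore_index=True),
            provenance=dict(self.provenance),
        )
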