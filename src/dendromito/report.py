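"""Summary tables over the nested dataset.

`summary_table` reproduces the shape of a classic EM-morphometry summary:
one row per genotype x layer with the median and sample standard
deviation (n-1 denominator) of each object metric over the pooled
objects, the per-tile density metrics over tiles, and exact Ns (mice,
objects, tiles).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import Genotype, HierarchicalDataset, Layer
from .spatial import tile_summaries

OBJECT_METRIC_COLS = ["area_um2", "feret_um", "aspect_ratio", "nn_dist_um"]
TILE_METRIC_COLS = ["count_per_100um2", "total_area_per_100um2"]


def _median_std(x: np.ndarray) -> tuple[float, float]:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return (np.nan, np.nan)
    med = float(np.median(x))
    std = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return med, std


def summary_table(dataset: HierarchicalDataset, object_class: str = "mitochondrion") -> pd.DataFrame:
    """Median (std) per genotype x layer for every metric, plus exact Ns.

    Requires computed object metrics.  Groups with no objects are still
    emitted, with N = 0 and null statistics.
    """
    obj = dataset.objects
    missing = [c for c in OBJECT_METRIC_COLS[:3] if c not in obj.columns]
    if missing:
        raise ValueError(f"summary_table requires computed metrics; missing {missing}")
    obj = obj[obj["object_class"] == object_class]
    tiles = tile_summaries(dataset, object_class=object_class)

    rows = []
    for g in Genotype:
        for l in Layer:
            o = obj[(obj["genotype"] == g.value) & (obj["layer"] == l.value)]
            t = tiles[(tiles["genotype"] == g.value) & (tiles["layer"] == l.value)]
            row = {
                "genotype": g.value,
                "layer": l.value,
                "n_mice": int(o["animal_id"].nunique()),
                "n_objects": int(len(o)),
                "n_tiles": int(len(t)),
            }
            for c in OBJECT_METRIC_COLS:
                vals = o[c].to_numpy(float) if c in o.columns else np.empty(0)
                med, std = _median_std(vals)
                row[f"{c}_median"], row[f"{c}_std"] = med, std
            for c in TILE_METRIC_COLS:
                med, std = _median_std(t[c].to_numpy(float))
                row[f"{c}_median"], row[f"{c}_std"] = med, std
            rows.append(row)
    return pd.DataFrame(rows)


def plasticity_summary(outcomes) -> dict:
    """Group summary of classified recordings: mean ratio +/- sem and tally."""
    ratios = np.array([o.post_pre_ratio for o in outcomes], dtype=float)
    ok = np.isfinite(ratios)
    tally = {}
    for o in outcomes:
        key = o.classification.value
        tally[key] = tally.get(key, 0) + 1
    n = int(ok.sum())
    return {
        "n": len(list(outcomes)),
        "mean_post_pre_ratio": float(ratios[ok].mean()) if n else float("nan"),
        "sem_post_pre_ratio": float(ratios[ok].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "outcomes": tally,
    }
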