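"""File I/O: TIFF images, metric/graph CSVs, ROI JSON, shade YAML."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .image_pipeline import OutgrowthMetrics, SkeletonGraph
from .ir_quant import ReferenceShades, RegionOfInterest
from .synthetic_data import OutgrowthGroundTruth

__all__ = [
    "read_image",
    "write_image",
    "metrics_to_frame",
    "graph_to_frames",
    "write_ground_truth",
    "load_rois",
    "load_shades",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF as stored (RGB stays channels-last)."""
    return tifffile.imread(str(path))


def as_channel_stack(img: np.ndarray) -> np.ndarray:
    """Normalize a multi-channel micrograph to channels-first."""
    if img.ndim == 3 and img.shape[0] > 8 >= img.shape[-1]:
        return np.moveaxis(img, -1, 0)
    return img


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), image)


def metrics_to_frame(metrics: OutgrowthMetrics, explant_id: str = "explant") -> pd.DataFrame:
    """One summary row per explant."""
    return pd.DataFrame(
        [
            {
                "explant_id": explant_id,
                "n_endings": metrics.n_endings,
                "n_branch_points": metrics.n_branch_points,
                "n_start_points": metrics.n_start_points,
                "median_length_um": metrics.median_length_um,
                "longest_um": metrics.longest_um,
                "total_length_um": metrics.total_length_um,
                "projected_area_um2": metrics.projected_area_um2,
            }
        ]
    )


def graph_to_frames(sg: SkeletonGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(nodes, edges) tables; coordinates are 0-based (row, col)."""
    nodes = pd.DataFrame(
        [
            {"node_id": n, "r": d["rc"][0], "c": d["rc"][1], "role": d["role"]}
            for n, d in sg.g.nodes(data=True)
        ]
    )
    edges = pd.DataFrame(
        [
            {"u": u, "v": v, "key": k, "length_um": d["length_um"], "n_pixels": len(d["path"])}
            for u, v, k, d in sg.g.edges(keys=True, data=True)
        ]
    )
    return nodes, edges


def write_ground_truth(gt: OutgrowthGroundTruth, out_dir: str | Path, stem: str = "truth") -> None:
    """Ground truth as CSV (one row per ending) + JSON (geometry)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "r": gt.endings[:, 0] if len(gt.endings) else [],
            "c": gt.endings[:, 1] if len(gt.endings) else [],
            "length_um": gt.lengths_um,
        }
    ).to_csv(out / f"{stem}_endings.csv", index=False)
    geom = {
        "pixel_size_um": gt.pixel_size_um,
        "total_length_um": gt.total_length_um,
        "body_polygon": gt.body_polygon.tolist(),
        "start_points": gt.start_points.tolist(),
        "branch_points": gt.branch_points.tolist(),
        "neurite_paths": [p.tolist() for p in gt.neurite_paths],
    }
    (out / f"{stem}_geometry.json").write_text(json.dumps(geom))


def load_rois(path: str | Path) -> dict[str, RegionOfInterest]:
    """ROIs from GeoJSON-style JSON: mapping name -> {include: [[...]],
    exclude: [[...]]} with (row, col) vertex lists."""
    raw = json.loads(Path(path).read_text())
    rois = {}
    for name, spec in raw.items():
        rois[name] = RegionOfInterest(
            include=[np.asarray(p, dtype=float) for p in spec["include"]],
            exclude=[np.asarray(p, dtype=float) for p in spec.get("exclude", [])],
        )
    return rois


def load_shades(path: str | Path) -> ReferenceShades:
    """Reference shades from YAML: ``shades: [[r,g,b], ...]`` and
    ``tolerance``."""
    raw = yaml.safe_load(Path(path).read_text())
    return ReferenceShades(
        shades=np.asarray(raw["shades"], dtype=float),
        tolerance=float(raw.get("tolerance", 40.0)),
    )
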