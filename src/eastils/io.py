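"""Readers and writers: tiles (PNG/TIFF + JSON sidecar), detections (GeoJSON/CSV), cohorts (CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from shapely.geometry import mapping, shape

from .segmentation import CellObject
from .stain import ImageTile
from .synthetic import SyntheticGroundTruth

__all__ = [
    "save_tile",
    "load_tile",
    "cells_to_geojson",
    "geojson_to_cells",
    "cells_to_dataframe",
    "ground_truth_to_geojson",
    "save_cohort",
    "load_cohort",
]


def save_tile(tile: ImageTile, path: str | Path) -> None:
    """Write a tile as PNG or TIFF, with µm calibration in a JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, tile.pixels)
    else:
        Image.fromarray(tile.pixels).save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"microns_per_pixel": tile.microns_per_pixel, "origin_um": list(tile.origin_um)})
    )


def load_tile(path: str | Path) -> ImageTile:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {"microns_per_pixel": 0.4986}
    return ImageTile(pixels, meta["microns_per_pixel"], tuple(meta.get("origin_um", (0.0, 0.0))))


def cells_to_geojson(cells: list[CellObject]) -> dict:
    """Detections as a GeoJSON FeatureCollection (nucleus geometry, measurements in properties)."""
    features = []
    for c in cells:
        props = {
            "centroid_um": list(c.centroid_um),
            "nucleus_area_um2": c.nucleus_area_um2,
            "cell_area_um2": c.cell_area_um2,
            "class_label": c.class_label,
            "class_probabilities": c.class_probabilities,
        }
        if c.cell_polygon is not None:
            props["cell_polygon"] = mapping(c.cell_polygon)
        features.append(
            {"type": "Feature", "geometry": mapping(c.nucleus_polygon), "properties": props}
        )
    return {"type": "FeatureCollection", "features": features}


def geojson_to_cells(doc: dict) -> list[CellObject]:
    cells = []
    for feat in doc["features"]:
        p = feat["properties"]
        cells.append(
            CellObject(
                nucleus_polygon=shape(feat["geometry"]),
                centroid_um=tuple(p["centroid_um"]),
                nucleus_area_um2=p["nucleus_area_um2"],
                cell_polygon=shape(p["cell_polygon"]) if p.get("cell_polygon") else None,
                cell_area_um2=p.get("cell_area_um2"),
                class_label=p.get("class_label", "unclassified"),
                class_probabilities=p.get("class_probabilities"),
            )
        )
    return cells


def cells_to_dataframe(cells: list[CellObject]) -> pd.DataFrame:
    """Flat per-cell table (one row per cell)."""
    rows = []
    for c in cells:
        row = {
            "centroid_x_um": c.centroid_um[0],
            "centroid_y_um": c.centroid_um[1],
            "nucleus_area_um2": c.nucleus_area_um2,
            "cell_area_um2": c.cell_area_um2,
            "class_label": c.class_label,
        }
        if c.class_probabilities:
            for k, v in c.class_probabilities.items():
                row[f"p_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def ground_truth_to_geojson(gt: SyntheticGroundTruth) -> dict:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(cell.polygon),
            "properties": {
                "class_label": cell.class_label,
                "center_um": list(cell.center_um),
                "area_um2": cell.area_um2,
            },
        }
        for cell in gt.cells
    ]
    features.append(
        {
            "type": "Feature",
            "geometry": mapping(gt.region_polygon),
            "properties": {"role": "region", "eastils_percent": gt.eastils_percent},
        }
    )
    return {"type": "FeatureCollection", "features": features}


def save_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
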