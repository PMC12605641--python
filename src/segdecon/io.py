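"""Readers and writers for the pipeline's on-disk formats.

Images go through tifffile/imageio; nuclei are exchanged as GeoJSON
FeatureCollections (polygons in µm) plus centroid CSVs; spot layouts read the
Visium ``tissue_positions`` CSV dialect with its ``scalefactors_json.json``
sidecar; count matrices round-trip through AnnData (.h5ad) or CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, mapping, shape

from .segmentation import NucleusInstance
from .spot_mapping import SpotLayout

__all__ = [
    "read_image",
    "write_image",
    "nuclei_to_geojson",
    "nuclei_from_geojson",
    "nuclei_to_csv",
    "read_visium_layout",
    "write_counts_csv",
]


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    return iio.imread(path)


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def nuclei_to_geojson(nuclei: list[NucleusInstance], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(n.polygon),
            "properties": {
                "id": n.id,
                "area_um2": n.area_um2,
                "centroid": list(n.centroid),
            },
        }
        for n in nuclei
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def nuclei_from_geojson(path: str | Path) -> list[NucleusInstance]:
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        poly = shape(feat["geometry"])
        if not isinstance(poly, Polygon):
            poly = max(poly.geoms, key=lambda g: g.area)
        props = feat["properties"]
        out.append(
            NucleusInstance(
                int(props["id"]), poly, tuple(props["centroid"]),
                float(props["area_um2"]),
            )
        )
    return out


def nuclei_to_csv(nuclei: list[NucleusInstance], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [n.id for n in nuclei],
            "x_um": [n.centroid[0] for n in nuclei],
            "y_um": [n.centroid[1] for n in nuclei],
            "area_um2": [n.area_um2 for n in nuclei],
        }
    ).to_csv(path, index=False)


def read_visium_layout(
    positions_csv: str | Path,
    scalefactors_json: str | Path | None = None,
    radius_um: float = 45.0,
    pitch_um: float = 100.0,
    um_per_px_fullres: float | None = None,
) -> SpotLayout:
    """Visium ``tissue_positions`` dialect: barcode, in_tissue, array_row,
    array_col, pxl_row_in_fullres, pxl_col_in_fullres.  Pixel coordinates are
    converted to µm with the full-resolution scale (from the sidecar's spot
    diameter when not given directly)."""
    df = pd.read_csv(positions_csv)
    if df.shape[1] == 6 and "barcode" not in df.columns:
        df.columns = [
            "barcode", "in_tissue", "array_row", "array_col",
            "pxl_row_in_fullres", "pxl_col_in_fullres",
        ]
    df = df[df["in_tissue"] == 1]
    scale = um_per_px_fullres
    if scale is None and scalefactors_json is not None:
        sf = json.loads(Path(scalefactors_json).read_text())
        # 55 um physical spot diameter over its full-resolution pixel size
        scale = 55.0 / float(sf["spot_diameter_fullres"])
    if scale is None:
        raise ValueError("need scalefactors_json or um_per_px_fullres")
    centers = np.column_stack(
        [df["pxl_col_in_fullres"] * scale, df["pxl_row_in_fullres"] * scale]
    )
    return SpotLayout(df["barcode"].tolist(), centers, radius_um, pitch_um)


def write_counts_csv(spot_ids, n_s, path: str | Path) -> None:
    pd.DataFrame({"spot_id": spot_ids, "n_s": np.asarray(n_s)}).to_csv(
        path, index=False
    )
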