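"""Readers and writers for the pipeline's tabular and image artifacts.

GeoJSON follows the QuPath dialect: a FeatureCollection of Polygon features
in pixel coordinates with ``classification`` and ``measurements``
properties.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

CELL_COLUMNS = [
    "cell_id", "x_um", "y_um", "area_um2", "nucleolus_diam_um",
    "nucleolus_contrast", "label", "binary_label",
]
PROFILE_COLUMNS = [
    "roi_id", "area_mm2", "n_total", "n_g3", "n_other",
    "dens_g3", "dens_other", "pct_g3",
]
COHORT_COLUMNS = ["sample_id", "grade", "dens_g3", "dens_other", "time_days", "event"]

CLASS_COLORS = {"G3": [255, 215, 0], "Other": [65, 105, 225], "": [128, 128, 128]}


def write_tile_png(path, rgb: np.ndarray) -> None:
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(path, format="PNG")


def read_tile(path) -> np.ndarray:
    img = np.asarray(Image.open(path).convert("RGB"))
    return img


def write_label_tiff(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


def read_label_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_cells_csv(path, cells: pd.DataFrame) -> None:
    cells.to_csv(path, index=False, columns=[c for c in CELL_COLUMNS if c in cells])


def read_cells_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_csv(path, truth) -> None:
    truth.to_frame().to_csv(path, index=False)


def write_profiles_csv(path, profiles: pd.DataFrame) -> None:
    profiles.to_csv(path, index=False, columns=[c for c in PROFILE_COLUMNS if c in profiles])


def read_profiles_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort_csv(path, cohort: pd.DataFrame) -> None:
    cols = [c for c in COHORT_COLUMNS if c in cohort] + [
        c for c in cohort.columns if c not in COHORT_COLUMNS
    ]
    cohort.to_csv(path, index=False, columns=cols)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def instances_to_geojson(instances, classifications=None, scale: float = 1.0) -> dict:
    """QuPath-style FeatureCollection from segmented instances.

    ``classifications`` maps instance id -> class name; unclassified
    instances carry an empty name.  Coordinates are pixels times ``scale``.
    """
    classifications = classifications or {}
    features = []
    for inst in instances:
        verts = (np.asarray(inst.polygon, dtype=float) * scale).tolist()
        verts.append(verts[0])  # closed ring
        name = classifications.get(inst.id, "")
        features.append(
            {
                "type": "Feature",
                "id": inst.id,
                "geometry": {"type": "Polygon", "coordinates": [verts]},
                "properties": {
                    "objectType": "annotation",
                    "classification": {
                        "name": name,
                        "color": CLASS_COLORS.get(name, CLASS_COLORS[""]),
                    },
                    "measurements": {"score": inst.score},
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(path, collection: dict) -> None:
    with open(path, "w") as fh:
        json.dump(collection, fh, indent=1)


def read_geojson(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def geojson_to_instances(collection: dict):
    """Rebuild lightweight instances (id, polygon vertices, score, name)."""
    out = []
    for feat in collection["features"]:
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)[:-1]
        props = feat.get("properties", {})
        out.append(
            {
                "id": feat.get("id", 0),
                "polygon": ring,
                "score": props.get("measurements", {}).get("score", 0.0),
                "name": props.get("classification", {}).get("name", ""),
            }
        )
    return out


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
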