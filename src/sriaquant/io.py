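"""Reading and writing section images, annotations and tables.

On-disk conventions:

* images: 8-bit RGB PNG or TIFF;
* calibration/provenance: JSON sidecar ``<image>.json`` with at least
  ``microns_per_pixel``, plus ``section_kind``, ``biopsy_id`` and the
  generating config/seed when the image is simulated;
* annotations: GeoJSON FeatureCollection ``<image>.geojson``; each feature
  carries a ``role`` property in {cortex, glomerulus, vessel, fold} and
  polygon coordinates in pixel units (0-based, x right, y down, integer
  coordinates are pixel centres);
* tables (pair measurements, cohort): CSV via pandas.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from shapely.geometry import mapping, shape as shapely_shape

from .quantify import BiopsyPair, RegionAnnotation, SectionImage, SriaMeasurement

__all__ = [
    "write_section_image",
    "read_section_image",
    "annotations_to_geojson",
    "annotations_from_geojson",
    "write_pair_table",
    "read_pair_table",
    "measurement_to_dict",
]


def _sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(image_path.suffix + ".json")


def _geojson_path(image_path: Path) -> Path:
    return image_path.with_suffix(image_path.suffix + ".geojson")


def annotations_to_geojson(annotations: list[RegionAnnotation]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"role": a.role},
                "geometry": mapping(a.geometry),
            }
            for a in annotations
        ],
    }


def annotations_from_geojson(doc: dict) -> list[RegionAnnotation]:
    if doc.get("type") != "FeatureCollection":
        raise ValueError("annotation document must be a GeoJSON FeatureCollection")
    out = []
    for feat in doc.get("features", []):
        role = feat.get("properties", {}).get("role")
        if role is None:
            raise ValueError("annotation feature lacks a 'role' property")
        out.append(RegionAnnotation(role=role, geometry=shapely_shape(feat["geometry"])))
    return out


def write_section_image(
    image: SectionImage,
    path: str | Path,
    config: Optional[object] = None,
) -> Path:
    """Write the raster (PNG or TIFF by extension), JSON sidecar and GeoJSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix == ".png":
        Image.fromarray(image.pixels, mode="RGB").save(path)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        raise ValueError(f"unsupported image extension {suffix!r}; use .png or .tif(f)")
    sidecar = {
        "microns_per_pixel": image.microns_per_pixel,
        "section_kind": image.section_kind,
        "biopsy_id": image.biopsy_id,
    }
    if config is not None:
        cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
        sidecar["config"] = cfg
        if "seed" in cfg:
            sidecar["seed"] = cfg["seed"]
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    _geojson_path(path).write_text(
        json.dumps(annotations_to_geojson(image.annotations), sort_keys=True)
    )
    return path


def read_section_image(
    path: str | Path,
    annotations_path: Optional[str | Path] = None,
    sidecar_path: Optional[str | Path] = None,
) -> SectionImage:
    """Load an image with its sidecar calibration and GeoJSON annotations."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        pixels = np.asarray(Image.open(path).convert("RGB"))
    elif suffix in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        raise ValueError(f"unsupported image extension {suffix!r}")
    sidecar_file = Path(sidecar_path) if sidecar_path else _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(
            f"calibration sidecar not found: {sidecar_file} (required for µm/px)"
        )
    sidecar = json.loads(sidecar_file.read_text())
    geo_file = Path(annotations_path) if annotations_path else _geojson_path(path)
    if not geo_file.exists():
        raise FileNotFoundError(f"annotation GeoJSON not found: {geo_file}")
    annotations = annotations_from_geojson(json.loads(geo_file.read_text()))
    return SectionImage(
        pixels=pixels,
        microns_per_pixel=float(sidecar["microns_per_pixel"]),
        section_kind=sidecar.get("section_kind", "paraffin"),
        annotations=annotations,
        biopsy_id=sidecar.get("biopsy_id", path.stem),
    )


def measurement_to_dict(m: SriaMeasurement) -> dict:
    return {
        "biopsy_id": m.biopsy_id,
        "section_kind": m.section_kind,
        "stained_px": m.stained_px,
        "cortex_px": m.cortex_px,
        "fraction_pct": m.fraction_pct,
        "threshold": m.threshold,
        "analysed_area_mm2": m.analysed_area_mm2,
        "channel_method": m.channel_method,
    }


def write_pair_table(pairs: list[BiopsyPair], path: str | Path) -> Path:
    """Serialise pairs to a flat CSV (one row per biopsy pair)."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "biopsy_id": p.biopsy_id,
                "sria_frozen_pct": p.frozen.fraction_pct,
                "sria_paraffin_pct": p.paraffin.fraction_pct,
                "area_frozen_mm2": p.frozen.analysed_area_mm2,
                "area_paraffin_mm2": p.paraffin.analysed_area_mm2,
                "threshold_frozen": p.frozen.threshold,
                "threshold_paraffin": p.paraffin.threshold,
                "original_if_frozen": p.original_if_frozen,
                "original_if_paraffin": p.original_if_paraffin,
                "donor_age": p.donor_age,
                "donor_male": p.donor_male,
                "donor_type": p.donor_type,
                "cit_hours": p.cit_hours,
                "included": p.included,
                "exclusion_reason": p.exclusion_reason,
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_pair_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
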