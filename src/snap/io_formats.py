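"""Readers and writers for every external file format the pipeline touches.

Images are PNG/JPEG rasters, nodule annotations use the VGG Image
Annotator (VIA) JSON dialect with rectangular regions, taproot masks are
single-channel 0/255 PNGs, and per-image quantification reports are CSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .types import BoundingBox

log = logging.getLogger(__name__)

N_POSITION_BINS = 10
REPORT_COLUMNS = (
    ["image_id", "total_count", "taproot_zone_count", "mean_box_area",
     "median_box_area", "box_area_sd", "taproot_length_px"]
    + [f"pos_bin_{i}" for i in range(N_POSITION_BINS)]
)


class FormatError(ValueError):
    """Raised when a file exists but cannot be decoded as the expected format."""


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG as an 8-bit RGB raster; grayscale is replicated to 3 channels."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"), dtype=np.uint8)
    except UnidentifiedImageError as e:
        raise FormatError(f"cannot decode image {path}: {e}") from e


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def _iter_via_entries(doc: dict):
    """Yield (filename, regions) from either VIA project saves or annotation exports."""
    entries = doc.get("_via_img_metadata", doc)
    if not isinstance(entries, dict):
        raise FormatError("VIA JSON top level is not an object")
    for key, entry in entries.items():
        if not isinstance(entry, dict) or "regions" not in entry:
            continue
        filename = entry.get("filename", key)
        regions = entry["regions"]
        if isinstance(regions, dict):  # old VIA versions index regions by string
            regions = [regions[k] for k in sorted(regions, key=str)]
        yield filename, regions


def read_vgg_annotations(path: str | Path) -> dict[str, list[BoundingBox]]:
    """Parse VIA JSON into image_id -> boxes; image_id is the filename stem.

    Only "rect" regions are meaningful; other shapes are skipped with a warning.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"malformed VIA JSON {path}: {e}") from e
    out: dict[str, list[BoundingBox]] = {}
    for filename, regions in _iter_via_entries(doc):
        image_id = Path(filename).stem
        boxes = out.setdefault(image_id, [])
        for idx, region in enumerate(regions):
            sa = region.get("shape_attributes", {})
            if sa.get("name") != "rect":
                log.warning("%s region %d of %s: non-rect shape %r skipped",
                            path, idx, image_id, sa.get("name"))
                continue
            x, y, w, h = sa["x"], sa["y"], sa["width"], sa["height"]
            if w <= 0 or h <= 0:
                raise ValueError(
                    f"{path}: image {image_id} region {idx} has non-positive size "
                    f"(width={w}, height={h})"
                )
            boxes.append(BoundingBox(x, y, x + w, y + h))
    return out


def write_vgg_annotations(annotations: dict[str, list[BoundingBox]],
                          path: str | Path, ext: str = ".png") -> None:
    """Write boxes as a VIA annotation export (one rect region per box)."""
    doc = {}
    for image_id, boxes in annotations.items():
        filename = image_id + ext
        doc[f"{filename}-1"] = {
            "filename": filename,
            "size": -1,
            "regions": [
                {
                    "shape_attributes": {
                        "name": "rect",
                        "x": b.x_min, "y": b.y_min,
                        "width": b.width, "height": b.height,
                    },
                    "region_attributes": {"label": "nodule"},
                }
                for b in boxes
            ],
            "file_attributes": {},
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG into {0,1}; any value > 127 counts as foreground."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except UnidentifiedImageError as e:
        raise FormatError(f"cannot decode mask {path}: {e}") from e
    if arr.ndim == 3:
        log.warning("%s: RGB mask reduced by channel max", path)
        arr = arr.max(axis=2)
    if arr.size == 0:
        raise ValueError(f"{path}: zero-size mask")
    return (arr > 127).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("zero-size mask")
    Image.fromarray((mask > 0).astype(np.uint8) * 255, mode="L").save(path)


def write_report(reports: list, path: str | Path) -> None:
    """Write NoduleReport rows as CSV with a fixed column order.

    Undefined statistics (no detections, or no taproot mask) are written as
    empty fields (NaN), the CSV sentinel for a missing value.
    """
    if not reports:
        raise ValueError("write_report requires a non-empty report list")
    rows = []
    for r in reports:
        row = {
            "image_id": r.image_id,
            "total_count": r.total_count,
            "taproot_zone_count": r.taproot_zone_count,
            "mean_box_area": r.mean_box_area,
            "median_box_area": r.median_box_area,
            "box_area_sd": r.box_area_sd,
            "taproot_length_px": r.taproot_length_px,
        }
        hist = r.position_histogram
        for i in range(N_POSITION_BINS):
            row[f"pos_bin_{i}"] = (hist[i] if hist is not None else np.nan)
        rows.append(row)
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
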