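"""Readers and writers for the artifact formats.

Images in as PNG/TIFF/JPEG normalised to [0, 1] (8- and 16-bit honoured,
EXIF orientation applied); label maps out as 16-bit single-channel TIFF;
object/growth/dose tables as CSV with header; scene specs and reports as
JSON. Experiment layouts aggregate per-group, per-timepoint means and SDs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image, ImageOps

from .imagesim import RenderedSample

__all__ = ["load_image", "save_image", "save_instance_map", "load_instance_map",
           "save_sample", "object_table", "write_results", "roi_from_polygon"]


def load_image(path) -> np.ndarray:
    """Read PNG/TIFF/JPEG into a float array in [0, 1].

    16-bit data keeps its full depth (divided by 65535); EXIF orientation
    tags are applied before conversion. Raises on unreadable files."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            im = ImageOps.exif_transpose(im)
            arr = np.asarray(im)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float64)
    raise ValueError(f"unsupported bit depth: {arr.dtype}")


def save_image(path, image: np.ndarray, bits: int = 8):
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=float), 0, 1)
    if bits == 16:
        data = (arr * 65535).round().astype(np.uint16)
    elif bits == 8:
        data = (arr * 255).round().astype(np.uint8)
    else:
        raise ValueError("bits must be 8 or 16")
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
    else:
        Image.fromarray(data).save(path)


def save_instance_map(path, labels: np.ndarray):
    """Label maps as 16-bit single-channel TIFF."""
    lab = np.asarray(labels)
    if lab.max() > 65535:
        raise ValueError("more than 65535 labels")
    tifffile.imwrite(Path(path), lab.astype(np.uint16))


def load_instance_map(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def object_table(sample: RenderedSample) -> pd.DataFrame:
    rows = [dataclasses.asdict(o) for o in sample.objects]
    for r in rows:
        r["centroid_y"], r["centroid_x"] = r.pop("centroid")
    return pd.DataFrame(rows, columns=["label_id", "cls", "centroid_y",
                                       "centroid_x", "diameter_px", "viability"])


def save_sample(sample: RenderedSample, stem: Path):
    """Write image (PNG), instance map (16-bit TIFF), object table (CSV)
    and scene spec (JSON) under a common path stem."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    save_image(stem.with_suffix(".png"), sample.image)
    save_instance_map(stem.parent / (stem.name + "_labels.tiff"), sample.instance_map)
    object_table(sample).to_csv(stem.with_suffix(".csv"), index=False)
    spec = dataclasses.asdict(sample.spec)
    spec["object_mix"] = [list(m) for m in spec["object_mix"]]
    (stem.with_suffix(".json")).write_text(json.dumps(spec, indent=2))


def roi_from_polygon(points, shape) -> np.ndarray:
    """Boolean mask from a polygon given as [(x, y), ...] pixel vertices."""
    from skimage.draw import polygon2mask
    pts = np.array([(y, x) for x, y in points], dtype=float)
    return polygon2mask(shape, pts)


def write_results(layout: pd.DataFrame, results: dict, csv_path, json_path=None):
    """Aggregate per-image results into per-group/timepoint mean +/- SD.

    `layout` needs columns group, replicate, timepoint, image; `results`
    maps image path -> measured value. Every image must be analysed, and a
    duplicated image path is an error. Single-replicate groups get an empty
    SD with a flag column.
    """
    if layout["image"].duplicated().any():
        raise ValueError("duplicate image paths in layout")
    missing = [p for p in layout["image"] if p not in results]
    if missing:
        raise ValueError(f"missing results for {len(missing)} images")
    df = layout.copy()
    df["value"] = df["image"].map(results)
    agg = (df.groupby(["group", "timepoint"], sort=True)["value"]
             .agg(["mean", "std", "count"]).reset_index())
    agg = agg.rename(columns={"std": "sd", "count": "n"})
    agg["single_replicate"] = agg["n"] == 1
    agg.loc[agg["single_replicate"], "sd"] = np.nan
    agg.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(agg.to_json(orient="records"))
    return agg
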