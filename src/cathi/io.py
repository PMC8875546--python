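"""Raster and report readers/writers.

PNG for 8-bit RGB images, TIFF for 16-bit label masks, CSV (6 significant
digits) for per-tubule and section reports, YAML for configurations.
CSV writing is deterministic so identical runs produce byte-identical
files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image, ImageDraw

from .geometry import Calibration
from .image import CalibratedImage
from .ihc import IHCMeasurement
from .morphometry import SectionReport, TubuleMeasurement

CSV_FLOAT_FORMAT = "%.6g"

TUBULE_CSV_COLUMNS = [
    "tubule_id",
    "tubule_area_um2",
    "tubule_perimeter_um",
    "lumen_area_um2",
    "lumen_perimeter_um",
    "tubule_d1_um",
    "tubule_d2_um",
    "tubule_davg_um",
    "lumen_d1_um",
    "lumen_d2_um",
    "lumen_davg_um",
    "se_area_um2",
    "se_area_ratio_pct",
    "se_len1_um",
    "se_len2_um",
    "se_len3_um",
    "se_len4_um",
    "se_len5_um",
    "se_thickness_mean_um",
    "is_longitudinal",
    "is_spermatid_positive",
    "sampled",
]


def write_image(path, image: CalibratedImage) -> None:
    iio.imwrite(Path(path), image.pixels)


def read_image(path, um_per_px: float) -> CalibratedImage:
    px = iio.imread(Path(path))
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[..., :3]
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {px.shape}")
    return CalibratedImage(px.astype(np.uint8), Calibration(um_per_px))


def write_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_labels(path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D label raster, got {arr.shape}")
    return arr.astype(np.int32)


def write_yaml(path, obj) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def tubules_to_dataframe(
    records: Sequence[TubuleMeasurement], sampled_ids: Sequence[int] = ()
) -> pd.DataFrame:
    sampled = set(sampled_ids)
    rows = []
    for r in records:
        lens = (
            list(r.se_thickness.lengths_um)
            if r.se_thickness is not None
            else [np.nan] * 5
        )
        rows.append(
            {
                "tubule_id": r.tubule_id,
                "tubule_area_um2": r.tubule_area_um2,
                "tubule_perimeter_um": r.tubule_perimeter_um,
                "lumen_area_um2": r.lumen_area_um2,
                "lumen_perimeter_um": r.lumen_perimeter_um,
                "tubule_d1_um": r.tubule_d1_um,
                "tubule_d2_um": r.tubule_d2_um,
                "tubule_davg_um": r.tubule_davg_um,
                "lumen_d1_um": r.lumen_d1_um,
                "lumen_d2_um": r.lumen_d2_um,
                "lumen_davg_um": r.lumen_davg_um,
                "se_area_um2": r.se_area_um2,
                "se_area_ratio_pct": r.se_area_ratio_pct,
                "se_len1_um": lens[0],
                "se_len2_um": lens[1],
                "se_len3_um": lens[2],
                "se_len4_um": lens[3],
                "se_len5_um": lens[4],
                "se_thickness_mean_um": (
                    r.se_thickness.mean_um
                    if r.se_thickness is not None
                    else np.nan
                ),
                "is_longitudinal": r.is_longitudinal,
                "is_spermatid_positive": r.is_spermatid_positive,
                "sampled": r.tubule_id in sampled,
            }
        )
    return pd.DataFrame(rows, columns=TUBULE_CSV_COLUMNS)


def section_report_to_dataframe(report: SectionReport) -> pd.DataFrame:
    d = dataclasses.asdict(report)
    d["sampled_tubule_ids"] = ";".join(
        str(i) for i in report.sampled_tubule_ids
    )
    return pd.DataFrame([d])


def ihc_to_dataframe(records: Sequence[IHCMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def write_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(Path(path), index=False, float_format=CSV_FLOAT_FORMAT)


def read_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc


def read_roi(path, shape: tuple[int, int]) -> np.ndarray:
    """Read an ROI as a mask TIFF or a polygon CSV with x,y columns."""
    from .ihc import roi_to_mask

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff", ".png"):
        if path.suffix.lower() == ".png":
            arr = iio.imread(path)
        else:
            arr = tifffile.imread(path)
        if arr.ndim == 3:
            arr = arr[..., 0]
        return roi_to_mask(arr > 0, shape)
    df = read_csv(path)
    if not {"x", "y"} <= set(df.columns):
        raise ValueError(f"{path}: polygon CSV needs 'x' and 'y' columns")
    return roi_to_mask(df[["x", "y"]].to_numpy(float), shape)


def numbered_overlay(
    image: CalibratedImage, tubule_labels: np.ndarray
) -> np.ndarray:
    """Internal-control overlay: tubule numbers drawn at their centroids."""
    img = Image.fromarray(image.pixels.copy())
    draw = ImageDraw.Draw(img)
    labels = [int(v) for v in np.unique(tubule_labels) if v != 0]
    for lab in labels:
        rows, cols = np.nonzero(tubule_labels == lab)
        draw.text(
            (float(cols.mean()), float(rows.mean())),
            str(lab),
            fill=(200, 0, 0),
            anchor="mm",
        )
    return np.asarray(img)
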