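"""Immunohistochemistry quantification.

Implements the standard workflow for chromogen quantification on RGB
micrographs: isolate a region of interest ("clear outside"), separate the
stains by colour deconvolution (Ruifrok-Johnston linear unmixing in
optical-density space), encode each stain channel as an 8-bit grayscale
image, threshold the stained structures, and report

* the positively-stained area percentage
      100 * (DAB-positive pixels) / (counterstain-positive pixels), and
* the uncalibrated optical density
      log10(255 / mean pixel value of the thresholded DAB channel).

The per-stain 8-bit encoding is I = round(255 * 10^(-c)), which makes the
optical-density formula the exact inverse of the encoding: a uniform field
of concentration c has mean pixel value 255 * 10^(-c).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu

from .image import CalibratedImage

logger = logging.getLogger(__name__)

#: mean counterstain OD (over the ROI) below which the counterstain is
#: considered absent and the area-percentage ratio is refused
_COUNTERSTAIN_MIN_OD = 0.02



def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("stain vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class StainMatrix:
    """Three unit optical-density stain vectors (columns: stain -> RGB OD).

    If only two stains are physically meaningful the residual third column
    is the normalized cross product of the first two.
    """

    matrix: np.ndarray
    names: tuple[str, str, str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {m.shape}")
        m = np.column_stack([_unit(m[:, k]) for k in range(3)])
        object.__setattr__(self, "matrix", m)
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > 1e8:
            raise ValueError(
                f"stain matrix is singular or near-singular (cond={cond:.3g})"
            )
        logger.debug("stain matrix condition number: %.3g", cond)

    @classmethod
    def from_two_stains(cls, v1, v2, names=("stain1", "stain2", "residual")):
        v1, v2 = _unit(v1), _unit(v2)
        v3 = np.cross(v1, v2)
        if np.linalg.norm(v3) < 1e-12:
            raise ValueError("stain vectors are collinear")
        return cls(np.column_stack([v1, v2, _unit(v3)]), tuple(names))

    @classmethod
    def hdab(cls) -> "StainMatrix":
        """Standard hematoxylin / DAB pair with a computed residual."""
        return cls.from_two_stains(
            (0.650, 0.704, 0.286),
            (0.268, 0.570, 0.776),
            names=("hematoxylin", "dab", "residual"),
        )

    @classmethod
    def identity(cls) -> "StainMatrix":
        return cls(np.eye(3), ("red_od", "green_od", "blue_od"))

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass(frozen=True)
class ThresholdSpec:
    """Dark-pass threshold on an 8-bit channel (positive iff value <= T)."""

    mode: str = "otsu"  # "manual" | "otsu"
    value: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in ("manual", "otsu"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "manual":
            if self.value is None or not (0 <= self.value <= 255):
                raise ValueError("manual threshold requires value in [0, 255]")


@dataclass(frozen=True)
class DeconvolvedImage:
    """Per-stain concentration and 8-bit rasters with their provenance."""

    concentrations: np.ndarray  # HxWx3, OD units, order = stain names
    eight_bit: np.ndarray  # HxWx3 uint8, I = round(255*10^-c)
    stain_names: tuple[str, str, str]
    stain_matrix: np.ndarray
    clipped_fraction: float

    def channel(self, name: str) -> np.ndarray:
        return self.eight_bit[..., self.stain_names.index(name)]

    def concentration(self, name: str) -> np.ndarray:
        return self.concentrations[..., self.stain_names.index(name)]


@dataclass(frozen=True)
class IHCMeasurement:
    """Per-ROI staining quantification record."""

    roi_id: str
    positive_area_px: int
    total_stained_area_px: Optional[int]
    positive_pct: Optional[float]
    mean_pixel_value: float
    od: float
    dab_positive_threshold: int
    dab_all_threshold: int
    counterstain_threshold: Optional[int]
    notes: str = ""


def encode_8bit(concentration: np.ndarray) -> np.ndarray:
    """Encode a concentration raster as I = round(255 * 10^(-c)), uint8."""
    vals = 255.0 * np.power(10.0, -np.asarray(concentration, dtype=float))
    return np.clip(np.round(vals), 0, 255).astype(np.uint8)


def roi_to_mask(
    roi: Union[np.ndarray, "list"], shape: tuple[int, int]
) -> np.ndarray:
    """Normalize an ROI (boolean mask or (x, y) polygon vertices) to a mask."""
    arr = np.asarray(roi)
    if arr.ndim == 2 and arr.shape == shape and arr.dtype == bool:
        mask = arr
    elif arr.ndim == 2 and arr.shape[1] == 2:
        # vertices are (x, y); polygon2mask expects (row, col)
        mask = polygon2mask(shape, arr[:, ::-1])
    else:
        raise ValueError(
            "roi must be a boolean mask matching the image or an Nx2 "
            f"(x, y) vertex list; got shape {arr.shape}, dtype {arr.dtype}"
        )
    if not mask.any():
        raise ValueError("roi is empty (0 pixels)")
    return mask


def clear_outside(image: CalibratedImage, roi) -> CalibratedImage:
    """Set pixels outside the ROI to white, leaving inside pixels untouched."""
    mask = roi_to_mask(roi, image.shape)
    out = np.full_like(image.pixels, 255)
    out[mask] = image.pixels[mask]
    return CalibratedImage(out, image.calibration)


def color_deconvolve(
    image: CalibratedImage, stains: StainMatrix
) -> DeconvolvedImage:
    """Unmix an RGB image into per-stain concentration rasters.

    Per channel OD = -log10(max(I, 1) / 255); concentrations are the
    stain-matrix inverse applied per pixel, with negative values clipped
    to zero (clipped fraction logged).
    """
    px = image.pixels.astype(float)
    od = -np.log10(np.maximum(px, 1.0) / 255.0)
    conc = od @ stains.inverse.T
    clipped = float(np.mean(conc < -1e-9))
    if clipped > 0:
        logger.debug("clipped %.4f of concentration values to 0", clipped)
    conc = np.clip(conc, 0.0, None)
    return DeconvolvedImage(
        concentrations=conc,
        eight_bit=encode_8bit(conc),
        stain_names=stains.names,
        stain_matrix=stains.matrix,
        clipped_fraction=clipped,
    )


def select_threshold(
    channel: np.ndarray,
    spec: ThresholdSpec,
    valid: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, int]:
    """Dark-pass threshold a channel; returns (positive mask, T used).

    Otsu thresholds are computed on the ``valid``-restricted histogram so
    cleared background never influences the cut.
    """
    channel = np.asarray(channel)
    values = channel[valid] if valid is not None else channel.ravel()
    if values.size == 0:
        raise ValueError("no pixels to threshold after roi exclusion")
    if spec.mode == "manual":
        t = int(spec.value)
    else:
        if values.min() == values.max():
            raise ValueError(
                "channel is constant; Otsu is undefined — supply a manual "
                "threshold"
            )
        t = int(threshold_otsu(values))
    positive = channel <= t
    if valid is not None:
        positive = positive & valid
    return positive, t


def positive_area_pct(positive_area_px: int, total_stained_area_px: int) -> float:
    """Positively-stained area as a percentage of the total stained area."""
    if total_stained_area_px <= 0:
        raise ValueError("total stained area must be > 0")
    if positive_area_px < 0 or positive_area_px > total_stained_area_px:
        raise ValueError(
            f"positive area {positive_area_px} outside [0, "
            f"{total_stained_area_px}]"
        )
    return 100.0 * (positive_area_px / total_stained_area_px)


def uncalibrated_od(mean_pixel_value: float) -> float:
    """Uncalibrated optical density log10(255 / mean pixel value), A.U."""
    if not 0 < mean_pixel_value <= 255:
        raise ValueError(
            f"mean pixel value must be in (0, 255], got {mean_pixel_value}"
        )
    return float(np.log10(255.0 / mean_pixel_value))


def measure_ihc(
    image: CalibratedImage,
    roi,
    stains: StainMatrix,
    dab_positive: ThresholdSpec = ThresholdSpec("otsu"),
    dab_all: Optional[ThresholdSpec] = None,
    counterstain: ThresholdSpec = ThresholdSpec("otsu"),
    roi_id: str = "roi",
    dab_stain: str = "dab",
    counter_stain: str = "hematoxylin",
) -> IHCMeasurement:
    """Full per-ROI IHC quantification.

    Runs clear-outside -> deconvolution -> thresholding (positive DAB,
    all DAB, counterstain) -> area percentage (when a counterstain is
    present) and uncalibrated optical density.
    """
    mask = roi_to_mask(roi, image.shape)
    cleared = clear_outside(image, mask)
    dec = color_deconvolve(cleared, stains)
    if dab_all is None:
        dab_all = dab_positive

    dab_chan = dec.channel(dab_stain)
    pos_mask, t_pos = select_threshold(dab_chan, dab_positive, valid=mask)
    all_mask, t_all = select_threshold(dab_chan, dab_all, valid=mask)
    positive_area = int(pos_mask.sum())

    if all_mask.any():
        mean_val = float(dab_chan[all_mask].mean())
    else:
        mean_val = 255.0
        logger.warning("%s: no DAB pixels passed the threshold", roi_id)
    od = uncalibrated_od(mean_val) if mean_val > 0 else float("inf")

    notes = ""
    counter_chan = dec.concentration(counter_stain)
    counter_mean_od = float(counter_chan[mask].mean())
    if counter_mean_od < _COUNTERSTAIN_MIN_OD:
        total_area = None
        pct = None
        t_counter = None
        notes = (
            "counterstain absent: positively-stained area percentage is "
            "undefined without a counterstain denominator"
        )
        logger.info("%s: %s", roi_id, notes)
    else:
        cmask, t_counter = select_threshold(
            dec.channel(counter_stain), counterstain, valid=mask
        )
        total_area = int(cmask.sum())
        pct = positive_area_pct(positive_area, total_area)

    return IHCMeasurement(
        roi_id=roi_id,
        positive_area_px=positive_area,
        total_stained_area_px=total_area,
        positive_pct=pct,
        mean_pixel_value=mean_val,
        od=od,
        dab_positive_threshold=t_pos,
        dab_all_threshold=t_all,
        counterstain_threshold=t_counter,
        notes=notes,
    )
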