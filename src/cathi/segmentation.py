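"""Automated segmentation of phantom-grade H&E images.

Replaces the manual selection steps of the slide-viewer workflow:
delineate the tissue section, label individual tubules and their lumina,
classify each tubule's section plane (cross vs. longitudinal) and detect
the elongated-spermatid marker in the peri-luminal band.

Every operator here is an intensity/shape heuristic whose parameters are
explicit in :class:`SegmentationParams`.  They are validated against the
phantom generator, whose contrast and packing conventions they assume;
robustness on real slides is not claimed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, measure, morphology, segmentation as sks

from .image import CalibratedImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the segmentation operators.

    Luminance thresholds are on rec.709 luma in [0, 1]: background is
    near 1.0, pale interstitium/lumen above ``ring_luminance``, the
    epithelium ring below it and the spermatid speckles below
    ``speckle_luminance``.
    """

    background_luminance: float = 0.985
    ring_luminance: float = 0.75
    speckle_luminance: float = 0.30
    min_tubule_area_um2: float = 500.0
    aspect_cutoff: float = 1.8
    min_speckles: int = 3
    speckle_min_length_px: float = 3.0
    speckle_min_eccentricity: float = 0.9
    periluminal_band_fraction: float = 0.10
    lumen_min_luminance: float = 0.85


@dataclass(frozen=True)
class SegmentationResult:
    """Labelled masks plus per-tubule classifications."""

    section: np.ndarray  # bool
    tubules: np.ndarray  # integer labels, 0 background
    lumina: np.ndarray  # integer labels matched to tubules, 0 = none
    plane_class: dict[int, str]  # label -> "cross" | "longitudinal"
    spermatid_positive: dict[int, bool]
    params: SegmentationParams

    @property
    def labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.tubules) if v != 0)


def _luminance(image: CalibratedImage) -> np.ndarray:
    return color.rgb2gray(image.pixels)


def segment_section(
    image: CalibratedImage, params: SegmentationParams = SegmentationParams()
) -> np.ndarray:
    """Largest connected tissue component after background thresholding.

    Tissue is anything darker than the (near-white) background; holes are
    filled so lumina and pale interstitium belong to the section.
    """
    gray = _luminance(image)
    tissue = gray < params.background_luminance
    if not tissue.any():
        raise ValueError("no tissue found: image is uniformly background")
    labels, n = ndimage.label(tissue)
    if n > 1:
        logger.info("found %d tissue candidates; keeping the largest", n)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    section = ndimage.binary_fill_holes(labels == keep)
    return section


def _split_by_lumina(
    filled: np.ndarray, lumen_candidates: np.ndarray
) -> np.ndarray:
    """Watershed-split a merged component using its lumina as markers."""
    markers, n = ndimage.label(lumen_candidates)
    if n <= 1:
        out = np.zeros(filled.shape, dtype=np.int32)
        out[filled] = 1
        return out
    dist = ndimage.distance_transform_edt(filled)
    return sks.watershed(-dist, markers=markers, mask=filled)


def segment_tubules(
    image: CalibratedImage,
    section: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Label individual tubules and their lumina inside the section.

    Detects the dark epithelium rings, fills each ring to a solid tubule,
    splits merged components by a distance-transform watershed seeded at
    their lumina, and applies a minimum-size filter.  The lumen of a
    tubule is the pale interior region; lumenless tubules get no lumen
    label and are logged.
    """
    gray = _luminance(image)
    dark = (gray < params.ring_luminance) & section
    ring_labels, n_rings = ndimage.label(dark)
    um2 = image.calibration.um2_per_px2
    min_px = params.min_tubule_area_um2 / um2

    tubules = np.zeros(section.shape, dtype=np.int32)
    lumina = np.zeros(section.shape, dtype=np.int32)
    next_label = 1
    for ring in range(1, n_rings + 1):
        comp = ring_labels == ring
        filled = ndimage.binary_fill_holes(comp)
        interior_pale = filled & ~comp & (gray > params.lumen_min_luminance)
        # speckles punch holes in the lumen; close them
        interior_pale = ndimage.binary_fill_holes(interior_pale)
        parts = _split_by_lumina(filled, interior_pale)
        for p in range(1, parts.max() + 1):
            part = parts == p
            if part.sum() < min_px:
                logger.debug(
                    "dropping component below min size (%d px < %.0f px)",
                    part.sum(),
                    min_px,
                )
                continue
            tubules[part] = next_label
            lum = part & interior_pale
            if lum.any():
                lumina[lum] = next_label
            else:
                logger.info("tubule %d has no detectable lumen", next_label)
            next_label += 1
    return tubules, lumina


def classify_plane(
    tubule_mask: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> str:
    """Classify a single tubule mask as cross or longitudinal section.

    Longitudinal iff the best-fit-ellipse axis ratio exceeds the aspect
    cutoff (default 1.8, between the phantom's cross (<= 1.3) and
    longitudinal (>= 2.5) shape families).
    """
    props = measure.regionprops(tubule_mask.astype(np.uint8))
    if not props or props[0].axis_minor_length == 0:
        raise ValueError("degenerate tubule mask")
    ratio = props[0].axis_major_length / props[0].axis_minor_length
    return "longitudinal" if ratio > params.aspect_cutoff else "cross"


def _crop_to_mask(mask: np.ndarray, pad: int = 4):
    """Bounding-box slices of a mask's foreground, padded."""
    sl = ndimage.find_objects(mask.astype(np.uint8))[0]
    return tuple(
        slice(max(s.start - pad, 0), min(s.stop + pad, n))
        for s, n in zip(sl, mask.shape)
    )


def detect_spermatid_positive(
    image: CalibratedImage,
    tubule_mask: np.ndarray,
    lumen_mask: np.ndarray | None,
    params: SegmentationParams = SegmentationParams(),
    gray: np.ndarray | None = None,
) -> bool:
    """Detect the elongated-spermatid marker in the peri-luminal band.

    Positive iff at least ``min_speckles`` dark elongated blobs
    (eccentricity and length bounds) lie in the lumen dilated by 10% of
    the tubule's equivalent radius.  With no lumen the whole tubule
    interior is searched and a warning logged.
    """
    if gray is None:
        gray = _luminance(image)
    r_eq = float(np.sqrt(tubule_mask.sum() / np.pi))
    radius = max(int(round(params.periluminal_band_fraction * r_eq)), 1)
    box = _crop_to_mask(tubule_mask, pad=radius + 2)
    tub = tubule_mask[box]
    if lumen_mask is not None and lumen_mask.any():
        band = (
            morphology.dilation(lumen_mask[box], morphology.disk(radius))
            & tub
        )
    else:
        logger.warning("no lumen: searching the whole tubule interior")
        band = tub
    dark = (gray[box] < params.speckle_luminance) & band
    blobs = measure.label(dark)
    count = 0
    for prop in measure.regionprops(blobs):
        if (
            prop.eccentricity >= params.speckle_min_eccentricity
            and prop.axis_major_length >= params.speckle_min_length_px
        ):
            count += 1
    return count >= params.min_speckles


def segment_image(
    image: CalibratedImage,
    params: SegmentationParams = SegmentationParams(),
) -> SegmentationResult:
    """Run the full segmentation chain on one H&E image."""
    section = segment_section(image, params)
    tubules, lumina = segment_tubules(image, section, params)
    gray = _luminance(image)
    plane: dict[int, str] = {}
    positive: dict[int, bool] = {}
    for lab in (int(v) for v in np.unique(tubules) if v != 0):
        tm = tubules == lab
        lm = lumina == lab
        plane[lab] = classify_plane(tm, params)
        positive[lab] = detect_spermatid_positive(
            image, tm, lm if lm.any() else None, params, gray=gray
        )
    return SegmentationResult(
        section=section,
        tubules=tubules,
        lumina=lumina,
        plane_class=plane,
        spermatid_positive=positive,
        params=params,
    )
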