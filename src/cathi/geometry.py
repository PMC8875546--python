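"""Calibrated geometric measurements on binary region masks.

All measurements operate on rasterized regions (boolean masks) with an
isotropic spatial calibration in micrometres per pixel, mirroring the
measurements a histologist takes in a slide viewer: area, perimeter, the
two longest perpendicular diameters, and the thickness of the
spermatogenic epithelium sampled along random rays.

Coordinate convention: 0-based, row-major (row = y, column = x), pixel
centers at integer coordinates, pixel-set semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure

logger = logging.getLogger(__name__)

#: minimum foreground pixels below which shape metrics are meaningless
_MIN_PIXELS = 4

#: Gaussian pre-smoothing (px) applied before extracting the 0.5
#: iso-contour; removes the staircase bias of a raw binary contour
#: (~5% overestimate on disks) while moving the level set of a smooth
#: convex shape by only ~sigma^2/(2R).
_CONTOUR_SIGMA = 1.0


@dataclass(frozen=True)
class Calibration:
    """Isotropic spatial calibration of a raster image."""

    um_per_px: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.um_per_px) or self.um_per_px <= 0:
            raise ValueError(
                f"um_per_px must be finite and > 0, got {self.um_per_px}"
            )

    @property
    def um2_per_px2(self) -> float:
        return self.um_per_px**2


@dataclass(frozen=True)
class RegionMask:
    """A binary region together with its calibration."""

    mask: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2-D, got ndim={m.ndim}")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    def require_nonempty(self) -> None:
        if self.pixel_count == 0:
            raise ValueError("mask is empty: no foreground pixels")

    def require_single_component(self) -> None:
        self.require_nonempty()
        _, n = ndimage.label(self.mask)
        if n != 1:
            raise ValueError(
                f"mask must be a single connected component, found {n}"
            )


@dataclass(frozen=True)
class ShapeMetrics:
    """Area, perimeter and perpendicular-diameter summary of one region.

    ``diameter_1`` is the maximum Feret (caliper) diameter, ``diameter_2``
    the maximum caliper extent perpendicular to it; ``diameter_avg`` is
    their arithmetic mean.
    """

    area_um2: float
    perimeter_um: float
    diameter_1_um: float
    diameter_2_um: float
    diameter_avg_um: float


@dataclass(frozen=True)
class ThicknessSample:
    """Five radially sampled epithelium lengths and their mean (um)."""

    lengths_um: tuple[float, float, float, float, float]
    mean_um: float
    rng_seed: int
    angles_rad: tuple[float, ...] = field(default=())


def region_area(region: RegionMask) -> float:
    """Area of the region in square micrometres (pixel count x calibration)."""
    region.require_nonempty()
    return region.pixel_count * region.calibration.um2_per_px2


def _outer_contour(mask: np.ndarray) -> np.ndarray:
    """Longest 0.5 iso-contour of the smoothed mask, in (row, col) coords."""
    smoothed = ndimage.gaussian_filter(
        mask.astype(float), sigma=_CONTOUR_SIGMA, mode="constant"
    )
    contours = measure.find_contours(smoothed, 0.5)
    if not contours:
        raise ValueError("no 0.5 iso-contour found (mask too small?)")

    def _length(c: np.ndarray) -> float:
        return float(np.sqrt(((np.diff(c, axis=0)) ** 2).sum(axis=1)).sum())

    return max(contours, key=_length)


def region_perimeter(region: RegionMask) -> float:
    """Perimeter in micrometres.

    Length of the sub-pixel 0.5 iso-contour polygon of the (smoothed)
    mask; for regions with holes only the outer contour counts.
    """
    region.require_single_component()
    if region.pixel_count < _MIN_PIXELS:
        raise ValueError(
            f"degenerate mask ({region.pixel_count} px < {_MIN_PIXELS})"
        )
    contour = _outer_contour(region.mask)
    seg = np.diff(contour, axis=0)
    length_px = float(np.sqrt((seg**2).sum(axis=1)).sum())
    return length_px * region.calibration.um_per_px


def _hull_points(mask: np.ndarray) -> np.ndarray:
    """Convex hull vertices of the foreground pixel centers as (x, y)."""
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols, rows]).astype(float)
    if len(pts) < 3:
        return pts
    try:
        hull = ConvexHull(pts)
    except Exception:  # collinear point sets
        return pts
    return pts[hull.vertices]


def perpendicular_diameters(region: RegionMask) -> tuple[float, float]:
    """The two longest perpendicular caliper diameters, in micrometres.

    ``d1`` is the maximum Feret diameter over the convex hull of pixel
    centers; ``d2`` is the caliper width measured perpendicular to d1's
    direction.  Ties in d1 direction are broken toward the smallest angle
    in [0, pi).
    """
    region.require_single_component()
    if region.pixel_count < _MIN_PIXELS:
        raise ValueError(
            f"degenerate mask ({region.pixel_count} px < {_MIN_PIXELS})"
        )
    pts = _hull_points(region.mask)
    # max pairwise distance over hull vertices
    diff = pts[:, None, :] - pts[None, :, :]
    d2mat = (diff**2).sum(axis=-1)
    best = np.max(d2mat)
    ii, jj = np.nonzero(np.isclose(d2mat, best))
    # tie-break: smallest direction angle in [0, pi)
    cand = []
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        v = pts[j] - pts[i]
        ang = np.arctan2(v[1], v[0]) % np.pi
        cand.append((ang, i, j))
    ang, i, j = min(cand)
    d1_px = float(np.sqrt(d2mat[i, j]))
    direction = (pts[j] - pts[i]) / d1_px
    perp = np.array([-direction[1], direction[0]])
    proj = pts @ perp
    d2_px = float(proj.max() - proj.min())
    um = region.calibration.um_per_px
    return d1_px * um, d2_px * um


def average_diameter(d1_um: float, d2_um: float) -> float:
    """Arithmetic mean of two perpendicular diameters."""
    if d1_um <= 0 or d2_um <= 0:
        raise ValueError(f"diameters must be > 0, got ({d1_um}, {d2_um})")
    return (d1_um + d2_um) / 2.0


def shape_metrics(region: RegionMask) -> ShapeMetrics:
    """Full area/perimeter/diameter summary of a single-component region."""
    d1, d2 = perpendicular_diameters(region)
    return ShapeMetrics(
        area_um2=region_area(region),
        perimeter_um=region_perimeter(region),
        diameter_1_um=d1,
        diameter_2_um=d2,
        diameter_avg_um=average_diameter(d1, d2),
    )


def _ray_crossing(
    mask: np.ndarray,
    origin: np.ndarray,
    direction: np.ndarray,
    t_start: float,
    t_max: float,
    step: float = 0.1,
) -> float | None:
    """First t in [t_start, t_max] where the ray leaves ``mask``.

    Nearest-neighbour sampling; returns the midpoint of the last-inside /
    first-outside bracket (sub-pixel to ~step/2).
    """
    t = t_start
    prev_inside = None
    nrow, ncol = mask.shape
    while t <= t_max:
        x = origin[0] + t * direction[0]
        y = origin[1] + t * direction[1]
        r, c = int(round(y)), int(round(x))
        inside = 0 <= r < nrow and 0 <= c < ncol and mask[r, c]
        if prev_inside and not inside:
            return t - step / 2.0
        prev_inside = inside
        t += step
    return None


def epithelium_thickness(
    tubule: RegionMask,
    lumen: RegionMask,
    seed: int,
    n_rays: int = 5,
    max_retries: int = 50,
) -> ThicknessSample:
    """Sample the spermatogenic-epithelium thickness along random rays.

    Casts ``n_rays`` rays from the lumen centroid at seeded uniform-random
    angles; each length is the distance between the lumen-boundary
    crossing and the tubule-outer-boundary crossing along the ray.  The
    reported thickness is the arithmetic mean of the five lengths.
    """
    tubule.require_single_component()
    lumen.require_single_component()
    if np.any(lumen.mask & ~tubule.mask):
        raise ValueError("lumen mask is not contained in the tubule mask")
    if tubule.calibration != lumen.calibration:
        raise ValueError("tubule and lumen calibrations differ")

    rows, cols = np.nonzero(lumen.mask)
    origin = np.array([cols.mean(), rows.mean()])
    t_max = float(np.hypot(*tubule.mask.shape)) + 2.0
    rng = np.random.default_rng(seed)

    lengths: list[float] = []
    angles: list[float] = []
    attempts = 0
    while len(lengths) < n_rays:
        if attempts >= n_rays + max_retries:
            raise RuntimeError(
                f"could not find {n_rays} valid rays after {attempts} attempts"
            )
        attempts += 1
        theta = float(rng.uniform(0.0, 2.0 * np.pi))
        direction = np.array([np.cos(theta), np.sin(theta)])
        t_lumen = _ray_crossing(lumen.mask, origin, direction, 0.0, t_max)
        if t_lumen is None:
            logger.warning("ray at %.3f rad never left the lumen; resampling", theta)
            continue
        t_outer = _ray_crossing(tubule.mask, origin, direction, t_lumen, t_max)
        if t_outer is None or t_outer <= t_lumen:
            logger.warning("ray at %.3f rad never left the tubule; resampling", theta)
            continue
        lengths.append((t_outer - t_lumen) * tubule.calibration.um_per_px)
        angles.append(theta)

    mean = float(np.mean(lengths))
    return ThicknessSample(
        lengths_um=tuple(lengths),
        mean_um=mean,
        rng_seed=seed,
        angles_rad=tuple(angles),
    )
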