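"""Derived histomorphometric quantities and the section-level report.

Per-tubule records hold the geometric measurements of one seminiferous
tubule (area, perimeter, perpendicular diameters of tubule and lumen,
spermatogenic-epithelium area, ratio and thickness).  The section report
aggregates the whole cross-section: total tissue geometry, tubule count,
the histomorphometric Bergmann-Kliesch percentage (share of tubules
containing elongated spermatids), interstitial area, tubule area ratio
and tubule number density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import (
    Calibration,
    RegionMask,
    ShapeMetrics,
    ThicknessSample,
    average_diameter,
    epithelium_thickness,
    region_area,
    region_perimeter,
    perpendicular_diameters,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TubuleMeasurement:
    """Geometric record of a single seminiferous tubule (all lengths um)."""

    tubule_id: int
    tubule_area_um2: float
    tubule_perimeter_um: float
    lumen_area_um2: Optional[float]
    lumen_perimeter_um: Optional[float]
    tubule_d1_um: float
    tubule_d2_um: float
    tubule_davg_um: float
    lumen_d1_um: Optional[float]
    lumen_d2_um: Optional[float]
    lumen_davg_um: Optional[float]
    se_area_um2: float
    se_area_ratio_pct: float
    se_thickness: Optional[ThicknessSample]
    is_longitudinal: bool
    is_spermatid_positive: bool


@dataclass(frozen=True)
class SectionReport:
    """Section-level aggregate of the whole testis cross-section."""

    total_testis_area_um2: float
    total_testis_perimeter_um: float
    total_testis_d1_um: float
    total_testis_d2_um: float
    total_testis_davg_um: float
    total_tubule_count: int
    spermatid_positive_count: int
    bergmann_kliesch_pct: float
    sum_all_tubule_areas_um2: float
    interstitial_area_um2: float
    tubule_area_ratio_pct: float
    tubule_number_density_per_um2: float
    sampled_tubule_ids: tuple[int, ...]


def count_tubules(tubule_labels: np.ndarray) -> int:
    """Number of distinct tubule labels (background 0 excluded)."""
    labels = np.unique(np.asarray(tubule_labels))
    return int((labels != 0).sum())


def bergmann_kliesch(positive: int, total: int) -> float:
    """Histomorphometric Bergmann-Kliesch score: 100 * positive / total."""
    if total <= 0:
        raise ValueError("total tubule count must be > 0")
    if not 0 <= positive <= total:
        raise ValueError(f"positive count {positive} outside [0, {total}]")
    return 100.0 * (positive / total)


def se_area(tubule_area_um2: float, lumen_area_um2: float) -> float:
    """Spermatogenic epithelium area: tubule area minus lumen area."""
    if lumen_area_um2 > tubule_area_um2:
        raise ValueError(
            f"lumen area {lumen_area_um2} exceeds tubule area "
            f"{tubule_area_um2}: mis-paired measurements"
        )
    return tubule_area_um2 - lumen_area_um2


def se_area_ratio(se_area_um2: float, tubule_area_um2: float) -> float:
    """Epithelium share of the tubule area, percent."""
    if tubule_area_um2 <= 0:
        raise ValueError("tubule area must be > 0")
    return 100.0 * (se_area_um2 / tubule_area_um2)


def interstitial_area(
    total_testis_area_um2: float, sum_all_tubule_areas_um2: float
) -> float:
    """Interstitial and other tissue area: total minus all tubule areas."""
    if sum_all_tubule_areas_um2 > total_testis_area_um2:
        raise ValueError(
            "summed tubule areas exceed the total testis area: "
            "inconsistent masks"
        )
    return total_testis_area_um2 - sum_all_tubule_areas_um2


def tubule_area_ratio(
    sum_all_tubule_areas_um2: float, total_testis_area_um2: float
) -> float:
    """Percentage of the testis cross-section occupied by tubules."""
    if total_testis_area_um2 <= 0:
        raise ValueError("total testis area must be > 0")
    return 100.0 * (sum_all_tubule_areas_um2 / total_testis_area_um2)


def tubule_number_density(
    total_tubule_count: int, total_testis_area_um2: float
) -> float:
    """Tubule count normalized by section area (pieces per square um)."""
    if total_testis_area_um2 <= 0:
        raise ValueError("total testis area must be > 0")
    return total_tubule_count / total_testis_area_um2


def sample_tubules(
    records: Sequence[TubuleMeasurement] | Sequence[dict],
    n_target: int,
    seed: int,
) -> list[int]:
    """Seeded uniform sample (without replacement) of cross-sectioned tubules.

    Longitudinally sectioned tubules are never sampled.  When fewer
    cross-sections exist than requested, all of them are returned and a
    warning is logged.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")

    def _get(r, key):
        return r[key] if isinstance(r, dict) else getattr(r, key)

    cross_ids = [
        _get(r, "tubule_id")
        for r in records
        if not _get(r, "is_longitudinal")
    ]
    if not cross_ids:
        raise ValueError("no cross-sectioned tubules available for sampling")
    rng = np.random.default_rng(seed)
    if len(cross_ids) <= n_target:
        if len(cross_ids) < n_target:
            logger.warning(
                "only %d cross-sectioned tubules available (requested %d); "
                "taking all",
                len(cross_ids),
                n_target,
            )
        return sorted(cross_ids)
    chosen = rng.choice(cross_ids, size=n_target, replace=False)
    return sorted(int(i) for i in chosen)


def measure_tubule(
    tubule_id: int,
    tubule_mask: np.ndarray,
    lumen_mask: Optional[np.ndarray],
    calibration: Calibration,
    *,
    is_longitudinal: bool = False,
    is_spermatid_positive: bool = False,
    thickness_seed: int = 0,
) -> TubuleMeasurement:
    """Measure one tubule (and its lumen, when present) from binary masks."""
    tub = RegionMask(tubule_mask, calibration)
    t_area = region_area(tub)
    t_perim = region_perimeter(tub)
    t_d1, t_d2 = perpendicular_diameters(tub)

    if lumen_mask is not None and lumen_mask.any():
        lum = RegionMask(lumen_mask, calibration)
        l_area = region_area(lum)
        l_perim = region_perimeter(lum)
        l_d1, l_d2 = perpendicular_diameters(lum)
        l_davg = average_diameter(l_d1, l_d2)
        thickness = epithelium_thickness(tub, lum, seed=thickness_seed)
        epi = se_area(t_area, l_area)
    else:
        l_area = l_perim = l_d1 = l_d2 = l_davg = None
        thickness = None
        epi = t_area

    return TubuleMeasurement(
        tubule_id=tubule_id,
        tubule_area_um2=t_area,
        tubule_perimeter_um=t_perim,
        lumen_area_um2=l_area,
        lumen_perimeter_um=l_perim,
        tubule_d1_um=t_d1,
        tubule_d2_um=t_d2,
        tubule_davg_um=average_diameter(t_d1, t_d2),
        lumen_d1_um=l_d1,
        lumen_d2_um=l_d2,
        lumen_davg_um=l_davg,
        se_area_um2=epi,
        se_area_ratio_pct=se_area_ratio(epi, t_area),
        se_thickness=thickness,
        is_longitudinal=is_longitudinal,
        is_spermatid_positive=is_spermatid_positive,
    )


def build_section_report(
    section_metrics: ShapeMetrics,
    records: Sequence[TubuleMeasurement],
    sampled_ids: Sequence[int] = (),
) -> SectionReport:
    """Assemble the section-level aggregate from component measurements."""
    total = len(records)
    positive = sum(r.is_spermatid_positive for r in records)
    sum_areas = float(sum(r.tubule_area_um2 for r in records))
    inter = interstitial_area(section_metrics.area_um2, sum_areas)
    return SectionReport(
        total_testis_area_um2=section_metrics.area_um2,
        total_testis_perimeter_um=section_metrics.perimeter_um,
        total_testis_d1_um=section_metrics.diameter_1_um,
        total_testis_d2_um=section_metrics.diameter_2_um,
        total_testis_davg_um=section_metrics.diameter_avg_um,
        total_tubule_count=total,
        spermatid_positive_count=positive,
        bergmann_kliesch_pct=bergmann_kliesch(positive, total)
        if total
        else 0.0,
        sum_all_tubule_areas_um2=sum_areas,
        interstitial_area_um2=inter,
        tubule_area_ratio_pct=tubule_area_ratio(
            sum_areas, section_metrics.area_um2
        ),
        tubule_number_density_per_um2=tubule_number_density(
            total, section_metrics.area_um2
        ),
        sampled_tubule_ids=tuple(sampled_ids),
    )
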