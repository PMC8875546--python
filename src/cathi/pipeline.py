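"""End-to-end pipeline: phantom -> segmentation -> morphometry -> IHC.

A run is fully described by a :class:`RunConfig`; every random choice is
seeded from it, the effective configuration is written next to the
outputs, and repeated runs produce byte-identical CSV files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as cio
from .geometry import Calibration, RegionMask, shape_metrics
from .image import CalibratedImage
from .ihc import StainMatrix, ThresholdSpec, measure_ihc
from .morphometry import (
    TubuleMeasurement,
    build_section_report,
    measure_tubule,
    sample_tubules,
)
from .phantom import PhantomSpec, generate_scene, render_he, render_ihc
from .segmentation import SegmentationParams, segment_image

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    out_dir: str
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    segmentation: SegmentationParams = field(
        default_factory=SegmentationParams
    )
    n_sample: int = 100
    seed: int = 0
    dab_threshold: Optional[int] = None  # None = Otsu
    # the counterstain cut selects "the entire stained area", so the
    # default is a loose manual threshold; Otsu is undefined on the
    # phantom's uniform counterstain
    counterstain_threshold: Optional[int] = 240
    ihc_dab_coverage: Optional[float] = None

    def threshold_spec(self, value: Optional[int]) -> ThresholdSpec:
        if value is None:
            return ThresholdSpec("otsu")
        return ThresholdSpec("manual", value)


def measure_from_segmentation(
    seg, calibration: Calibration, seed: int
) -> list[TubuleMeasurement]:
    """Per-tubule measurements from a segmentation result.

    Each tubule's thickness rays get a sub-seed derived from the run seed
    and the tubule label, so records are independent of processing order.
    """
    records = []
    for lab in seg.labels:
        tm = seg.tubules == lab
        lm = seg.lumina == lab
        records.append(
            measure_tubule(
                lab,
                tm,
                lm if lm.any() else None,
                calibration,
                is_longitudinal=seg.plane_class[lab] == "longitudinal",
                is_spermatid_positive=seg.spermatid_positive[lab],
                thickness_seed=(seed * 100003 + lab) % (2**31),
            )
        )
    return records


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full phantom -> segment -> measure -> IHC pipeline.

    Returns a mapping from artifact name to written path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    spec = dataclasses.replace(config.phantom, seed=config.seed)
    scene = generate_scene(spec)
    he_image, masks = render_he(scene)
    ihc_image, ihc_fields = render_ihc(
        scene, dab_coverage=config.ihc_dab_coverage
    )

    written["he_image"] = out / "he.png"
    cio.write_image(written["he_image"], he_image)
    written["ihc_image"] = out / "ihc.png"
    cio.write_image(written["ihc_image"], ihc_image)
    for name in ("tubules", "lumina"):
        written[f"truth_{name}"] = out / f"truth_{name}.tif"
        cio.write_labels(written[f"truth_{name}"], masks[name])
    written["truth_section"] = out / "truth_section.tif"
    cio.write_labels(written["truth_section"], masks["section"].astype(np.uint16))

    from .phantom import scene_to_dataframe

    written["scene_csv"] = out / "scene.csv"
    cio.write_csv(written["scene_csv"], scene_to_dataframe(scene))

    seg = segment_image(he_image, config.segmentation)
    written["seg_tubules"] = out / "seg_tubules.tif"
    cio.write_labels(written["seg_tubules"], seg.tubules)
    written["seg_lumina"] = out / "seg_lumina.tif"
    cio.write_labels(written["seg_lumina"], seg.lumina)
    written["overlay"] = out / "overlay.png"
    overlay = cio.numbered_overlay(he_image, seg.tubules)
    cio.write_image(
        written["overlay"], CalibratedImage(overlay, he_image.calibration)
    )

    cal = he_image.calibration
    section_m = shape_metrics(RegionMask(seg.section, cal))
    records = measure_from_segmentation(seg, cal, config.seed)
    sampled = sample_tubules(records, config.n_sample, config.seed)
    report = build_section_report(section_m, records, sampled)

    written["tubules_csv"] = out / "tubules.csv"
    cio.write_csv(
        written["tubules_csv"], cio.tubules_to_dataframe(records, sampled)
    )
    written["section_csv"] = out / "section.csv"
    cio.write_csv(
        written["section_csv"], cio.section_report_to_dataframe(report)
    )

    roi = ihc_fields["tissue"]
    ihc_m = measure_ihc(
        ihc_image,
        roi,
        StainMatrix.hdab(),
        dab_positive=config.threshold_spec(config.dab_threshold),
        counterstain=config.threshold_spec(config.counterstain_threshold),
        roi_id="phantom_field",
    )
    written["ihc_csv"] = out / "ihc.csv"
    cio.write_csv(written["ihc_csv"], cio.ihc_to_dataframe([ihc_m]))

    written["config"] = out / "run_config.yml"
    cio.write_yaml(written["config"], config)
    return written
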