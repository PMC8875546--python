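"""Calibrated RGB image container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Calibration


@dataclass(frozen=True)
class CalibratedImage:
    """An 8-bit RGB raster with an isotropic um-per-pixel calibration."""

    pixels: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3 RGB, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]
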