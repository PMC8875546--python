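import numpy as np
import pytest

from cathi import (
    Calibration,
    PhantomSpec,
    RegionMask,
    generate_scene,
    render_he,
    segment_image,
)


def disk_mask(radius_px: int, pad: int = 5, shape=None) -> np.ndarray:
    """Rasterized disk: pixel centers within radius of the center."""
    n = 2 * (radius_px + pad) + 1
    if shape is None:
        shape = (n, n)
    c = (shape[0] // 2, shape[1] // 2)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (xx - c[1]) ** 2 + (yy - c[0]) ** 2 <= radius_px**2


def ellipse_mask(a_px: float, b_px: float, angle_rad: float = 0.0, pad: int = 5):
    n = 2 * (int(np.ceil(max(a_px, b_px))) + pad) + 1
    c = n // 2
    yy, xx = np.mgrid[:n, :n]
    x, y = xx - c, yy - c
    ct, st = np.cos(angle_rad), np.sin(angle_rad)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def region(mask, um_per_px=1.0) -> RegionMask:
    return RegionMask(mask, Calibration(um_per_px))


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=0)


@pytest.fixture(scope="session")
def default_scene(default_spec):
    return generate_scene(default_spec)


@pytest.fixture(scope="session")
def default_render(default_scene):
    return render_he(default_scene)


@pytest.fixture(scope="session")
def default_segmentation(default_render):
    image, _ = default_render
    return segment_image(image)


@pytest.fixture(scope="session")
def matched_labels(default_scene, default_segmentation):
    """Map ground-truth tubule label -> segmentation label (via centers)."""
    seg = default_segmentation
    mapping = {}
    for rec in default_scene.records:
        cx, cy = rec.center_xy
        lab = int(seg.tubules[int(round(cy)), int(round(cx))])
        mapping[rec.label] = lab
    return mapping
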