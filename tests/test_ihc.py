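"""Stain deconvolution and IHC quantification."""

import numpy as np
import pytest

from cathi import (
    CalibratedImage,
    Calibration,
    PhantomSpec,
    StainMatrix,
    ThresholdSpec,
    clear_outside,
    color_deconvolve,
    generate_scene,
    measure_ihc,
    positive_area_pct,
    render_ihc,
    select_threshold,
    uncalibrated_od,
)
from cathi.ihc import encode_8bit


def _img(pixels, um=1.0):
    return CalibratedImage(np.asarray(pixels, dtype=np.uint8), Calibration(um))


def synth_pixel(stains: StainMatrix, conc) -> np.ndarray:
    """Beer-Lambert forward model for a single pixel."""
    od = stains.matrix @ np.asarray(conc, float)
    return np.clip(np.round(255.0 * 10.0**-od), 0, 255).astype(np.uint8)


class TestDeconvolution:
    def test_white_pixel_zero_concentration(self):
        img = _img(np.full((4, 4, 3), 255))
        dec = color_deconvolve(img, StainMatrix.hdab())
        assert np.all(dec.concentrations == 0.0)
        assert np.all(dec.eight_bit == 255)

    def test_single_stain_round_trip(self):
        stains = StainMatrix.hdab()
        px = synth_pixel(stains, (0.0, 0.5, 0.0))
        img = _img(np.tile(px, (3, 3, 1)))
        dec = color_deconvolve(img, stains)
        assert dec.concentration("dab")[0, 0] == pytest.approx(0.5, abs=0.01)
        assert dec.concentration("hematoxylin")[0, 0] == pytest.approx(
            0.0, abs=0.01
        )

    @pytest.mark.parametrize(
        "c_hema,c_dab",
        [
            (0.0, 0.0),
            (0.0, 0.3),
            (0.0, 2.0),
            (0.4, 0.3),
            (0.4, 0.9),
            (1.0, 0.9),
            (2.0, 0.0),
            (1.0, 1.0),
        ],
    )
    def test_round_trip_grid(self, c_hema, c_dab):
        """Synthesize -> deconvolve within the 8-bit quantization bound.

        Each stain is planted up to OD 2; the combined optical density
        stays within the range an 8-bit channel can represent.
        """
        stains = StainMatrix.hdab()
        px = synth_pixel(stains, (c_hema, c_dab, 0.0))
        dec = color_deconvolve(_img(px.reshape(1, 1, 3)), stains)
        assert dec.concentration("hematoxylin")[0, 0] == pytest.approx(
            c_hema, abs=0.02
        )
        assert dec.concentration("dab")[0, 0] == pytest.approx(c_dab, abs=0.02)

    def test_identity_stains_give_channel_od(self):
        img = _img([[[128, 64, 255]]])
        dec = color_deconvolve(img, StainMatrix.identity())
        expected = -np.log10(np.array([128, 64, 255]) / 255.0)
        assert dec.concentrations[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_phantom_field_round_trip(self, default_scene):
        img, fields = render_ihc(default_scene)
        dec = color_deconvolve(img, StainMatrix.hdab())
        assert np.abs(
            dec.concentration("dab") - fields["dab"]
        ).max() <= 0.02
        assert np.abs(
            dec.concentration("hematoxylin") - fields["hematoxylin"]
        ).max() <= 0.02

    def test_eight_bit_encoding_consistency(self):
        c = np.array([[0.0, 0.5, 1.0, 3.0]])
        enc = encode_8bit(c)
        assert enc[0, 0] == 255
        assert enc[0, 1] == round(255 * 10**-0.5)
        # monotone decreasing in concentration
        assert np.all(np.diff(enc[0].astype(int)) < 0)


class TestThreshold:
    def test_manual_all_pass(self):
        chan = np.full((10, 10), 100, np.uint8)
        mask, t = select_threshold(chan, ThresholdSpec("manual", 128))
        assert t == 128 and mask.all()

    def test_manual_none_pass(self):
        chan = np.full((5, 5), 1, np.uint8)
        mask, t = select_threshold(chan, ThresholdSpec("manual", 0))
        assert not mask.any()

    def test_otsu_constant_raster_rejected(self):
        chan = np.full((5, 5), 7, np.uint8)
        with pytest.raises(ValueError, match="manual"):
            select_threshold(chan, ThresholdSpec("otsu"))

    def test_otsu_separates_bimodal_exactly(self):
        chan = np.full((20, 20), 250, np.uint8)
        planted = np.zeros_like(chan, bool)
        planted[5:10, 5:15] = True
        chan[planted] = 40
        mask, t = select_threshold(chan, ThresholdSpec("otsu"))
        assert np.array_equal(mask, planted)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            ThresholdSpec("manual")
        with pytest.raises(ValueError):
            ThresholdSpec("manual", 300)
        with pytest.raises(ValueError):
            ThresholdSpec("magic")


class TestFormulas:
    def test_positive_area_pct(self):
        assert positive_area_pct(2500, 10000) == 25.0
        assert positive_area_pct(10, 10) == 100.0
        with pytest.raises(ValueError):
            positive_area_pct(5, 0)
        with pytest.raises(ValueError):
            positive_area_pct(11, 10)

    @pytest.mark.parametrize(
        "mean,expected", [(255.0, 0.0), (25.5, 1.0), (2.55, 2.0)]
    )
    def test_uncalibrated_od(self, mean, expected):
        assert uncalibrated_od(mean) == pytest.approx(expected)

    def test_uncalibrated_od_domain(self):
        with pytest.raises(ValueError):
            uncalibrated_od(0.0)
        with pytest.raises(ValueError):
            uncalibrated_od(256.0)

    def test_od_strictly_decreasing_in_mean(self):
        means = np.linspace(1, 255, 50)
        ods = [uncalibrated_od(m) for m in means]
        assert all(a > b for a, b in zip(ods, ods[1:]))


class TestClearOutside:
    def test_full_roi_identity(self):
        rng = np.random.default_rng(0)
        img = _img(rng.integers(0, 255, (8, 8, 3)))
        out = clear_outside(img, np.ones((8, 8), bool))
        assert np.array_equal(out.pixels, img.pixels)

    def test_empty_roi_rejected(self):
        img = _img(np.zeros((8, 8, 3)))
        with pytest.raises(ValueError, match="empty"):
            clear_outside(img, np.zeros((8, 8), bool))

    def test_outside_pixels_white(self):
        img = _img(np.zeros((8, 8, 3)))
        roi = np.zeros((8, 8), bool)
        roi[2:4, 2:4] = True
        out = clear_outside(img, roi)
        assert np.all(out.pixels[~roi] == 255)
        assert np.all(out.pixels[roi] == 0)

    def test_polygon_roi(self):
        img = _img(np.zeros((20, 20, 3)))
        poly = [(2.0, 2.0), (15.0, 2.0), (15.0, 15.0), (2.0, 15.0)]
        out = clear_outside(img, poly)
        assert np.all(out.pixels[5, 5] == 0)
        assert np.all(out.pixels[0, 0] == 255)


@pytest.fixture(scope="module")
def stained_scene():
    return generate_scene(
        PhantomSpec(n_tubules=8, section_radius_um=500.0, seed=13)
    )


class TestMeasureIHC:

    def test_counterstained_measurement(self, stained_scene):
        img, fields = render_ihc(stained_scene, dab_coverage=0.3)
        m = measure_ihc(
            img,
            fields["tissue"],
            StainMatrix.hdab(),
            counterstain=ThresholdSpec("manual", 240),
        )
        assert m.positive_pct == pytest.approx(30.0, abs=1.0)
        assert m.od == pytest.approx(stained_scene.spec.ihc_dab_od, abs=0.02)

    def test_counterstain_free_refuses_percentage(self):
        scene = generate_scene(
            PhantomSpec(
                n_tubules=8,
                section_radius_um=500.0,
                seed=13,
                ihc_hema_od=0.0,
            )
        )
        img, fields = render_ihc(scene)
        m = measure_ihc(img, fields["tissue"], StainMatrix.hdab())
        assert m.positive_pct is None
        assert m.total_stained_area_px is None
        assert "counterstain" in m.notes
        assert m.od == pytest.approx(scene.spec.ihc_dab_od, abs=0.02)

    def test_determinism(self, stained_scene):
        img, fields = render_ihc(stained_scene, dab_coverage=0.25)
        kw = dict(counterstain=ThresholdSpec("manual", 240))
        m1 = measure_ihc(img, fields["tissue"], StainMatrix.hdab(), **kw)
        m2 = measure_ihc(img, fields["tissue"], StainMatrix.hdab(), **kw)
        assert m1 == m2

    def test_cleared_background_excluded(self, stained_scene):
        """Stats agree whether computed on the cleared image or with the
        ROI applied to the original directly."""
        img, fields = render_ihc(stained_scene, dab_coverage=0.2)
        roi = fields["tissue"]
        cleared = clear_outside(img, roi)
        kw = dict(counterstain=ThresholdSpec("manual", 240))
        m1 = measure_ihc(img, roi, StainMatrix.hdab(), **kw)
        m2 = measure_ihc(cleared, roi, StainMatrix.hdab(), **kw)
        assert m1.positive_pct == m2.positive_pct
        assert m1.od == m2.od
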