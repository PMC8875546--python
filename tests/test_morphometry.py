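"""Derived-quantity formulas, sampling and the section report."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cathi import (
    Calibration,
    ShapeMetrics,
    bergmann_kliesch,
    build_section_report,
    count_tubules,
    interstitial_area,
    measure_tubule,
    sample_tubules,
    se_area,
    se_area_ratio,
    tubule_area_ratio,
    tubule_number_density,
)

from conftest import disk_mask


areas = st.floats(min_value=1.0, max_value=1e8, allow_nan=False)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(tubule=areas, frac=st.floats(0.0, 0.999))
def test_epithelium_lumen_additivity(tubule, frac):
    """se_area + lumen_area == tubule_area exactly, and the ratio matches
    an independent recomputation to machine precision."""
    lumen = tubule * frac
    epi = se_area(tubule, lumen)
    assert epi + lumen == pytest.approx(tubule, rel=1e-15)
    ratio = se_area_ratio(epi, tubule)
    assert ratio == pytest.approx(100.0 * (tubule - lumen) / tubule, rel=1e-12)
    assert 0.0 <= ratio <= 100.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(total=areas, frac=st.floats(0.0, 1.0))
def test_interstitial_tubule_ratio_additivity(total, frac):
    """Tubule area ratio and interstitial fraction sum to exactly 100%."""
    tubules = total * frac
    inter = interstitial_area(total, tubules)
    assert inter + tubules == pytest.approx(total, rel=1e-12)
    pct = tubule_area_ratio(tubules, total)
    assert pct + 100.0 * inter / total == pytest.approx(100.0, rel=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    positive=st.integers(0, 1000),
    extra=st.integers(0, 1000),
)
def test_bergmann_kliesch_range(positive, extra):
    total = positive + extra
    if total == 0:
        return
    score = bergmann_kliesch(positive, total)
    assert 0.0 <= score <= 100.0
    assert score == pytest.approx(100.0 * positive / total, rel=1e-12)


def test_bergmann_kliesch_examples():
    assert bergmann_kliesch(50, 100) == 50.0
    assert bergmann_kliesch(37, 37) == 100.0
    with pytest.raises(ValueError):
        bergmann_kliesch(1, 0)
    with pytest.raises(ValueError):
        bergmann_kliesch(5, 4)


def test_se_area_examples():
    assert se_area(5000.0, 1000.0) == 4000.0
    assert se_area(123.0, 0.0) == 123.0
    with pytest.raises(ValueError, match="mis-paired"):
        se_area(100.0, 200.0)


def test_se_area_annulus_oracle():
    """Concentric disks r=100/60 px: epithelium area ~ pi(100^2 - 60^2)."""
    cal = Calibration(1.0)
    outer = disk_mask(100, pad=6)
    inner = disk_mask(60, pad=46)
    m = measure_tubule(1, outer, inner, cal)
    assert m.se_area_um2 == pytest.approx(
        np.pi * (100**2 - 60**2), rel=0.01
    )
    assert m.se_area_ratio_pct == pytest.approx(100 * (1 - 0.6**2), rel=0.01)


def test_se_area_ratio_examples():
    assert se_area_ratio(4000.0, 5000.0) == 80.0
    assert se_area_ratio(777.0, 777.0) == 100.0
    with pytest.raises(ValueError):
        se_area_ratio(1.0, 0.0)


def test_interstitial_area_examples():
    assert interstitial_area(1_000_000.0, 600_000.0) == 400_000.0
    assert interstitial_area(5000.0, 0.0) == 5000.0
    with pytest.raises(ValueError, match="inconsistent"):
        interstitial_area(100.0, 200.0)


def test_tubule_area_ratio_examples():
    assert tubule_area_ratio(600_000.0, 1_000_000.0) == 60.0
    assert tubule_area_ratio(0.0, 123.0) == 0.0


def test_tubule_number_density():
    assert tubule_number_density(500, 1_000_000.0) == 5e-4
    # doubling the calibration quadruples area, so density divides by 4
    assert tubule_number_density(500, 4_000_000.0) == 5e-4 / 4
    with pytest.raises(ValueError):
        tubule_number_density(1, 0.0)


def test_count_tubules():
    labels = np.zeros((20, 20), np.uint16)
    labels[1:5, 1:5] = 3
    labels[10:14, 10:14] = 7
    assert count_tubules(labels) == 2
    assert count_tubules(np.zeros((5, 5), np.uint16)) == 0


class TestSampling:
    def _records(self, n_cross, n_long):
        recs = [
            {"tubule_id": i + 1, "is_longitudinal": i < n_long}
            for i in range(n_cross + n_long)
        ]
        return recs

    def test_sample_excludes_longitudinal(self):
        recs = self._records(200, 20)
        ids = sample_tubules(recs, 100, seed=1)
        assert len(ids) == 100
        assert len(set(ids)) == 100
        long_ids = {r["tubule_id"] for r in recs if r["is_longitudinal"]}
        assert not long_ids & set(ids)

    def test_small_pool_takes_all(self, caplog):
        recs = self._records(40, 5)
        with caplog.at_level(logging.WARNING):
            ids = sample_tubules(recs, 75, seed=0)
        assert len(ids) == 40
        assert any("40" in r.message for r in caplog.records)

    def test_seed_determinism(self):
        recs = self._records(150, 0)
        assert sample_tubules(recs, 80, 5) == sample_tubules(recs, 80, 5)
        assert sample_tubules(recs, 80, 5) != sample_tubules(recs, 80, 6)

    def test_no_cross_tubules_rejected(self):
        with pytest.raises(ValueError, match="no cross-sectioned"):
            sample_tubules(self._records(0, 10), 10, seed=0)


def _dummy_records(n=10, positive=4):
    cal = Calibration(1.0)
    outer = disk_mask(40, pad=5)
    inner = disk_mask(20, pad=25)
    return [
        measure_tubule(
            i + 1,
            outer,
            inner,
            cal,
            is_spermatid_positive=i < positive,
            thickness_seed=i,
        )
        for i in range(n)
    ]


def test_section_report_invariants():
    records = _dummy_records()
    tubule_area = records[0].tubule_area_um2
    section = ShapeMetrics(
        area_um2=tubule_area * 50,
        perimeter_um=5000.0,
        diameter_1_um=1500.0,
        diameter_2_um=1400.0,
        diameter_avg_um=1450.0,
    )
    rep = build_section_report(section, records, sampled_ids=[1, 2, 3])
    assert rep.total_tubule_count == 10
    assert rep.spermatid_positive_count == 4
    assert rep.bergmann_kliesch_pct == 40.0
    assert rep.interstitial_area_um2 == pytest.approx(
        rep.total_testis_area_um2 - rep.sum_all_tubule_areas_um2
    )
    assert rep.tubule_area_ratio_pct + (
        100 * rep.interstitial_area_um2 / rep.total_testis_area_um2
    ) == pytest.approx(100.0)
    assert rep.tubule_number_density_per_um2 == pytest.approx(
        10 / rep.total_testis_area_um2
    )


def test_tubule_measurement_invariants():
    for m in _dummy_records(3):
        assert m.lumen_area_um2 < m.tubule_area_um2
        assert m.se_area_um2 == m.tubule_area_um2 - m.lumen_area_um2
        assert 0 < m.se_area_ratio_pct < 100
        assert m.lumen_d1_um <= m.tubule_d1_um
        assert m.lumen_d2_um <= m.tubule_d2_um
        assert m.tubule_davg_um == (m.tubule_d1_um + m.tubule_d2_um) / 2
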