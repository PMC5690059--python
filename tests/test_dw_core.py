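import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwcalc import synthetic_phantoms as sp
from dwcalc.contouring import auto_contour
from dwcalc.dw_core import (
    SliceMetrics,
    dw_all,
    dw_n,
    per_slice_metrics,
    percent_diff,
    scan_metrics,
    select_slices,
    slice_dw,
)


def _metrics_from_dw(dws):
    return [SliceMetrics(i, float(i), 1.0, 0.0, d) for i, d in enumerate(dws)]


class TestSliceDw:
    def test_body_phantom_closed_form(self):
        """32-cm PMMA phantom: mean 120 HU over 804.25 cm^2 gives 33.87 cm."""
        assert slice_dw(120.0, 804.25) == pytest.approx(33.87, abs=0.005)

    def test_head_phantom_closed_form(self):
        assert slice_dw(120.0, 201.06) == pytest.approx(16.933, abs=0.001)

    def test_water_identity(self):
        """A 0-HU region has D_W equal to its equal-area circle diameter."""
        assert slice_dw(0.0, math.pi * 16.0**2) == pytest.approx(32.0, abs=1e-12)

    def test_pure_air_limit(self):
        assert slice_dw(-1000.0, 123.0) == 0.0

    def test_sub_floor_mean_clamped_to_zero(self):
        assert slice_dw(-1200.0, 50.0) == 0.0

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValueError):
            slice_dw(0.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(hu=st.floats(-999, 2000), area=st.floats(1.0, 2000.0),
           scale=st.floats(1.01, 4.0))
    def test_monotone_in_hu_and_area(self, hu, area, scale):
        base = slice_dw(hu, area)
        assert slice_dw(hu, area * scale) > base
        assert slice_dw(hu + 100, area) > base

    @settings(max_examples=50, derandomize=True)
    @given(hu=st.floats(-999, 2000), area=st.floats(1.0, 2000.0),
           s=st.floats(0.5, 3.0))
    def test_scale_equivariance(self, hu, area, s):
        """Scaling pixel spacing by s scales areas by s^2 and D_W by s."""
        assert slice_dw(hu, area * s**2) == pytest.approx(s * slice_dw(hu, area))


class TestPerSliceMetrics:
    def test_area_unit_conversion(self):
        """100 masked pixels at 1.0 mm spacing make 1 cm^2."""
        ph = sp.generate(sp.disk_spec(4.0, 0.0, grid=(64, 64)))
        m = per_slice_metrics(ph.ct, auto_contour(ph.ct))[0]
        assert m.area_cm2 == pytest.approx(ph.body_mask[0].sum() / 100.0)

    def test_uniform_disk_matches_pixel_count_closed_form(self, small_disk):
        body = auto_contour(small_disk.ct)
        m = per_slice_metrics(small_disk.ct, body)[0]
        n_px = small_disk.body_mask[0].sum()
        assert m.mean_hu == pytest.approx(120.0)
        assert m.dw_cm == pytest.approx(slice_dw(120.0, n_px / 100.0))

    def test_mean_linearity_half_and_half(self, small_disk):
        """Half 0 HU / half 240 HU averages to the uniform-120 diameter."""
        hu = small_disk.ct.hu.copy()
        mask = small_disk.body_mask
        cols = np.arange(hu.shape[2]) < hu.shape[2] // 2
        hu[:, :, cols] = np.where(mask[:, :, cols], 0.0, hu[:, :, cols])
        hu[:, :, ~cols] = np.where(mask[:, :, ~cols], 240.0, hu[:, :, ~cols])
        vol = type(small_disk.ct)(hu, small_disk.ct.pixel_spacing,
                                  small_disk.ct.slice_positions)
        m = per_slice_metrics(vol, auto_contour(vol))[0]
        assert m.mean_hu == pytest.approx(120.0, abs=1.0)
        assert m.dw_cm == pytest.approx(slice_dw(120.0, m.area_cm2), rel=5e-4)


class TestDwAll:
    def test_arithmetic_mean(self):
        assert dw_all(_metrics_from_dw([20.0, 22.0, 24.0])) == 22.0

    def test_single_slice(self):
        assert dw_all(_metrics_from_dw([19.5])) == 19.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dw_all([])


class TestSelectSlices:
    @pytest.mark.parametrize(
        "n_total, n, expected",
        [
            (9, 9, list(range(9))),
            (101, 1, [50]),
            (5, 3, [0, 2, 4]),
            (5, 5, [0, 1, 2, 3, 4]),
            (7, 1, [3]),
        ],
    )
    def test_frozen_examples(self, n_total, n, expected):
        assert select_slices(n_total, n) == expected

    def test_rejects_n_out_of_range(self):
        with pytest.raises(ValueError):
            select_slices(3, 5)
        with pytest.raises(ValueError):
            select_slices(3, 0)

    @settings(max_examples=200, derandomize=True)
    @given(n_total=st.integers(1, 400), n=st.sampled_from([1, 3, 5, 7, 9]))
    def test_even_spread_properties(self, n_total, n):
        if n > n_total:
            return
        idx = select_slices(n_total, n)
        assert len(idx) == n and idx == sorted(set(idx))
        assert all(0 <= i < n_total for i in idx)
        if n > 1:
            assert idx[0] == 0 and idx[-1] == n_total - 1
            gaps = np.diff(idx)
            assert gaps.max() - gaps.min() <= 1  # even distribution
        # symmetry about the center whenever the ideal positions are exact
        if n > 1 and (n_total - 1) % (n - 1) == 0:
            assert sorted(n_total - 1 - i for i in idx) == idx


class TestEstimators:
    def test_percent_diff_signed(self):
        assert percent_diff(22.0, 20.0) == pytest.approx(10.0)
        assert percent_diff(20.0, 20.0) == 0.0

    def test_homogeneous_profile_gives_zero_pd(self):
        mets = _metrics_from_dw([25.0] * 11)
        da = dw_all(mets)
        for n in (1, 3, 5, 7, 9):
            val, _ = dw_n(mets, n)
            assert percent_diff(val, da) == 0.0

    def test_dw_n_mean_over_selection(self):
        mets = _metrics_from_dw([10.0, 20.0, 30.0, 40.0, 50.0])
        val, sel = dw_n(mets, 3)
        assert val == pytest.approx((10.0 + 30.0 + 50.0) / 3.0)
        assert sel == [0, 2, 4]


class TestScanMetrics:
    def test_end_to_end_consistency(self, small_disk):
        body = auto_contour(small_disk.ct)
        m = scan_metrics(small_disk.ct, body, n_values=(1, 3))
        assert m.dw_all == pytest.approx(np.mean([s.dw_cm for s in m.slices]))
        assert m.pd_n[1] == pytest.approx(
            100 * (m.dw_n[1] - m.dw_all) / m.dw_all)
        assert m.n_excluded == 0
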