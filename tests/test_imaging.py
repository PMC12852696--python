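"""Stack background subtraction, alignment and circle measurements."""

import numpy as np
import pytest

from neurotransit import imaging
from neurotransit.imaging import (
    BackgroundSpec,
    CellMeasurement,
    ImageStack,
    align_apical_surface,
    apicobasal_profile,
    average_background_stack,
    call_prb_status,
    measure_cell,
    subtract_average_background,
    subtract_tissue_background,
)


def _stack(pixels, **kw):
    return ImageStack(np.asarray(pixels, dtype=float), **kw)


def _uniform(value, nz=3, ny=40, nx=40):
    return _stack(np.full((nz, 3, ny, nx), float(value)))


ROI = np.array([[2, 2], [20, 2], [20, 20], [2, 20]], dtype=float)


class TestAverageBackground:
    def test_uniform_stack_minus_own_average_is_zero(self):
        s = _uniform(37.0)
        avg = average_background_stack(s.pixels)
        out = subtract_average_background(s, avg)
        assert np.all(out.pixels == 0.0)

    def test_simple_arithmetic(self):
        out = subtract_average_background(_uniform(100.0), np.full((3, 3, 40, 40), 30.0))
        assert np.all(out.pixels == 70.0)

    def test_clamped_at_zero(self):
        out = subtract_average_background(_uniform(10.0), np.full((3, 3, 40, 40), 30.0))
        assert np.all(out.pixels == 0.0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            subtract_average_background(_uniform(1.0), np.zeros((3, 3, 10, 10)))


class TestTissueBackground:
    def test_z_constant_per_channel_fully_removed(self):
        nz = 5
        px = np.empty((nz, 3, 30, 30))
        for z in range(nz):
            for c in range(3):
                px[z, c] = 10.0 * (c + 1) + 2.0 * z
        spec = BackgroundSpec(tissue_roi=ROI, channel_constants={"GFP": 0, "Myc": 0, "pRb": 0})
        out = subtract_tissue_background(_stack(px), spec)
        assert np.abs(out.pixels).max() < 1e-9

    def test_prb_constant_60_zeroes_uniform_residual(self):
        # pRb channel uniformly at 60 after the ROI step: ROI mean subtraction
        # removes nothing extra here because the plane is offset-only; use a
        # stack where the ROI region is clean and the constant does the rest
        px = np.zeros((2, 3, 30, 30))
        px[:, 2, :, :] = 60.0
        spec = BackgroundSpec(
            tissue_roi=ROI, channel_constants={"GFP": 5.0, "Myc": 5.0, "pRb": 60.0}
        )
        out = subtract_tissue_background(_stack(px), spec)
        assert np.all(out.pixels[:, 2] == 0.0)

    def test_linear_z_gradient_removed_exactly(self):
        nz = 7
        px = np.empty((nz, 3, 30, 30))
        for z in range(nz):
            for c in range(3):
                px[z, c] = 50.0 - 3.0 * z + 5.0 * c
        spec = BackgroundSpec(tissue_roi=ROI, channel_constants={"GFP": 0, "Myc": 0, "pRb": 0})
        out = subtract_tissue_background(_stack(px), spec)
        assert np.abs(out.pixels).max() < 1e-6

    def test_roi_outside_image_raises(self):
        spec = BackgroundSpec(tissue_roi=np.array([[100, 100], [120, 100], [120, 120]]))
        with pytest.raises(ValueError):
            subtract_tissue_background(_uniform(1.0, ny=30, nx=30), spec)

    def test_order_enforced_average_before_tissue(self):
        s = subtract_tissue_background(
            _uniform(5.0), BackgroundSpec(tissue_roi=ROI, channel_constants={"GFP": 0, "Myc": 0, "pRb": 0})
        )
        with pytest.raises(RuntimeError):
            subtract_average_background(s, np.zeros_like(s.pixels))


class TestAlignment:
    def test_horizontal_line_at_zero_is_identity(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(0, 10, size=(2, 3, 30, 30))
        s = _stack(px)
        out = align_apical_surface(s, np.array([[0.0, 0.0], [29.0, 0.0]]))
        assert np.allclose(out.pixels, px, atol=1e-9)
        assert out.apical_axis_aligned

    def test_tilted_line_distance_preserved(self):
        # marked pixel at known perpendicular distance from a tilted line
        ny = nx = 120
        px = np.zeros((1, 3, ny, nx))
        px[0, :, 90, 40] = 100.0
        s = _stack(px, pixel_size_um=1.0)
        theta = np.radians(12.0)
        line = np.array([[0.0, 20.0], [nx - 1.0, 20.0 + np.tan(theta) * (nx - 1)]])
        out = align_apical_surface(s, line)
        iy, ix = np.unravel_index(np.argmax(out.pixels[0, 0]), out.pixels[0, 0].shape)
        d_true = (90 - 20 - np.tan(theta) * 40) * np.cos(theta)
        assert abs(iy - d_true) <= 1.0

    def test_degenerate_line_raises(self):
        with pytest.raises(ValueError):
            align_apical_surface(_uniform(1.0), np.array([[5.0, 5.0], [5.0, 5.0]]))


class TestMeasureCell:
    def test_uniform_value_measured_exactly(self):
        s = _uniform(7.0, ny=60, nx=60)
        s.pixel_size_um = 0.5
        m = measure_cell(s, 15.0, 15.0, 1, diameter_um=8.0)
        assert m.mean_gfp == m.mean_myc == m.mean_prb == pytest.approx(7.0)

    def test_gaussian_blob_matches_analytic_disc_integral(self):
        ny = nx = 101
        sigma_px = 8.0
        amp = 200.0
        yy, xx = np.mgrid[0:ny, 0:nx]
        blob = amp * np.exp(-(((xx - 50) ** 2 + (yy - 50) ** 2) / (2 * sigma_px**2)))
        px = np.zeros((1, 3, ny, nx))
        px[0, :] = blob
        s = _stack(px, pixel_size_um=1.0)
        r = 2 * sigma_px
        m = measure_cell(s, 50.0, 50.0, 0, diameter_um=2 * r)
        analytic = amp * (2 * sigma_px**2 / r**2) * (1 - np.exp(-(r**2) / (2 * sigma_px**2)))
        assert m.mean_myc == pytest.approx(analytic, rel=0.02)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 50, size=(1, 3, 60, 60))
        s1 = _stack(base, pixel_size_um=1.0)
        shifted = np.roll(base, shift=(7, 5), axis=(2, 3))
        s2 = _stack(shifted, pixel_size_um=1.0)
        m1 = measure_cell(s1, 20.0, 20.0, 0)
        m2 = measure_cell(s2, 25.0, 27.0, 0)
        assert m1.mean_gfp == pytest.approx(m2.mean_gfp)

    def test_out_of_bounds_circle_flagged(self):
        s = _uniform(1.0, ny=20, nx=20)
        with pytest.warns(UserWarning):
            m = measure_cell(s, 0.2, 0.2, 0, diameter_um=8.0)
        assert not m.in_bounds


class TestPrbThreshold:
    @pytest.mark.parametrize(
        "value,expected", [(30.0, False), (30.01, True), (0.0, False), (29.99, False)]
    )
    def test_strict_threshold_at_30(self, value, expected):
        m = CellMeasurement(0, 0, 0, 0, 0, mean_prb=value)
        assert call_prb_status(m) is expected


class TestProfile:
    def test_empty_input_gives_empty_table(self):
        assert apicobasal_profile([]).empty

    def test_y_values_from_measurements(self):
        ms = [
            CellMeasurement(1.0, 12.0, 0, 0, 50.0, 40.0, prb_pos=True),
            CellMeasurement(2.0, 70.0, 0, 0, 200.0, 5.0, prb_pos=False),
        ]
        prof = apicobasal_profile(ms, bin_width_um=10.0)
        assert list(prof["y_um"]) == [12.0, 70.0]
        assert list(prof["y_bin"]) == [10.0, 70.0]
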