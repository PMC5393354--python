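"""Dark/flood correction identities, dead-pixel detection, profile matrix, F_ABS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epid2dose import (CineStack, CorrectionSet, EnergyMode, FrameImage,
                       apply_beam_profile_correction, build_dark_field,
                       build_flood_field, build_profile_matrix,
                       compute_abs_factor, correct_raw, detect_dead_pixels,
                       load_correction_set, open_beam_profile,
                       profile_matrix_from_radial, save_correction_set)

N = 32


def img(values, pitch=1.0, units="ADU"):
    return FrameImage(np.asarray(values, float), pitch, units)


def const_img(v, n=N):
    return img(np.full((n, n), float(v)))


def simple_cs(dark_v=50.0, flood_net_v=100.0, **kw):
    return CorrectionSet(dark=const_img(dark_v), flood=const_img(flood_net_v), **kw)


class TestDarkFlood:
    def test_dark_field_average(self):
        stack = CineStack([const_img(50)] * 5)
        assert np.all(build_dark_field(stack).pixels == 50)

    def test_flood_is_dark_subtracted_average(self):
        stack = CineStack([const_img(150)] * 4)
        flood = build_flood_field(stack, const_img(50))
        assert np.all(flood.pixels == 100)

    def test_flood_equal_to_dark_gives_zero(self):
        stack = CineStack([const_img(50)] * 3)
        assert np.all(build_flood_field(stack, const_img(50)).pixels == 0)

    def test_flood_recovers_gain_map_exactly(self):
        rng = np.random.default_rng(2)
        gain = 1 + 0.05 * rng.standard_normal((N, N))
        dark = 50.0 * np.ones((N, N))
        frames = [img(gain * 100 + dark) for _ in range(3)]
        flood = build_flood_field(CineStack(frames), img(dark))
        np.testing.assert_allclose(flood.pixels, 100 * gain, rtol=1e-12)

    def test_dark_mean_recovery_under_noise(self):
        rng = np.random.default_rng(3)
        sigma, n = 5.0, 300
        frames = [img(50 + sigma * rng.standard_normal((N, N)))
                  for _ in range(n)]
        dark = build_dark_field(CineStack(frames))
        tol = 5 * sigma / np.sqrt(n)
        assert np.mean(np.abs(dark.pixels - 50) < tol) >= 0.99


class TestCorrectRaw:
    def test_flood_exposure_corrects_to_one(self):
        cs = simple_cs()
        out = correct_raw(const_img(150), cs)
        np.testing.assert_allclose(out.pixels, 1.0, atol=1e-12)
        assert out.units_tag == "relative"

    def test_dark_exposure_corrects_to_zero(self):
        out = correct_raw(const_img(50), simple_cs())
        np.testing.assert_allclose(out.pixels, 0.0, atol=1e-12)

    def test_arithmetic(self):
        out = correct_raw(const_img(200), simple_cs())
        np.testing.assert_allclose(out.pixels, 1.5)

    def test_integrated_image_dark_scale(self):
        # 10 summed frames carry 10 dark offsets
        out = correct_raw(const_img(10 * 50 + 100), simple_cs(), dark_scale=10)
        np.testing.assert_allclose(out.pixels, 1.0)

    def test_nonpositive_flood_at_live_pixel_errors(self):
        flood = np.full((N, N), 100.0)
        flood[3, 4] = 0.0
        mask = np.zeros((N, N), bool)  # pixel forced live
        with pytest.raises(ValueError, match=r"3.*4"):
            CorrectionSet(dark=const_img(50), flood=img(flood),
                          dead_pixel_mask=mask)

    def test_dead_pixel_filled_from_neighbours(self):
        flood = np.full((N, N), 100.0)
        flood[5, 5] = 0.0  # dead: flagged automatically
        cs = CorrectionSet(dark=const_img(50), flood=img(flood))
        assert cs.dead_pixel_mask[5, 5]
        out = correct_raw(const_img(150), cs)
        np.testing.assert_allclose(out.pixels, 1.0, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(-200, 200), st.floats(0.1, 10))
    def test_shift_and_joint_scale_invariance(self, shift, scale):
        """Adding a constant to raw+dark, or scaling numerator and
        denominator jointly, leaves the corrected image unchanged."""
        rng = np.random.default_rng(9)
        raw = rng.uniform(100, 4000, (N, N))
        dark = rng.uniform(40, 60, (N, N))
        flood_net = rng.uniform(80, 120, (N, N))
        base = correct_raw(img(raw), CorrectionSet(dark=img(dark),
                                                   flood=img(flood_net)))
        shifted = correct_raw(img(raw + shift),
                              CorrectionSet(dark=img(dark + shift),
                                            flood=img(flood_net)))
        scaled = correct_raw(img(dark + scale * (raw - dark)),
                             CorrectionSet(dark=img(dark),
                                           flood=img(scale * flood_net)))
        np.testing.assert_allclose(shifted.pixels, base.pixels, rtol=1e-9,
                                   atol=1e-12)
        np.testing.assert_allclose(scaled.pixels, base.pixels, rtol=1e-9,
                                   atol=1e-12)


class TestProfileMatrix:
    def test_flat_reference_gives_unit_matrix(self):
        m = build_profile_matrix(const_img(5.0))
        np.testing.assert_allclose(m.pixels, 1.0)

    def test_horned_reference_normalised_at_centre(self):
        n = 129
        ax = (np.arange(n) - (n - 1) / 2) * 1.6
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        r = np.hypot(yy, xx)
        ref = np.where(np.abs(r - 80) < 2, 1.05, 1.0)
        m = build_profile_matrix(FrameImage(ref, 1.6, "relative"))
        assert m.pixels[n // 2, n // 2] == 1.0
        assert np.isclose(m.pixels[n // 2, n // 2 + 50], 1.05)  # 80 mm off-axis

    def test_fff_matrix_decreases_radially(self):
        n = 129
        ax = (np.arange(n) - (n - 1) / 2) * 1.6
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        ref = open_beam_profile(EnergyMode.MV6_FFF, np.hypot(yy, xx))
        m = build_profile_matrix(FrameImage(ref, 1.6, "relative"))
        row = m.pixels[n // 2, n // 2:]
        assert np.all(np.diff(row) < 0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            build_profile_matrix(img(np.zeros((N, N))))

    def test_radial_expansion_matches_2d(self):
        radii = np.linspace(0, 200, 100)
        vals = open_beam_profile(EnergyMode.MV6_WFF, radii)
        like = const_img(1.0, n=64)
        m = profile_matrix_from_radial(radii, vals, like)
        yy = like.row_positions_mm()[:, None]
        xx = like.col_positions_mm()[None, :]
        expected = open_beam_profile(EnergyMode.MV6_WFF, np.hypot(yy, xx))
        np.testing.assert_allclose(m.pixels, expected, rtol=2e-4)

    def test_matrix_roundtrip_restores_reference(self):
        """Correcting the flood-derived flat image with the matrix built from
        the true profile reproduces that profile to < 0.1 %."""
        n = 64
        ax = (np.arange(n) - (n - 1) / 2) * 1.6
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        profile = open_beam_profile(EnergyMode.MV6_WFF, np.hypot(yy, xx))
        matrix = build_profile_matrix(FrameImage(profile, 1.6, "relative"))
        cs = CorrectionSet(dark=FrameImage(np.full((n, n), 50.0), 1.6),
                           flood=FrameImage(np.full((n, n), 100.0), 1.6),
                           beam_profile_matrix=matrix)
        flat = correct_raw(FrameImage(np.full((n, n), 150.0), 1.6), cs)
        restored = apply_beam_profile_correction(flat, cs)
        centre = profile[n // 2, n // 2]
        np.testing.assert_allclose(restored.pixels, profile / centre, rtol=1e-3)


class TestDeadPixels:
    def test_clean_maps_empty_mask(self):
        rng = np.random.default_rng(1)
        dark = img(100 + 2 * rng.standard_normal((N, N)))
        flood = img(1000 + 10 * rng.standard_normal((N, N)))
        assert detect_dead_pixels(dark, flood).sum() == 0

    def test_zero_flood_pixel_flagged(self):
        flood = np.full((N, N), 100.0)
        flood[2, 2] = 0.0
        mask = detect_dead_pixels(const_img(50), img(flood))
        assert mask[2, 2] and mask.sum() == 1

    def test_injected_outliers_recovered_exactly(self):
        rng = np.random.default_rng(77)
        n = 256
        dark = 100 + 2 * rng.standard_normal((n, n))
        flood = 1000 + 10 * rng.standard_normal((n, n))
        rows = rng.choice(n, 10, replace=False)
        cols = rng.choice(n, 10, replace=False)
        dark[rows[:5], cols[:5]] = 4000.0  # hot pixels
        flood[rows[5:], cols[5:]] = 100.0  # dim pixels
        mask = detect_dead_pixels(img(dark), img(flood), k_mad=6)
        expected = np.zeros((n, n), bool)
        expected[rows, cols] = True
        np.testing.assert_array_equal(mask, expected)


class TestAbsFactor:
    @pytest.mark.parametrize("d_epid,expected", [(100.0, 1.0), (80.0, 1.25)])
    def test_ratio(self, d_epid, expected):
        assert compute_abs_factor(d_epid, 100.0) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            compute_abs_factor(0.0, 100.0)
        with pytest.raises(ValueError):
            compute_abs_factor(10.0, -1.0)


class TestSerialization:
    def test_round_trip(self, tmp_path):
        cs = simple_cs(mode_tag=EnergyMode.MV6_FFF)
        cs.f_abs[EnergyMode.MV6_FFF] = 1.234
        save_correction_set(cs, tmp_path / "cal")
        back = load_correction_set(tmp_path / "cal")
        np.testing.assert_allclose(back.dark.pixels, cs.dark.pixels)
        np.testing.assert_allclose(back.flood.pixels, cs.flood.pixels)
        assert back.mode_tag is EnergyMode.MV6_FFF
        assert back.f_abs[EnergyMode.MV6_FFF] == pytest.approx(1.234)
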