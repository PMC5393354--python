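"""Forward simulator: field geometry, detector model, determinism, plans."""

import numpy as np
import pytest

from epid2dose import (CorrectionSet, EnergyMode, FieldSpec, FluenceMap,
                       FrameImage, PanelModel, build_dark_field,
                       build_flood_field, correct_raw, ground_truth_dose,
                       make_field_fluence, make_mlc_polygon,
                       make_synthetic_plan, open_beam_profile,
                       simulate_calibration_stacks, simulate_epid_stack)

from conftest import MODE, N_PX, PITCH_MM


class TestFieldGeometry:
    def test_square_field_width_both_axes(self):
        flu = make_field_fluence(FieldSpec("square", 10.0, mode_tag=MODE),
                                 PITCH_MM, N_PX)
        v = flu.values
        for profile in (v[N_PX // 2, :], v[:, N_PX // 2]):
            above = np.nonzero(profile >= 0.5 * profile.max())[0]
            width = (above[-1] - above[0] + 1) * PITCH_MM
            assert abs(width - 100.0) <= PITCH_MM

    def test_small_circle_area(self):
        flu = make_field_fluence(
            FieldSpec("circle", 2.0, penumbra_sigma_mm=1.0, mode_tag=MODE),
            0.4, 256)
        area_cm2 = np.count_nonzero(flu.values >= 0.5 * flu.values.max()) * 0.04 ** 2
        assert abs(area_cm2 - np.pi) / np.pi < 0.05

    def test_zero_amplitude_zero_map(self):
        flu = make_field_fluence(
            FieldSpec("square", 5.0, amplitude=0.0, mode_tag=MODE),
            PITCH_MM, N_PX)
        assert np.all(flu.values == 0)

    def test_field_exceeding_grid_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_field_fluence(FieldSpec("square", 18.0, mode_tag=MODE),
                               PITCH_MM, 64)  # 10.2 cm panel

    def test_wff_profile_has_horns_fff_is_peaked(self):
        r = np.array([0.0, 80.0])
        wff = open_beam_profile(EnergyMode.MV10_WFF, r)
        fff = open_beam_profile(EnergyMode.MV10_FFF, r)
        assert wff[1] > wff[0]  # horn at 8 cm
        assert fff[1] < fff[0]  # cone falls off


class TestMlcPolygon:
    def test_square_polygon_equivalent_to_square(self):
        s = 3.0
        poly = make_mlc_polygon([(-s, -s), (s, -s), (s, s), (-s, s)],
                                mode=MODE)
        a = make_field_fluence(poly, PITCH_MM, N_PX)
        b = make_field_fluence(FieldSpec("square", 2 * s, mode_tag=MODE),
                               PITCH_MM, N_PX)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_l_shape_area(self):
        # 6x6 square minus its 3x3 corner: 27 cm^2
        # pitch chosen so polygon edges fall between pixel centres (the
        # rasteriser samples pixel centres; edges on centres resolve outward)
        verts = [(-3, -3), (3, -3), (3, 0), (0, 0), (0, 3), (-3, 3)]
        flu = make_field_fluence(
            make_mlc_polygon(verts, penumbra_sigma_mm=0.5, mode=MODE), 0.75, 256)
        area = np.count_nonzero(flu.values >= 0.5 * flu.values.max()) * 0.075 ** 2
        assert abs(area - 27.0) / 27.0 < 0.02

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError, match="3 vertices"):
            make_mlc_polygon([(0, 0), (1, 1)])

    def test_self_intersecting_rejected(self):
        with pytest.raises(ValueError, match="self-intersecting"):
            make_mlc_polygon([(0, 0), (2, 2), (2, 0), (0, 2)])


class TestDetectorModel:
    def test_zero_fluence_no_noise_gives_dark_frames(self):
        panel = PanelModel(32, 32, 1.0, gain_sigma=0.0, dark_level_adu=80.0,
                           dark_sigma_adu=0.0, read_noise_adu=0.0, n_frames=3)
        flu = FluenceMap(np.zeros((32, 32)), 1.0, MODE)
        kde = _delta_glare()
        stack = simulate_epid_stack(flu, kde, panel, poisson=False)
        for f in stack.frames:
            np.testing.assert_array_equal(f.pixels, 80.0)

    def test_degenerate_model_returns_scaled_signal(self):
        panel = PanelModel(32, 32, 1.0, gain_sigma=0.0, dark_level_adu=0.0,
                           dark_sigma_adu=0.0, read_noise_adu=0.0,
                           conversion_adu=500.0, n_frames=1)
        rng = np.random.default_rng(2)
        flu = FluenceMap(rng.uniform(0, 1, (32, 32)), 1.0, MODE)
        kde = _delta_glare()
        stack = simulate_epid_stack(flu, kde, panel, poisson=False)
        np.testing.assert_allclose(stack.frames[0].pixels, flu.values * 500.0,
                                   atol=1e-9)

    def test_same_seed_bit_identical(self):
        panel = PanelModel(32, 32, 1.0, seed=5, n_frames=4)
        flu = FluenceMap(np.ones((32, 32)), 1.0, MODE)
        kde = _delta_glare()
        a = simulate_epid_stack(flu, kde, panel, seed=9)
        b = simulate_epid_stack(flu, kde, panel, seed=9)
        np.testing.assert_array_equal(a.as_array(), b.as_array())

    def test_forward_model_linear_in_amplitude(self):
        panel = PanelModel(32, 32, 1.0, dark_level_adu=0.0, dark_sigma_adu=0.0,
                           read_noise_adu=0.0, n_frames=2)
        kde = _delta_glare()
        base = FluenceMap(np.ones((32, 32)), 1.0, MODE)
        twice = FluenceMap(2 * np.ones((32, 32)), 1.0, MODE)
        a = simulate_epid_stack(base, kde, panel, poisson=False).as_array()
        b = simulate_epid_stack(twice, kde, panel, poisson=False).as_array()
        np.testing.assert_allclose(b, 2 * a, rtol=1e-12)


class TestCalibrationStacks:
    def test_noiseless_flood_recovers_gain_exactly(self):
        panel = PanelModel(32, 32, 1.0, gain_sigma=0.03, dark_sigma_adu=0.0,
                           read_noise_adu=0.0, seed=3)
        kde = _delta_glare()
        dark_st, flood_st = simulate_calibration_stacks(
            panel, kde, MODE, n_frames=5, poisson=False, include_profile=False)
        dark = build_dark_field(dark_st)
        flood = build_flood_field(flood_st, dark)
        per_frame = panel.conversion_adu / 5
        np.testing.assert_allclose(flood.pixels / per_frame, panel.gain_map,
                                   rtol=1e-9)

    def test_fresh_flood_exposure_corrects_to_one(self):
        """End to end: calibrate from simulated stacks, then a fresh flood
        frame corrects to unity within 1 % at the stated noise."""
        panel = PanelModel(64, 64, 1.6, conversion_adu=3e5, seed=13)
        kde = _delta_glare(1.6)
        dark_st, flood_st = simulate_calibration_stacks(panel, kde, MODE,
                                                        n_frames=300, seed=21)
        dark = build_dark_field(dark_st)
        flood = build_flood_field(flood_st, dark)
        cs = CorrectionSet(dark=dark, flood=flood, mode_tag=MODE)
        _, fresh = simulate_calibration_stacks(panel, kde, MODE,
                                               n_frames=300, seed=99)
        from epid2dose import average_frames
        fresh_avg = average_frames(fresh)
        out = correct_raw(fresh_avg, cs)
        assert np.abs(out.pixels - 1).max() < 0.01

    def test_seeded_determinism(self):
        panel = PanelModel(32, 32, 1.0, seed=5)
        kde = _delta_glare()
        a = simulate_calibration_stacks(panel, kde, MODE, n_frames=3, seed=7)
        b = simulate_calibration_stacks(panel, kde, MODE, n_frames=3, seed=7)
        np.testing.assert_array_equal(a[0].as_array(), b[0].as_array())
        np.testing.assert_array_equal(a[1].as_array(), b[1].as_array())


class TestGroundTruthAndPlans:
    def test_delta_fluence_gives_scaled_kernel(self, kpb):
        n = 2 * kpb.half_size_px + 1
        flu = np.zeros((n, n)); flu[n // 2, n // 2] = 1.0
        d = ground_truth_dose(FluenceMap(flu, PITCH_MM, MODE), kpb, 50.0)
        np.testing.assert_allclose(d.values, 50.0 * kpb.values, atol=1e-12)
        assert d.depth_cm == MODE.d_max_cm

    def test_linearity_in_dose_per_amplitude(self, kpb, ref_fluence):
        d1 = ground_truth_dose(ref_fluence, kpb, 1.0)
        d2 = ground_truth_dose(ref_fluence, kpb, 3.5)
        np.testing.assert_allclose(d2.values, 3.5 * d1.values, rtol=1e-12)

    def test_single_segment_plan_is_that_segment(self):
        segs, comp = make_synthetic_plan(1, seed=4, pitch_mm=PITCH_MM,
                                         n_px=N_PX, mode=MODE)
        assert len(segs) == 1
        direct = make_field_fluence(segs[0], PITCH_MM, N_PX)
        np.testing.assert_allclose(comp.values, direct.values, atol=1e-12)

    def test_composite_is_sum_of_segments(self):
        segs, comp = make_synthetic_plan(5, seed=8, pitch_mm=PITCH_MM,
                                         n_px=N_PX, mode=MODE)
        total = sum(make_field_fluence(s, PITCH_MM, N_PX).values for s in segs)
        np.testing.assert_allclose(comp.values, total, atol=1e-12)

    def test_plan_deterministic_under_seed(self):
        _, a = make_synthetic_plan(4, seed=3, n_px=64)
        _, b = make_synthetic_plan(4, seed=3, n_px=64)
        np.testing.assert_array_equal(a.values, b.values)


class TestModelMismatchProbe:
    """The detector may glare differently than the deconvolution model
    assumes; simulating with a perturbed kernel while reconstructing with
    the packaged one probes that robustness.  Absolute calibration absorbs
    the global response change and DTA the penumbra reshaping."""

    def test_reconstruction_robust_to_glare_mismatch(self, kde, kpb,
                                                     profile_matrix):
        from epid2dose import (GlareParams, GammaCriteria, build_glare_kernel,
                               calibrate_absolute, cax_value, gamma_index,
                               reconstruct_dose)
        # broader core, heavier tails than the deconvolution model assumes
        true_glare = build_glare_kernel(
            GlareParams(0.90, 0.45, [(0.06, 3.0), (0.04, 14.0)], MODE),
            PITCH_MM, 24)
        panel = PanelModel(N_PX, N_PX, PITCH_MM, seed=7).noiseless()
        dark_st, flood_st = simulate_calibration_stacks(
            panel, true_glare, MODE, n_frames=3, seed=41, poisson=False)
        dark = build_dark_field(dark_st)
        cs = CorrectionSet(dark=dark,
                           flood=build_flood_field(flood_st, dark),
                           beam_profile_matrix=profile_matrix, mode_tag=MODE)
        flu = make_field_fluence(FieldSpec("square", 10.0, mode_tag=MODE),
                                 PITCH_MM, N_PX)
        calibrate_absolute(
            simulate_epid_stack(flu, true_glare, panel, seed=51, poisson=False),
            cs, kde, kpb, MODE)
        dose = reconstruct_dose(
            simulate_epid_stack(flu, true_glare, panel, seed=52, poisson=False),
            cs, kde, kpb, MODE)
        assert cax_value(dose) == pytest.approx(100.0, rel=5e-3)
        from epid2dose import ground_truth_dose as gtd
        truth = gtd(flu, kpb, 100.0 / cax_value(gtd(flu, kpb, 1.0)))
        assert gamma_index(dose, truth,
                           GammaCriteria(3, 3)).pass_rate_pct >= 99.0


def _delta_glare(pitch=1.0):
    from epid2dose import Kernel
    v = np.zeros((17, 17)); v[8, 8] = 1.0
    return Kernel(v, pitch, "glare_K_de")
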