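"""Shared fixtures: desk-scale panel (128 px @ 1.6 mm = 20.48 cm) and kernels.

Expensive objects (the Monte-Carlo pencil-beam kernel, calibration stacks)
are session-scoped so the suite builds them once.
"""

import numpy as np
import pytest

from epid2dose import (CorrectionSet, EnergyMode, FieldSpec, FrameImage,
                       PanelModel, build_dark_field, build_flood_field,
                       build_glare_kernel, build_profile_matrix,
                       calibrate_absolute, default_glare_params,
                       default_spectrum, generate_pencil_beam_kernel,
                       make_field_fluence, open_beam_profile,
                       simulate_calibration_stacks, simulate_epid_stack,
                       water_cross_sections)

PITCH_MM = 1.6
N_PX = 128
MODE = EnergyMode.MV6_WFF


@pytest.fixture(scope="session")
def mode():
    return MODE


@pytest.fixture(scope="session")
def xs():
    return water_cross_sections()


@pytest.fixture(scope="session")
def kde():
    return build_glare_kernel(default_glare_params(MODE), PITCH_MM, 24)


@pytest.fixture(scope="session")
def kpb(xs):
    return generate_pencil_beam_kernel(default_spectrum(MODE), xs,
                                       depth_cm=MODE.d_max_cm, pitch_mm=PITCH_MM,
                                       half_size_px=40, n_histories=200_000, seed=3)


@pytest.fixture(scope="session")
def profile_matrix():
    ax = (np.arange(N_PX) - (N_PX - 1) / 2) * PITCH_MM
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    ref = FrameImage(open_beam_profile(MODE, np.hypot(yy, xx)), PITCH_MM, "relative")
    return build_profile_matrix(ref)


@pytest.fixture(scope="session")
def ref_fluence():
    """10x10 cm2 reference field at unit amplitude."""
    return make_field_fluence(FieldSpec("square", 10.0, mode_tag=MODE),
                              PITCH_MM, N_PX)


@pytest.fixture(scope="session")
def noisy_panel():
    return PanelModel(N_PX, N_PX, PITCH_MM, seed=7)


def build_correction_set(panel, kde, profile_matrix, *, poisson, n_frames,
                         seed=41):
    dark_st, flood_st = simulate_calibration_stacks(
        panel, kde, MODE, n_frames=n_frames, seed=seed, poisson=poisson)
    dark = build_dark_field(dark_st)
    flood = build_flood_field(flood_st, dark)
    return CorrectionSet(dark=dark, flood=flood,
                         beam_profile_matrix=profile_matrix, mode_tag=MODE)


@pytest.fixture(scope="session")
def calibrated_noiseless(kde, kpb, profile_matrix, ref_fluence, noisy_panel):
    """(panel, correction set) pair, noiseless, with F_ABS from a 100 MU reference."""
    panel = noisy_panel.noiseless()
    cs = build_correction_set(panel, kde, profile_matrix, poisson=False, n_frames=3)
    ref_stack = simulate_epid_stack(ref_fluence, kde, panel, seed=51, poisson=False)
    calibrate_absolute(ref_stack, cs, kde, kpb, MODE)
    return panel, cs


@pytest.fixture(scope="session")
def calibrated_noisy(kde, kpb, profile_matrix, ref_fluence, noisy_panel):
    """Noisy counterpart: Poisson + read noise, 300-frame calibration stacks."""
    cs = build_correction_set(noisy_panel, kde, profile_matrix,
                              poisson=True, n_frames=300)
    ref_stack = simulate_epid_stack(ref_fluence, kde, noisy_panel, seed=51)
    calibrate_absolute(ref_stack, cs, kde, kpb, MODE)
    return noisy_panel, cs
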