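"""Pixel-response calibration: dark/flood stacks -> correction set.

Simulates 300-frame beam-off (dark) and open-beam (flood) cine
acquisitions on a noisy 128x128 panel, builds the correction set, and
verifies the two fixed points of the correction: a fresh flood exposure
corrects to ~1 everywhere, a dark exposure to ~0.
"""

import numpy as np

from epid2dose import (CorrectionSet, EnergyMode, PanelModel, average_frames,
                       build_dark_field, build_flood_field,
                       build_glare_kernel, correct_raw, default_glare_params,
                       simulate_calibration_stacks)

mode = EnergyMode.MV6_WFF
panel = PanelModel(128, 128, pixel_pitch_mm=1.6, seed=7)
k_de = build_glare_kernel(default_glare_params(mode), 1.6, 24)

dark_stack, flood_stack = simulate_calibration_stacks(
    panel, k_de, mode, n_frames=300, seed=11)
dark = build_dark_field(dark_stack)
flood = build_flood_field(flood_stack, dark)
cs = CorrectionSet(dark=dark, flood=flood, mode_tag=mode)
print(f"dark level        : {dark.pixels.mean():8.2f} ADU "
      f"(panel truth {panel.dark_level_adu})")
print(f"dead pixels       : {int(cs.dead_pixel_mask.sum())}")

# a fresh, independently seeded flood acquisition must correct to unity
_, fresh = simulate_calibration_stacks(panel, k_de, mode, n_frames=300, seed=99)
corrected = correct_raw(average_frames(fresh), cs)
dev = np.abs(corrected.pixels - 1)
print(f"fresh flood -> 1  : mean dev {dev.mean():.2e}, max dev {dev.max():.2e}")

corrected_dark = correct_raw(dark, cs)
print(f"dark  -> 0        : max |value| {np.abs(corrected_dark.pixels).max():.2e}")
print("\nThe correction removes per-pixel offset and gain exactly; the ~1 % "
      "residuals on the fresh flood are the Poisson counting noise of the "
      "two finite 300-frame acquisitions, not a calibration bias.")
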