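"""Inverse chain: corrected image -> incident fluence -> water dose -> cGy.

The corrected, profile-restored EPID image is modelled as the incident
primary photon fluence blurred by the detector glare kernel,

    image = fluence (x) K_de ,

so fluence is recovered by deconvolution.  The unqualified inverse is
ill-posed (K_de has small high-frequency content), so it is realised as a
Wiener-style regularised inverse filter with a relative spectral floor:

    F_hat = I_hat . conj(H) / (|H|^2 + (eps . max|H|)^2)

computed on a reflect-padded grid and cropped back.  The fluence is then
convolved with the water pencil-beam kernel to the relative dose at d_max,

    D_w = fluence (x) K_pb ,

and scaled to absolute cGy by the per-mode calibration factor F_ABS.

The canonical order of operations is: dark/flood correction ->
beam-profile matrix -> deconvolution -> pencil-beam convolution ->
absolute scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import RegularGridInterpolator

from .calibration import (CorrectionSet, apply_beam_profile_correction,
                          compute_abs_factor, correct_raw)
from .frames import CineStack, EnergyMode, FrameImage, integrate_frames
from .kernels import Kernel

__all__ = [
    "FluenceMap",
    "DoseMap",
    "DeconvSettings",
    "deconvolve_fluence",
    "convolve_dose",
    "to_absolute",
    "cax_value",
    "output_factor",
    "resample_kernel",
    "reconstruct_relative_dose",
    "reconstruct_dose",
    "calibrate_absolute",
]

log = logging.getLogger(__name__)


@dataclass
class FluenceMap:
    """Relative primary photon fluence on the detector grid."""

    values: np.ndarray
    pixel_pitch_mm: float
    mode_tag: EnergyMode | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("fluence must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fluence values must be finite")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be positive")

    def as_frame(self, units_tag: str = "relative") -> FrameImage:
        return FrameImage(self.values, self.pixel_pitch_mm, units_tag)


@dataclass
class DoseMap:
    """Absolute 2D water dose (cGy) at depth d_max for an energy mode."""

    values: np.ndarray
    pixel_pitch_mm: float
    mode_tag: EnergyMode | None = None
    depth_cm: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("dose must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        if self.mode_tag is not None and self.depth_cm is not None:
            if not np.isclose(self.depth_cm, self.mode_tag.d_max_cm):
                raise ValueError(
                    f"depth {self.depth_cm} cm != d_max of {self.mode_tag.value}")

    def as_frame(self) -> FrameImage:
        return FrameImage(self.values, self.pixel_pitch_mm, "cGy")


@dataclass
class DeconvSettings:
    """Numerical policy of the regularised inverse filter.

    regularization_eps
        Relative spectral floor: frequencies where |H| falls below
        ``eps * max|H|`` are damped instead of amplified.  Default 1e-3.
    pad_policy, pad_width_px
        Boundary padding before the FFT (reflect by default) to keep the
        long glare tails from wrapping around; pad width must cover the
        kernel half-width (enforced at call time, where the kernel is known).
    clip_negative
        Clip noise-induced negative fluence to zero (count is logged).
    """

    regularization_eps: float = 1e-3
    pad_policy: str = "reflect"
    pad_width_px: int | None = None
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.regularization_eps < 0.5:
            raise ValueError("regularization_eps must be in (0, 0.5)")
        if self.pad_policy not in ("reflect", "zero"):
            raise ValueError("pad_policy must be 'reflect' or 'zero'")


def _check_pitch(pitch_a: float, pitch_b: float) -> None:
    if not np.isclose(pitch_a, pitch_b, rtol=1e-9):
        raise ValueError(
            f"pixel pitch mismatch ({pitch_a} vs {pitch_b} mm); resample the "
            "kernel explicitly with resample_kernel")


def _check_normalized(k: Kernel) -> None:
    if k.normalization != "sum_to_one":
        raise ValueError("kernel must be sum-normalised")


def deconvolve_fluence(img: FrameImage, k_de: Kernel,
                       settings: DeconvSettings | None = None) -> FluenceMap:
    """Recover incident fluence from a corrected image by Wiener inverse filtering."""
    settings = settings or DeconvSettings()
    _check_pitch(img.pixel_pitch_mm, k_de.pixel_pitch_mm)
    _check_normalized(k_de)
    pad = settings.pad_width_px if settings.pad_width_px is not None \
        else k_de.half_size_px
    if pad < k_de.half_size_px:
        raise ValueError("pad_width_px must be at least the kernel half-width")

    mode = "reflect" if settings.pad_policy == "reflect" else "constant"
    padded = np.pad(img.pixels, pad, mode=mode)
    if padded.shape[0] < k_de.values.shape[0] or padded.shape[1] < k_de.values.shape[1]:
        raise ValueError("kernel larger than the padded image")

    h = _otf(k_de, padded.shape)
    floor = settings.regularization_eps * np.abs(h).max()
    img_f = np.fft.fft2(padded)
    flu = np.real(np.fft.ifft2(img_f * np.conj(h) / (np.abs(h) ** 2 + floor ** 2)))
    flu = flu[pad:pad + img.n_rows, pad:pad + img.n_cols]

    if settings.clip_negative:
        n_neg = int(np.count_nonzero(flu < 0))
        if n_neg:
            log.info("deconvolution clipped %d negative pixels to 0", n_neg)
        flu = np.maximum(flu, 0.0)
    return FluenceMap(flu, img.pixel_pitch_mm)


def _otf(k: Kernel, shape: tuple[int, int]) -> np.ndarray:
    """Optical transfer function: kernel embedded at the origin of ``shape``."""
    big = np.zeros(shape)
    kh, kw = k.values.shape
    big[:kh, :kw] = k.values
    cr, cc = k.center
    big = np.roll(big, (-cr, -cc), axis=(0, 1))
    return np.fft.fft2(big)


def convolve_dose(fluence: FluenceMap, k_pb: Kernel) -> FrameImage:
    """Convolve fluence with the pencil-beam kernel: relative water dose at d_max.

    Linear (zero-padded frequency-domain) convolution; output geometry equals
    the input grid.
    """
    _check_pitch(fluence.pixel_pitch_mm, k_pb.pixel_pitch_mm)
    _check_normalized(k_pb)
    dose = signal.fftconvolve(fluence.values, k_pb.values, mode="same")
    return FrameImage(np.maximum(dose, 0.0), fluence.pixel_pitch_mm, "relative")


def to_absolute(rel_dose: FrameImage, cs: CorrectionSet, mode: EnergyMode) -> DoseMap:
    """Scale a relative dose image to absolute cGy with the mode's F_ABS."""
    if mode not in cs.f_abs:
        raise ValueError(f"correction set has no F_ABS for {mode.value}")
    return DoseMap(rel_dose.pixels * cs.f_abs[mode], rel_dose.pixel_pitch_mm,
                   mode_tag=mode, depth_cm=mode.d_max_cm)


def cax_value(d: DoseMap | FluenceMap | FrameImage, roi_px: int = 2) -> float:
    """Mean over the central (2*roi_px+1)^2 region (central-axis readout).

    For even grid dimensions the block is centred on pixel ``n // 2``
    (half a pixel off the geometric centre; negligible for the flat field
    centres this readout targets).
    """
    values = d.pixels if isinstance(d, FrameImage) else d.values
    nr, nc = values.shape
    r0, c0 = nr // 2, nc // 2
    if roi_px < 0 or r0 - roi_px < 0 or r0 + roi_px >= nr \
            or c0 - roi_px < 0 or c0 + roi_px >= nc:
        raise ValueError("ROI outside grid")
    return float(values[r0 - roi_px:r0 + roi_px + 1,
                        c0 - roi_px:c0 + roi_px + 1].mean())


def output_factor(field_dose: DoseMap | FrameImage, ref_dose: DoseMap | FrameImage,
                  roi_px: int = 2) -> float:
    """CAX dose of a field relative to the 10x10 cm2 reference field."""
    if isinstance(field_dose, DoseMap) and isinstance(ref_dose, DoseMap):
        if field_dose.mode_tag != ref_dose.mode_tag:
            raise ValueError("output factor requires matching energy modes")
    ref = cax_value(ref_dose, roi_px)
    if ref == 0:
        raise ValueError("reference CAX dose is zero")
    return cax_value(field_dose, roi_px) / ref


def resample_kernel(k: Kernel, new_pitch_mm: float) -> Kernel:
    """Resample a kernel to a new pixel pitch (bilinear) and re-normalise.

    Pitch mismatches are never resolved implicitly; call this explicitly
    when an image and a kernel were produced on different grids.
    """
    if not new_pitch_mm > 0:
        raise ValueError("new_pitch_mm must be positive")
    h = k.half_size_px
    old = np.arange(-h, h + 1) * k.pixel_pitch_mm
    extent = h * k.pixel_pitch_mm
    new_h = int(np.floor(extent / new_pitch_mm))
    new_ax = np.arange(-new_h, new_h + 1) * new_pitch_mm
    interp = RegularGridInterpolator((old, old), k.values, method="linear",
                                     bounds_error=False, fill_value=0.0)
    yy, xx = np.meshgrid(new_ax, new_ax, indexing="ij")
    vals = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(yy.shape)
    vals = np.maximum(vals, 0.0)
    vals /= vals.sum()
    return Kernel(vals, new_pitch_mm, k.kind, k.mode_tag, meta=dict(k.meta))


# ---------------------------------------------------------------------------
# end-to-end conveniences


def reconstruct_relative_dose(stack_or_img: CineStack | FrameImage,
                              cs: CorrectionSet, k_de: Kernel, k_pb: Kernel,
                              settings: DeconvSettings | None = None) -> FrameImage:
    """Run the full relative chain: integrate, correct, deconvolve, convolve."""
    if isinstance(stack_or_img, CineStack):
        img = integrate_frames(stack_or_img)
        dark_scale = float(len(stack_or_img))  # N integrated frames carry N offsets
        log.info("integrated %d cine frames", len(stack_or_img))
    else:
        img = stack_or_img
        dark_scale = 1.0
    corrected = correct_raw(img, cs, dark_scale=dark_scale)
    if cs.beam_profile_matrix is not None:
        corrected = apply_beam_profile_correction(corrected, cs)
    fluence = deconvolve_fluence(corrected, k_de, settings)
    return convolve_dose(fluence, k_pb)


def reconstruct_dose(stack_or_img: CineStack | FrameImage, cs: CorrectionSet,
                     k_de: Kernel, k_pb: Kernel, mode: EnergyMode,
                     settings: DeconvSettings | None = None) -> DoseMap:
    """Full absolute chain ending in a cGy dose map at the mode's d_max."""
    rel = reconstruct_relative_dose(stack_or_img, cs, k_de, k_pb, settings)
    dose = to_absolute(rel, cs, mode)
    log.info("absolute dose via F_ABS=%.6g (%s)", cs.f_abs[mode], mode.value)
    return dose


def calibrate_absolute(reference_stack: CineStack | FrameImage, cs: CorrectionSet,
                       k_de: Kernel, k_pb: Kernel, mode: EnergyMode,
                       delivered_dose_cGy: float = 100.0,
                       settings: DeconvSettings | None = None,
                       roi_px: int = 2) -> float:
    """Derive and store F_ABS from a reference delivery (100 MU, 10x10 cm2).

    D_EPID is the central 5x5-pixel mean of the reconstructed relative-dose
    image of the reference delivery; F_ABS = delivered dose / D_EPID is
    written into ``cs.f_abs[mode]`` and returned.
    """
    rel = reconstruct_relative_dose(reference_stack, cs, k_de, k_pb, settings)
    d_epid = cax_value(rel, roi_px)
    f = compute_abs_factor(d_epid, delivered_dose_cGy)
    cs.f_abs[mode] = f
    return f
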