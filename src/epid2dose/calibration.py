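"""Panel calibration: dark/flood correction, beam-profile matrix, dead pixels, F_ABS.

The raw cine signal of an amorphous-silicon panel carries a per-pixel dark
current offset and a per-pixel gain.  Both are calibrated from beam-off
(dark field, DF) and full-coverage open-beam (flood field, FF) stacks, and
every measured image is corrected as

    corrected = (raw - DF_mean) / (FF_mean - DF_mean)

Because the flood exposure itself contains the open-beam profile (the WFF
"horns" or the FFF cone), flood normalisation flattens that structure out
of every image; a multiplicative beam-profile matrix, built from a
reference open-beam profile (water-scan data on the real system, the
generator's analytic profile here), restores it.

An absolute calibration factor F_ABS per energy mode converts the
reconstructed relative dose to cGy.  It is defined by delivering 100 MU
(100 cGy at d_max under reference conditions, 10x10 cm2 field) and taking
F_ABS = 100 cGy / D_EPID, where D_EPID is the mean of the central 5x5
pixel region of the fully reconstructed relative-dose image of that
delivery (a small CAX ROI suppresses noise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import tifffile
from scipy.stats import median_abs_deviation

from .frames import CineStack, EnergyMode, FrameImage, average_frames

__all__ = [
    "CorrectionSet",
    "build_dark_field",
    "build_flood_field",
    "correct_raw",
    "apply_beam_profile_correction",
    "build_profile_matrix",
    "profile_matrix_from_radial",
    "detect_dead_pixels",
    "compute_abs_factor",
    "save_correction_set",
    "load_correction_set",
]

DEFAULT_K_MAD = 6.0


@dataclass
class CorrectionSet:
    """Everything needed to correct a raw image for one energy mode.

    ``f_abs`` maps :class:`EnergyMode` to the absolute calibration factor
    (cGy per corrected-integrated relative-dose unit).
    """

    dark: FrameImage
    flood: FrameImage
    beam_profile_matrix: FrameImage | None = None
    dead_pixel_mask: np.ndarray | None = None
    f_abs: dict[EnergyMode, float] = dc_field(default_factory=dict)
    mode_tag: EnergyMode | None = None
    k_mad: float = DEFAULT_K_MAD

    def __post_init__(self) -> None:
        if not self.dark.same_geometry(self.flood):
            raise ValueError("dark and flood geometry mismatch")
        if self.dead_pixel_mask is None:
            self.dead_pixel_mask = detect_dead_pixels(self.dark, self.flood, self.k_mad)
        self.dead_pixel_mask = np.asarray(self.dead_pixel_mask, dtype=bool)
        if self.dead_pixel_mask.shape != self.dark.pixels.shape:
            raise ValueError("dead_pixel_mask shape mismatch")
        live = ~self.dead_pixel_mask
        if np.any(self.flood.pixels[live] <= 0):
            bad = np.argwhere((self.flood.pixels <= 0) & live)[0]
            raise ValueError(f"flood signal non-positive at live pixel {tuple(bad)}")
        if self.beam_profile_matrix is not None:
            if not self.beam_profile_matrix.same_geometry(self.dark):
                raise ValueError("beam_profile_matrix geometry mismatch")
            if np.any(self.beam_profile_matrix.pixels <= 0):
                raise ValueError("beam_profile_matrix must be positive everywhere")
        for mode, f in self.f_abs.items():
            if not f > 0:
                raise ValueError(f"f_abs for {mode} must be positive")


def build_dark_field(stack: CineStack) -> FrameImage:
    """Average a beam-off stack into the dark-field (offset) image, in ADU.

    On the physical system a 300-frame average is used; the caller is
    responsible for the stack having been acquired beam-off.
    """
    img = average_frames(stack)
    return img.with_pixels(img.pixels, units_tag="ADU")


def build_flood_field(stack: CineStack, dark: FrameImage) -> FrameImage:
    """Average offset-corrected open-beam frames into the flood-field gain image.

    Each frame has the dark image subtracted before averaging; the result is
    the mean net flood signal (FF_mean - DF_mean in the correction equation).
    """
    if len(stack) == 0:
        raise ValueError("cannot build flood from an empty stack")
    if not stack.frames[0].same_geometry(dark):
        raise ValueError("flood stack geometry differs from dark image")
    net = stack.as_array().mean(axis=0) - dark.pixels
    return stack.frames[0].with_pixels(net, units_tag="ADU")


def detect_dead_pixels(dark: FrameImage, flood: FrameImage,
                       k_mad: float = DEFAULT_K_MAD) -> np.ndarray:
    """Flag dead/hot pixels from the calibration maps.

    A pixel is flagged when its net flood signal is non-positive, or when
    its value deviates from the map median by more than ``k_mad`` robust
    standard deviations (MAD scaled to be consistent with a Gaussian sigma)
    in either the dark or the flood map.
    """
    if not dark.same_geometry(flood):
        raise ValueError("dark/flood geometry mismatch")
    mask = flood.pixels <= 0
    for img in (dark, flood):
        v = img.pixels
        med = np.median(v)
        mad = median_abs_deviation(v, axis=None, scale="normal")
        if mad > 0:
            mask |= np.abs(v - med) > k_mad * mad
    return mask


def correct_raw(raw: FrameImage, cs: CorrectionSet, dark_scale: float = 1.0,
                ) -> FrameImage:
    """Apply the dark/flood pixel-response correction to a raw image.

    Returns ``(raw - dark_scale * dark) / flood_net`` at live pixels
    (``flood_net`` being the dark-subtracted flood average), with dead
    pixels filled by the median of their live in-grid 8-neighbours after
    correction.  Output is dimensionless (units_tag ``relative``).

    ``dark_scale`` is 1 for a single frame (the panel's per-frame offset
    correction); an image integrated over N cine frames carries N dark
    offsets, so pass ``dark_scale=N``.
    """
    if not raw.same_geometry(cs.dark):
        raise ValueError("raw image geometry differs from correction set")
    dead = cs.dead_pixel_mask
    denom = cs.flood.pixels
    live = ~dead
    if np.any(denom[live] <= 0):
        bad = np.argwhere((denom <= 0) & live)[0]
        raise ValueError(f"flood - dark non-positive at live pixel {tuple(bad)}")
    out = np.zeros_like(raw.pixels)
    out[live] = (raw.pixels[live] - dark_scale * cs.dark.pixels[live]) / denom[live]
    out = _fill_dead(out, dead)
    return raw.with_pixels(out, units_tag="relative")


def _fill_dead(values: np.ndarray, dead: np.ndarray) -> np.ndarray:
    """Replace dead pixels by the median of their live in-grid 8-neighbours."""
    if not dead.any():
        return values
    out = values.copy()
    nr, nc = values.shape
    for r, c in np.argwhere(dead):
        neigh = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and not dead[rr, cc]:
                    neigh.append(values[rr, cc])
        out[r, c] = np.median(neigh) if neigh else 0.0
    return out


def apply_beam_profile_correction(img: FrameImage, cs: CorrectionSet) -> FrameImage:
    """Multiply a corrected image by the beam-profile matrix.

    Restores the open-beam profile structure (WFF horns, FFF cone) that the
    flood normalisation removed.  The input must already be dark/flood
    corrected (relative units).
    """
    if cs.beam_profile_matrix is None:
        raise ValueError("correction set has no beam-profile matrix")
    if not img.same_geometry(cs.beam_profile_matrix):
        raise ValueError("image geometry differs from beam-profile matrix")
    return img.with_pixels(img.pixels * cs.beam_profile_matrix.pixels)


def build_profile_matrix(reference_profile_2d: FrameImage) -> FrameImage:
    """Centre-normalise a reference open-beam map into the profile matrix.

    The reference is a positive relative dose/fluence map of the open beam
    covering the panel (water-scan data on the real system).  The matrix is
    that map scaled to 1.0 at the grid centre (mean of the central 2x2
    block for even dimensions).
    """
    v = reference_profile_2d.pixels
    if np.any(v <= 0):
        raise ValueError("reference profile must be positive everywhere")
    nr, nc = v.shape
    r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0
    rlo, rhi = int(np.floor(r0)), int(np.ceil(r0))
    clo, chi = int(np.floor(c0)), int(np.ceil(c0))
    centre = v[rlo:rhi + 1, clo:chi + 1].mean()
    return reference_profile_2d.with_pixels(v / centre, units_tag="relative")


def profile_matrix_from_radial(radii_mm: np.ndarray, values: np.ndarray,
                               like: FrameImage) -> FrameImage:
    """Expand a radial open-beam profile (e.g. from a CSV scan) to a 2D matrix.

    Intended for rotationally symmetric WFF/FFF open beams; values are
    linearly interpolated in radius and centre-normalised.
    """
    radii_mm = np.asarray(radii_mm, float)
    values = np.asarray(values, float)
    if np.any(values <= 0):
        raise ValueError("radial profile values must be positive")
    yy = like.row_positions_mm()[:, None]
    xx = like.col_positions_mm()[None, :]
    r = np.hypot(yy, xx)
    v2d = np.interp(r, radii_mm, values)
    return build_profile_matrix(like.with_pixels(v2d, units_tag="relative"))


def compute_abs_factor(d_epid_reference: float, delivered_dose_cGy: float = 100.0) -> float:
    """Absolute calibration factor F_ABS = delivered dose / D_EPID.

    ``d_epid_reference`` is the CAX value of the reconstructed relative-dose
    image of the reference delivery (100 MU == 100 cGy at d_max, 10x10 cm2
    field at 100 cm source-detector distance).
    """
    if not d_epid_reference > 0:
        raise ValueError("d_epid_reference must be positive")
    if not delivered_dose_cGy > 0:
        raise ValueError("delivered_dose_cGy must be positive")
    return delivered_dose_cGy / d_epid_reference


# ---------------------------------------------------------------------------
# serialization: directory of TIFFs + meta.json


def save_correction_set(cs: CorrectionSet, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / "dark.tiff", cs.dark.pixels.astype(np.float32))
    tifffile.imwrite(d / "flood.tiff", cs.flood.pixels.astype(np.float32))
    if cs.beam_profile_matrix is not None:
        tifffile.imwrite(d / "profile_matrix.tiff",
                         cs.beam_profile_matrix.pixels.astype(np.float32))
    tifffile.imwrite(d / "dead_mask.tiff", cs.dead_pixel_mask.astype(np.uint8))
    meta = {
        "energy_mode": cs.mode_tag.value if cs.mode_tag else None,
        "f_abs": {m.value: f for m, f in cs.f_abs.items()},
        "k_mad": cs.k_mad,
        "pitch_mm": cs.dark.pixel_pitch_mm,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))


def load_correction_set(directory: str | Path) -> CorrectionSet:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    pitch = meta.get("pitch_mm", 0.2)
    dark = FrameImage(tifffile.imread(d / "dark.tiff"), pitch, "ADU")
    flood = FrameImage(tifffile.imread(d / "flood.tiff"), pitch, "ADU")
    pm_path = d / "profile_matrix.tiff"
    pm = (FrameImage(tifffile.imread(pm_path), pitch, "relative")
          if pm_path.exists() else None)
    mask = tifffile.imread(d / "dead_mask.tiff").astype(bool)
    mode = EnergyMode.parse(meta["energy_mode"]) if meta.get("energy_mode") else None
    f_abs = {EnergyMode.parse(k): float(v) for k, v in meta.get("f_abs", {}).items()}
    return CorrectionSet(dark=dark, flood=flood, beam_profile_matrix=pm,
                         dead_pixel_mask=mask, f_abs=f_abs, mode_tag=mode,
                         k_mad=meta.get("k_mad", DEFAULT_K_MAD))
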