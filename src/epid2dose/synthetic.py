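"""Forward simulator: ground-truth fluence, dose, and raw cine EPID stacks.

Every stage of the inverse pipeline is testable without measured linac
data because this module generates the whole forward chain with known
ground truth:

* field fluence maps — square / rectangular / circular / MLC-polygon
  apertures with a Gaussian penumbra, shaped by the mode's open-beam
  profile (WFF: flat centre with mild "horns"; FFF: radially decreasing
  cone) and scaled by an amplitude that encodes MU and output factor;
* a linear detector model — the ideal signal is the fluence convolved
  with the glare kernel; each cine frame adds per-pixel gain, dark offset,
  Poisson counting noise and Gaussian read noise, all seeded;
* calibration stacks (300-frame dark and flood acquisitions) and
  ground-truth water dose (fluence convolved with the pencil-beam kernel).

The detector forward model is deliberately linear-shift-invariant and
shares the glare kernel with the inverse model, so round-trip tests
isolate pipeline correctness; ``mismatch_kernel`` lets robustness tests
blur with a kernel that differs from the one used for deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter
import shapely

from .frames import CineStack, EnergyMode, FrameImage
from .kernels import Kernel
from .reconstruct import DoseMap, FluenceMap, cax_value

__all__ = [
    "FieldSpec",
    "PanelModel",
    "open_beam_profile",
    "make_field_fluence",
    "make_mlc_polygon",
    "simulate_epid_stack",
    "simulate_calibration_stacks",
    "ground_truth_dose",
    "make_synthetic_plan",
    "amplitudes_for_output_factors",
]

#: active panel area of the emulated detector, cm
PANEL_SIDE_CM = 20.48


@dataclass
class FieldSpec:
    """Specification of one delivered field.

    ``dimensions_cm`` is interpreted per shape: one side for ``square``,
    (width, height) for ``rectangle``, the diameter for ``circle``, and a
    list of (x, y) vertices in cm for ``mlc_polygon``.  ``amplitude``
    scales the fluence and encodes MU / output factor.
    """

    shape: str
    dimensions_cm: object
    penumbra_sigma_mm: float = 3.0
    amplitude: float = 1.0
    mode_tag: EnergyMode = EnergyMode.MV6_WFF

    def __post_init__(self) -> None:
        if self.shape not in ("square", "rectangle", "circle", "mlc_polygon"):
            raise ValueError(f"unknown field shape {self.shape!r}")
        if not self.penumbra_sigma_mm > 0:
            raise ValueError("penumbra_sigma_mm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.shape == "square":
            s = float(self.dimensions_cm)
            if not 2.0 <= s <= 20.0:
                raise ValueError("square side must lie in [2, 20] cm for the panel")
        elif self.shape == "rectangle":
            w, h = self.dimensions_cm
            if w <= 0 or h <= 0:
                raise ValueError("rectangle sides must be positive")
        elif self.shape == "circle":
            if not float(self.dimensions_cm) > 0:
                raise ValueError("circle diameter must be positive")


def make_mlc_polygon(vertices_cm: list[tuple[float, float]],
                     penumbra_sigma_mm: float = 3.0, amplitude: float = 1.0,
                     mode: EnergyMode = EnergyMode.MV6_WFF) -> FieldSpec:
    """Build an irregular MLC-shaped field from polygon vertices (cm).

    The polygon must be simple (non-self-intersecting) with at least three
    vertices; the aperture is its rasterisation.
    """
    if len(vertices_cm) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    poly = shapely.Polygon(vertices_cm)
    if not poly.is_valid:
        raise ValueError("self-intersecting or otherwise invalid polygon")
    return FieldSpec("mlc_polygon", list(vertices_cm), penumbra_sigma_mm,
                     amplitude, mode)


def open_beam_profile(mode: EnergyMode, r_mm: np.ndarray) -> np.ndarray:
    """Radial open-beam profile of a mode, normalised to 1 on the axis.

    WFF: flat centre with mild flattening-filter horns (~4 % at 8 cm
    off-axis, falling beyond).  FFF: forward-peaked cone, ~15 % lower at
    8 cm.  These packaged shapes stand in for water-scan data.
    """
    r = np.asarray(r_mm, float)
    if mode.has_flattening_filter:
        u = (r / 80.0) ** 2
        return 1.0 + 0.04 * u * np.exp(1.0 - u)
    return np.exp(-(r / 198.0) ** 2)


def _aperture(spec: FieldSpec, yy_cm: np.ndarray, xx_cm: np.ndarray) -> np.ndarray:
    if spec.shape == "square":
        s = float(spec.dimensions_cm) / 2
        return ((np.abs(xx_cm) <= s) & (np.abs(yy_cm) <= s)).astype(float)
    if spec.shape == "rectangle":
        w, h = spec.dimensions_cm
        return ((np.abs(xx_cm) <= w / 2) & (np.abs(yy_cm) <= h / 2)).astype(float)
    if spec.shape == "circle":
        rad = float(spec.dimensions_cm) / 2
        return (np.hypot(xx_cm, yy_cm) <= rad).astype(float)
    poly = shapely.Polygon(spec.dimensions_cm)
    inside = shapely.contains_xy(poly, xx_cm.ravel(), yy_cm.ravel())
    return inside.reshape(xx_cm.shape).astype(float)


def make_field_fluence(spec: FieldSpec, pitch_mm: float, n_px: int,
                       include_profile: bool = True) -> FluenceMap:
    """Rasterise a field into a ground-truth fluence map.

    Binary aperture, blurred with the Gaussian penumbra, multiplied by the
    mode's open-beam profile and scaled by the amplitude.
    """
    half_cm = (n_px - 1) / 2.0 * pitch_mm / 10.0
    if spec.shape == "square":
        bound = float(spec.dimensions_cm) / 2
    elif spec.shape == "rectangle":
        bound = max(spec.dimensions_cm) / 2
    elif spec.shape == "circle":
        bound = float(spec.dimensions_cm) / 2
    else:
        bound = max(max(abs(vx), abs(vy)) for vx, vy in spec.dimensions_cm)
    if bound > half_cm:
        raise ValueError(f"field exceeds the grid ({bound:.1f} cm half-extent "
                         f"vs {half_cm:.1f} cm)")
    ax_cm = (np.arange(n_px) - (n_px - 1) / 2.0) * pitch_mm / 10.0
    yy, xx = np.meshgrid(ax_cm, ax_cm, indexing="ij")
    ap = _aperture(spec, yy, xx)
    flu = gaussian_filter(ap, sigma=spec.penumbra_sigma_mm / pitch_mm,
                          mode="constant")
    if include_profile:
        flu = flu * open_beam_profile(spec.mode_tag, np.hypot(yy, xx) * 10.0)
    return FluenceMap(spec.amplitude * flu, pitch_mm, spec.mode_tag)


# ---------------------------------------------------------------------------
# detector model


@dataclass
class PanelModel:
    """Stochastic model of the flat-panel response.

    gain_sigma
        Relative spread of the per-pixel multiplicative sensitivity
        (gain map mean 1).
    dark_level_adu / dark_sigma_adu
        Mean dark current and its fixed per-pixel dispersion.
    read_noise_adu
        Gaussian read noise per frame.
    conversion_adu
        Integrated ADU per unit ideal signal over the whole delivery
        (sets the Poisson SNR: CAX SNR ~ sqrt(conversion) at amplitude 1).
    """

    n_rows: int = 128
    n_cols: int = 128
    pixel_pitch_mm: float = 1.6
    gain_sigma: float = 0.02
    dark_level_adu: float = 100.0
    dark_sigma_adu: float = 2.0
    read_noise_adu: float = 1.0
    conversion_adu: float = 10_000.0
    n_frames: int = 10
    seed: int = 0
    gain_map: np.ndarray = dc_field(init=False)
    dark_map: np.ndarray = dc_field(init=False)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.conversion_adu <= 0:
            raise ValueError("conversion_adu must be positive")
        rng = np.random.default_rng(self.seed)
        shape = (self.n_rows, self.n_cols)
        self.gain_map = 1.0 + self.gain_sigma * rng.standard_normal(shape)
        if np.any(self.gain_map <= 0):
            raise ValueError("gain map must be positive; reduce gain_sigma")
        self.dark_map = self.dark_level_adu \
            + self.dark_sigma_adu * rng.standard_normal(shape)

    def noiseless(self) -> "PanelModel":
        """Copy with Poisson and read noise off, unit gain, zero dark (same geometry)."""
        return PanelModel(self.n_rows, self.n_cols, self.pixel_pitch_mm,
                          gain_sigma=0.0, dark_level_adu=0.0, dark_sigma_adu=0.0,
                          read_noise_adu=0.0, conversion_adu=self.conversion_adu,
                          n_frames=self.n_frames, seed=self.seed)


def simulate_epid_stack(fluence: FluenceMap, k_de: Kernel, panel: PanelModel,
                        seed: int = 0, poisson: bool = True) -> CineStack:
    """Simulate a raw cine acquisition of a delivery.

    The ideal signal is ``fluence (x) K_de``; each of ``panel.n_frames``
    frames receives 1/n_frames of the counts with Poisson noise (if
    enabled), the per-pixel gain, the dark offset and Gaussian read noise.
    Deterministic for a fixed seed.
    """
    if fluence.values.shape != (panel.n_rows, panel.n_cols):
        raise ValueError("fluence grid does not match the panel")
    if not np.isclose(fluence.pixel_pitch_mm, panel.pixel_pitch_mm):
        raise ValueError("fluence pitch does not match the panel")
    if not np.isclose(fluence.pixel_pitch_mm, k_de.pixel_pitch_mm):
        raise ValueError("glare kernel pitch does not match the panel")
    ideal = signal.fftconvolve(fluence.values, k_de.values, mode="same")
    ideal = np.maximum(ideal, 0.0)
    rng = np.random.default_rng(seed)
    per_frame = ideal * (panel.conversion_adu / panel.n_frames)
    frames = []
    for _ in range(panel.n_frames):
        counts = rng.poisson(per_frame).astype(float) if poisson else per_frame
        frame = counts * panel.gain_map + panel.dark_map
        if panel.read_noise_adu > 0:
            frame = frame + panel.read_noise_adu * rng.standard_normal(ideal.shape)
        frames.append(FrameImage(frame, panel.pixel_pitch_mm, "ADU"))
    return CineStack(frames, mode_tag=fluence.mode_tag)


def simulate_calibration_stacks(panel: PanelModel, k_de: Kernel,
                                mode: EnergyMode, n_frames: int = 300,
                                seed: int = 1, poisson: bool = True,
                                include_profile: bool = True,
                                ) -> tuple[CineStack, CineStack]:
    """Simulate the beam-off dark stack and the open-beam flood stack.

    The flood beam fully covers the panel; by default it carries the mode's
    open-beam profile (as a real flood acquisition does), which is what the
    beam-profile matrix later restores.  ``include_profile=False`` gives an
    idealised flat flood.
    """
    rng = np.random.default_rng(seed)
    shape = (panel.n_rows, panel.n_cols)
    dark_frames = []
    for _ in range(n_frames):
        f = panel.dark_map.copy()
        if panel.read_noise_adu > 0:
            f = f + panel.read_noise_adu * rng.standard_normal(shape)
        dark_frames.append(FrameImage(f, panel.pixel_pitch_mm, "ADU"))
    dark_stack = CineStack(dark_frames, mode_tag=mode)

    pm = PanelModel(panel.n_rows, panel.n_cols, panel.pixel_pitch_mm,
                    panel.gain_sigma, panel.dark_level_adu, panel.dark_sigma_adu,
                    panel.read_noise_adu, panel.conversion_adu,
                    n_frames=n_frames, seed=panel.seed)
    if include_profile:
        ax_mm = (np.arange(panel.n_rows) - (panel.n_rows - 1) / 2.0) \
            * panel.pixel_pitch_mm
        yy, xx = np.meshgrid(ax_mm, ax_mm, indexing="ij")
        flood_values = open_beam_profile(mode, np.hypot(yy, xx))
    else:
        flood_values = np.ones(shape)
    flood_flu = FluenceMap(flood_values, panel.pixel_pitch_mm, mode)
    flood_stack = simulate_epid_stack(flood_flu, k_de, pm,
                                      seed=seed + 1, poisson=poisson)
    return dark_stack, flood_stack


def ground_truth_dose(fluence: FluenceMap, k_pb: Kernel,
                      dose_per_amplitude: float = 100.0) -> DoseMap:
    """Reference water dose: fluence convolved with K_pb, scaled to cGy.

    This is the comparison surface for gamma analyses and round-trip tests.
    """
    if not np.isclose(fluence.pixel_pitch_mm, k_pb.pixel_pitch_mm):
        raise ValueError("fluence and kernel pitch mismatch")
    dose = signal.fftconvolve(fluence.values, k_pb.values, mode="same")
    mode = fluence.mode_tag
    return DoseMap(np.maximum(dose, 0.0) * dose_per_amplitude,
                   fluence.pixel_pitch_mm, mode,
                   depth_cm=mode.d_max_cm if mode else None)


def make_synthetic_plan(n_segments: int, seed: int, pitch_mm: float = 1.6,
                        n_px: int = 128, mode: EnergyMode = EnergyMode.MV6_WFF,
                        ) -> tuple[list[FieldSpec], FluenceMap]:
    """Random multi-segment plan emulating an integrated dynamic delivery.

    Each segment is a random simple MLC-like polygon (a rectangle with
    jittered vertices) with a random amplitude; the composite fluence is
    the exact sum of the per-segment fluences, as a time-integrated IMRT /
    VMAT delivery is for a linear detector.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    rng = np.random.default_rng(seed)
    segments: list[FieldSpec] = []
    composite = np.zeros((n_px, n_px))
    # keep segments (plus jitter) inside the panel with a small margin
    half_cm = (n_px - 1) / 2.0 * pitch_mm / 10.0 - 0.5
    w_max = min(9.0, half_cm)
    for _ in range(n_segments):
        w = rng.uniform(3.0, w_max)
        h = rng.uniform(3.0, w_max)
        c_lim = max(half_cm - w_max / 2 - 0.4, 0.0)
        cx = rng.uniform(-c_lim, c_lim)
        cy = rng.uniform(-c_lim, c_lim)
        base = np.array([(cx - w / 2, cy - h / 2), (cx + w / 2, cy - h / 2),
                         (cx + w / 2, cy + h / 2), (cx - w / 2, cy + h / 2)])
        jitter = rng.uniform(-0.3, 0.3, base.shape)
        verts = [tuple(v) for v in base + jitter]
        poly = shapely.Polygon(verts)
        if not poly.is_valid:  # tiny jitter can in principle fold a vertex
            verts = [tuple(v) for v in base]
        spec = make_mlc_polygon(verts, penumbra_sigma_mm=3.0,
                                amplitude=float(rng.uniform(0.3, 1.0)), mode=mode)
        segments.append(spec)
        composite += make_field_fluence(spec, pitch_mm, n_px).values
    return segments, FluenceMap(composite, pitch_mm, mode)


def amplitudes_for_output_factors(sizes_cm: list[float], targets: list[float],
                                  ref_size_cm: float, k_pb: Kernel,
                                  pitch_mm: float, n_px: int,
                                  mode: EnergyMode = EnergyMode.MV6_WFF,
                                  penumbra_sigma_mm: float = 3.0) -> list[float]:
    """Amplitudes making the ground-truth CAX dose ratios equal the target OFs.

    The output factor is a CAX *dose* ratio, and the pencil-beam kernel
    makes CAX dose depend on field size (lateral scatter), so the amplitude
    of each field is the target OF divided by the field's unit-amplitude
    CAX dose relative to the reference field's.
    """
    if len(sizes_cm) != len(targets):
        raise ValueError("sizes and targets differ in length")
    ref = FieldSpec("square", ref_size_cm, penumbra_sigma_mm, 1.0, mode)
    ref_cax = cax_value(ground_truth_dose(
        make_field_fluence(ref, pitch_mm, n_px), k_pb, 1.0))
    amps = []
    for size, of in zip(sizes_cm, targets):
        spec = FieldSpec("square", size, penumbra_sigma_mm, 1.0, mode)
        cax = cax_value(ground_truth_dose(
            make_field_fluence(spec, pitch_mm, n_px), k_pb, 1.0))
        amps.append(of * ref_cax / cax)
    return amps
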