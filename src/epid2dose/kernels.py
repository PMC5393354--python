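"""Energy-specific kernels: detector glare (K_de) and water pencil-beam dose (K_pb).

Two point-response functions drive the image-to-dose conversion:

* the **glare kernel** ``K_de`` — the detector's response to a pencil of
  incident photons, dominated by optical photon spread in the Gd2O2S
  scintillator.  It is modelled parametrically as a narrow Gaussian core
  plus exponential tails (per energy mode), and is *deconvolved* from the
  corrected image to recover incident fluence;

* the **pencil-beam kernel** ``K_pb`` — the 2D dose deposited in water in a
  thin slab at depth d_max by a normally incident photon pencil beam.  It
  is generated here by a photon Monte Carlo under the kerma approximation
  (energy transferred to electrons is deposited at the interaction point),
  with Klein-Nishina Compton sampling, photoelectric absorption and pair
  production in a 30 cm water box.  Fluence *convolved* with K_pb gives the
  relative water dose.

Both kernels are sum-normalised so convolution preserves total signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import tifffile

from .frames import EnergyMode

__all__ = [
    "Kernel",
    "PhotonSpectrum",
    "CrossSectionTable",
    "GlareParams",
    "water_cross_sections",
    "default_spectrum",
    "default_glare_params",
    "build_glare_kernel",
    "generate_pencil_beam_kernel",
    "PencilBeamResult",
    "run_pencil_beam_mc",
    "sample_compton",
    "klein_nishina_total_cm2",
    "klein_nishina_pdf_cos",
    "radial_profile",
    "save_kernel",
    "load_kernel",
]

ELECTRON_REST_MEV = 0.511
PAIR_THRESHOLD_MEV = 2 * ELECTRON_REST_MEV
#: classical electron radius, cm
R_E_CM = 2.8179403262e-13
#: electrons per gram of water: N_A * (Z/A)_water
ELECTRONS_PER_G_WATER = 3.3428e23
WATER_DENSITY_G_CM3 = 1.0


# ---------------------------------------------------------------------------
# kernel container


@dataclass
class Kernel:
    """A 2D point-response function on a square pixel grid.

    ``values`` has odd dimensions ``(2h+1, 2h+1)`` with the response peak at
    the central bin (``center``).  ``normalization`` records whether the
    grid sums to one (the convention used throughout the pipeline) or peaks
    at one (display only).
    """

    values: np.ndarray
    pixel_pitch_mm: float
    kind: str  # "glare_K_de" | "pencil_beam_K_pb"
    mode_tag: EnergyMode | None = None
    normalization: str = "sum_to_one"
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("kernel must be 2D")
        if any(s % 2 == 0 for s in self.values.shape):
            raise ValueError("kernel dimensions must be odd (centred peak bin)")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("kernel values must be finite and non-negative")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if self.kind not in ("glare_K_de", "pencil_beam_K_pb"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.normalization == "sum_to_one":
            s = self.values.sum()
            if not np.isclose(s, 1.0, atol=1e-6):
                raise ValueError(f"sum_to_one kernel sums to {s}")

    @property
    def center(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)

    @property
    def half_size_px(self) -> int:
        return self.values.shape[0] // 2

    def central_fraction(self) -> float:
        """Fraction of total response in the central bin (core sharpness index)."""
        return float(self.values[self.center] / self.values.sum())


def radial_profile(k: Kernel, n_bins: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthally averaged kernel profile in equal-width annuli about the centre.

    Returns (bin-centre radius in mm, mean kernel value per annulus); empty
    annuli yield NaN.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    h = k.half_size_px
    idx = np.arange(-h, h + 1) * k.pixel_pitch_mm
    r = np.hypot(idx[:, None], idx[None, :])
    r_max = r.max() * (1 + 1e-12)
    edges = np.linspace(0.0, r_max, n_bins + 1)
    which = np.minimum((r / r_max * n_bins).astype(int), n_bins - 1)
    sums = np.bincount(which.ravel(), weights=k.values.ravel(), minlength=n_bins)
    counts = np.bincount(which.ravel(), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, mean


def save_kernel(k: Kernel, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, k.values.astype(np.float64))
    meta = {
        "kind": k.kind,
        "energy_mode": k.mode_tag.value if k.mode_tag else None,
        "pitch_mm": k.pixel_pitch_mm,
        "center": list(k.center),
        "normalization": k.normalization,
        **{kk: v for kk, v in k.meta.items()
           if isinstance(v, (int, float, str, bool, type(None)))},
    }
    (Path(str(path) + ".json")).write_text(json.dumps(meta, indent=1))


def load_kernel(path: str | Path) -> Kernel:
    path = Path(path)
    values = tifffile.imread(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    mode = EnergyMode.parse(meta["energy_mode"]) if meta.get("energy_mode") else None
    extra = {k: v for k, v in meta.items()
             if k not in ("kind", "energy_mode", "pitch_mm", "center", "normalization")}
    return Kernel(values, meta["pitch_mm"], meta["kind"], mode,
                  meta.get("normalization", "sum_to_one"), extra)


# ---------------------------------------------------------------------------
# photon spectrum


@dataclass
class PhotonSpectrum:
    """Relative photon fluence spectrum of a linac beam, binned in energy."""

    energy_bins_MeV: np.ndarray
    weights: np.ndarray
    mode_tag: EnergyMode | None = None

    def __post_init__(self) -> None:
        self.energy_bins_MeV = np.asarray(self.energy_bins_MeV, float)
        self.weights = np.asarray(self.weights, float)
        if self.energy_bins_MeV.size == 0:
            raise ValueError("spectrum is empty")
        if self.energy_bins_MeV.size != self.weights.size:
            raise ValueError("energy bins and weights differ in length")
        if np.any(np.diff(self.energy_bins_MeV) <= 0):
            raise ValueError("energy bins must be strictly ascending")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        e = self.energy_bins_MeV
        if e.min() <= 0.01 or e.max() >= 20:
            raise ValueError("energies must lie within (0.01, 20) MeV")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights sum to zero")
        self.weights = self.weights / total

    def mean_energy_MeV(self) -> float:
        return float(np.sum(self.energy_bins_MeV * self.weights))

    @classmethod
    def monoenergetic(cls, energy_MeV: float,
                      mode: EnergyMode | None = None) -> "PhotonSpectrum":
        return cls(np.array([energy_MeV]), np.array([1.0]), mode)


#: bremsstrahlung shape exponent: weights ~ E^a * (E_max - E).  FFF beams,
#: having no flattening filter to harden them, are softer (more negative a).
_SPECTRUM_SHAPE_A = {True: 0.0, False: -0.6}  # key: has_flattening_filter
_SPECTRUM_E_MIN_MEV = 0.25
_SPECTRUM_N_BINS = 30


def default_spectrum(mode: EnergyMode) -> PhotonSpectrum:
    """Representative bremsstrahlung-shaped spectrum for an energy mode.

    Shape ``w(E) ~ E^a (E_max - E)`` between 0.25 MeV and the nominal
    accelerating potential, giving a mean energy of roughly one third of
    nominal; FFF modes use a softer exponent than WFF modes at the same
    nominal energy.
    """
    e_max = mode.nominal_mv
    a = _SPECTRUM_SHAPE_A[mode.has_flattening_filter]
    edges = np.linspace(_SPECTRUM_E_MIN_MEV, e_max, _SPECTRUM_N_BINS + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    w = centres ** a * (e_max - centres)
    return PhotonSpectrum(centres, w, mode)


# ---------------------------------------------------------------------------
# water cross sections


@dataclass
class CrossSectionTable:
    """Mass attenuation coefficients of water (cm^2/g) on a log energy grid.

    Partial coefficients for Compton (incoherent) scattering, photoelectric
    absorption and pair production; ``total`` is their sum (coherent
    scattering is excluded by design — a < 5 % effect above 100 keV).
    Interpolation is log-log for the strictly positive channels and linear
    for pair production (which is zero below its 1.022 MeV threshold).
    """

    energy_MeV: np.ndarray
    compton: np.ndarray
    photoelectric: np.ndarray
    pair: np.ndarray
    density_g_cm3: float = WATER_DENSITY_G_CM3

    def __post_init__(self) -> None:
        for name in ("compton", "photoelectric", "pair"):
            arr = np.asarray(getattr(self, name), float)
            setattr(self, name, arr)
            if np.any(arr < 0):
                raise ValueError(f"{name} coefficients must be non-negative")
        self.energy_MeV = np.asarray(self.energy_MeV, float)

    @property
    def total(self) -> np.ndarray:
        return self.compton + self.photoelectric + self.pair

    def _loglog(self, table: np.ndarray, e: np.ndarray) -> np.ndarray:
        return np.exp(np.interp(np.log(e), np.log(self.energy_MeV),
                                np.log(np.maximum(table, 1e-300))))

    def mu_total_cm(self, e: np.ndarray) -> np.ndarray:
        """Total linear attenuation coefficient (1/cm) at energy e (MeV)."""
        e = np.asarray(e, float)
        mu = (self._loglog(self.compton, e) + self._loglog(self.photoelectric, e)
              + np.interp(e, self.energy_MeV, self.pair))
        return mu * self.density_g_cm3

    def channel_fractions(self, e: np.ndarray) -> np.ndarray:
        """Interaction probabilities (compton, photoelectric, pair) at e, shape (n, 3)."""
        e = np.asarray(e, float)
        parts = np.stack([
            self._loglog(self.compton, e),
            self._loglog(self.photoelectric, e),
            np.interp(e, self.energy_MeV, self.pair),
        ], axis=-1)
        return parts / parts.sum(axis=-1, keepdims=True)


def klein_nishina_total_cm2(e_MeV: np.ndarray) -> np.ndarray:
    """Klein-Nishina total Compton cross section per electron (cm^2)."""
    k = np.asarray(e_MeV, float) / ELECTRON_REST_MEV
    t = np.log1p(2 * k)
    sigma = (2 * np.pi * R_E_CM ** 2
             * ((1 + k) / k ** 2 * (2 * (1 + k) / (1 + 2 * k) - t / k)
                + t / (2 * k) - (1 + 3 * k) / (1 + 2 * k) ** 2))
    return sigma


def klein_nishina_pdf_cos(cos_theta: np.ndarray, e_MeV: float) -> np.ndarray:
    """Unnormalised Klein-Nishina density in cos(theta) of the scattered photon."""
    k = e_MeV / ELECTRON_REST_MEV
    eta = 1 + k * (1 - cos_theta)  # E / E'
    sin2 = 1 - cos_theta ** 2
    return (1 / eta ** 2) * (eta + 1 / eta - sin2)


# photoelectric fit for water (tau/rho ~ 4.9 (E/10 keV)^-3.1 cm^2/g) and
# pair-production anchors (nuclear + electron field, cm^2/g), approximate
# magnitudes for liquid water above threshold
_PAIR_ANCHORS_MEV = np.array([PAIR_THRESHOLD_MEV, 1.25, 1.5, 2.0, 3.0, 4.0,
                              5.0, 6.0, 8.0, 10.0, 15.0, 20.0])
_PAIR_ANCHORS_CM2G = np.array([0.0, 2.0e-5, 7.7e-5, 3.9e-4, 1.13e-3, 1.8e-3,
                               2.4e-3, 2.9e-3, 3.9e-3, 4.7e-3, 6.4e-3, 7.7e-3])


def water_cross_sections(n_energies: int = 40) -> CrossSectionTable:
    """Build the packaged water attenuation table on a log grid, 0.01-20 MeV.

    Compton from the closed-form Klein-Nishina total cross section times the
    electron density of water; photoelectric from a power-law fit (monotone
    decreasing); pair production interpolated from anchor values above its
    threshold.
    """
    e = np.geomspace(0.0101, 19.9, n_energies)
    compton = klein_nishina_total_cm2(e) * ELECTRONS_PER_G_WATER
    photoelectric = 4.9 * (e / 0.01) ** -3.1
    pair = np.interp(e, _PAIR_ANCHORS_MEV, _PAIR_ANCHORS_CM2G, left=0.0)
    return CrossSectionTable(e, compton, photoelectric, pair)


# ---------------------------------------------------------------------------
# glare kernel (parametric)


@dataclass
class GlareParams:
    """Parameters of the radial glare model: Gaussian core + exponential tails.

    ``tail_components`` is a list of ``(weight, scale_mm)`` pairs; all
    weights (core + tails) must sum to 1, and the core must be narrower
    than every tail.
    """

    core_weight: float
    core_sigma_mm: float
    tail_components: list[tuple[float, float]]
    mode_tag: EnergyMode | None = None

    def __post_init__(self) -> None:
        weights = [self.core_weight] + [w for w, _ in self.tail_components]
        if any(w <= 0 for w in weights):
            raise ValueError("all component weights must be positive")
        if not np.isclose(sum(weights), 1.0, atol=1e-9):
            raise ValueError(f"component weights must sum to 1, got {sum(weights)}")
        if self.core_sigma_mm <= 0 or any(s <= 0 for _, s in self.tail_components):
            raise ValueError("scales must be positive")
        if self.tail_components and self.core_sigma_mm >= min(
                s for _, s in self.tail_components):
            raise ValueError("core sigma must be smaller than every tail scale")

    def radial_density(self, r_mm: np.ndarray) -> np.ndarray:
        """Continuous 2D density (per mm^2) at radius r; integrates to 1 over the plane."""
        r = np.asarray(r_mm, float)
        out = (self.core_weight / (2 * np.pi * self.core_sigma_mm ** 2)
               * np.exp(-0.5 * (r / self.core_sigma_mm) ** 2))
        for w, s in self.tail_components:
            out = out + w / (2 * np.pi * s ** 2) * np.exp(-r / s)
        return out


#: packaged per-mode glare defaults.  Optical spread in the scintillator is
#: sub-millimetre for most of the light, with few-percent long-range tails
#: from optical scatter and in-panel photon scatter; higher-energy beams
#: deposit slightly deeper and glare slightly more.
_GLARE_DEFAULTS: dict[EnergyMode, GlareParams] = {
    EnergyMode.MV6_WFF: GlareParams(0.94, 0.35, [(0.04, 2.5), (0.02, 12.0)],
                                    EnergyMode.MV6_WFF),
    EnergyMode.MV10_WFF: GlareParams(0.93, 0.38, [(0.045, 3.0), (0.025, 14.0)],
                                     EnergyMode.MV10_WFF),
    EnergyMode.MV15_WFF: GlareParams(0.92, 0.40, [(0.05, 3.5), (0.03, 16.0)],
                                     EnergyMode.MV15_WFF),
    EnergyMode.MV6_FFF: GlareParams(0.945, 0.34, [(0.038, 2.4), (0.017, 11.0)],
                                    EnergyMode.MV6_FFF),
    EnergyMode.MV10_FFF: GlareParams(0.935, 0.37, [(0.043, 2.9), (0.022, 13.0)],
                                     EnergyMode.MV10_FFF),
}


def default_glare_params(mode: EnergyMode) -> GlareParams:
    return _GLARE_DEFAULTS[mode]


def build_glare_kernel(params: GlareParams, pitch_mm: float,
                       half_size_px: int = 32) -> Kernel:
    """Discretise the parametric glare model onto a pixel grid.

    The continuous radial density is evaluated at bin centres, multiplied by
    the pixel area and sum-normalised.  The result is monotone
    non-increasing in radius by construction.
    """
    if half_size_px < 8:
        raise ValueError("half_size_px must be >= 8")
    idx = np.arange(-half_size_px, half_size_px + 1) * pitch_mm
    r = np.hypot(idx[:, None], idx[None, :])
    values = params.radial_density(r) * pitch_mm ** 2
    values /= values.sum()
    return Kernel(values, pitch_mm, "glare_K_de", params.mode_tag,
                  meta={"core_sigma_mm": params.core_sigma_mm,
                        "core_weight": params.core_weight})


# ---------------------------------------------------------------------------
# pencil-beam Monte Carlo


@dataclass
class PencilBeamResult:
    """Raw output of the pencil-beam Monte Carlo before kernel normalisation.

    ``tally_MeV`` is the 2D energy deposited (MeV) in the scoring slab;
    ``rel_uncertainty`` the per-bin relative statistical uncertainty from
    batch statistics (NaN where nothing was scored).  The energy ledger
    (``launched/deposited/escaped_MeV``) covers the whole 30 cm box, not
    just the scoring slab, and closes to float precision by construction.
    ``primary_transmission`` is the fraction of launched photons that
    reached the scoring depth without interacting (expectation
    ``sum_E w(E) exp(-mu(E) d)``).
    """

    tally_MeV: np.ndarray
    rel_uncertainty: np.ndarray
    launched_MeV: float
    deposited_MeV: float
    escaped_MeV: float
    primary_transmission: float
    n_histories: int
    pitch_mm: float
    depth_cm: float


#: geometry of the water box (semi-infinite phantom approximation)
BOX_HALF_CM = 15.0
BOX_DEPTH_CM = 30.0
SLAB_THICKNESS_CM = 0.2
ENERGY_CUTOFF_MEV = 0.02


def _rotate_directions(d: np.ndarray, cos_t: np.ndarray, rng: np.random.Generator,
                       ) -> np.ndarray:
    """Rotate unit vectors ``d`` by polar angle acos(cos_t), uniform azimuth."""
    n = d.shape[0]
    sin_t = np.sqrt(np.maximum(0.0, 1 - cos_t ** 2))
    phi = rng.uniform(0, 2 * np.pi, n)
    # orthonormal frame (u, v, d); avoid degeneracy for d near +/-z
    near_z = np.abs(d[:, 2]) > 0.99
    a = np.where(near_z[:, None], np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]))
    u = np.cross(a, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    new = (sin_t * np.cos(phi))[:, None] * u + (sin_t * np.sin(phi))[:, None] * v \
        + cos_t[:, None] * d
    return new / np.linalg.norm(new, axis=1, keepdims=True)


def sample_compton(e_MeV: np.ndarray, rng: np.random.Generator,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sample Compton scattering from the Klein-Nishina distribution (Kahn's method).

    Returns ``(e_out_MeV, cos_theta)`` of the scattered photon for each
    incident energy.
    """
    e = np.atleast_1d(np.asarray(e_MeV, float))
    k = e / ELECTRON_REST_MEV
    eta = np.empty_like(e)
    pending = np.arange(e.size)
    while pending.size:
        kp = k[pending]
        r1, r2, r3 = rng.random((3, pending.size))
        take_a = r1 <= (2 * kp + 1) / (2 * kp + 9)
        eta_try = np.where(take_a, 1 + 2 * kp * r2, (1 + 2 * kp) / (1 + 2 * kp * r2))
        cos_try = 1 - (eta_try - 1) / kp
        acc_a = take_a & (r3 <= 4 * (1 / eta_try - 1 / eta_try ** 2))
        acc_b = (~take_a) & (r3 <= 0.5 * (cos_try ** 2 + 1 / eta_try))
        acc = acc_a | acc_b
        eta[pending[acc]] = eta_try[acc]
        pending = pending[~acc]
    cos_theta = 1 - (eta - 1) / k
    return e / eta, np.clip(cos_theta, -1.0, 1.0)


def _transport_batch(e0: np.ndarray, xs: CrossSectionTable, depth_cm: float,
                     pitch_cm: float, half: int, rng: np.random.Generator,
                     ) -> tuple[np.ndarray, float, float, float, int]:
    """Track one batch of pencil-beam photons; returns (tally, launched,
    deposited, escaped, n_primary_crossings)."""
    n = e0.size
    size = 2 * half + 1
    tally = np.zeros((size, size))
    launched = float(e0.sum())
    deposited = 0.0
    escaped = 0.0
    n_primary = 0

    pos = np.zeros((n, 3))
    dirn = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
    e = e0.copy()
    primary = np.ones(n, bool)
    pending_pos: list[np.ndarray] = []
    pending_e: list[np.ndarray] = []

    z_lo, z_hi = depth_cm - SLAB_THICKNESS_CM / 2, depth_cm + SLAB_THICKNESS_CM / 2

    def score(p: np.ndarray, de: np.ndarray) -> None:
        nonlocal deposited
        deposited += float(de.sum())
        in_slab = (p[:, 2] >= z_lo) & (p[:, 2] < z_hi)
        if not in_slab.any():
            return
        i = np.round(p[in_slab, 0] / pitch_cm).astype(int) + half
        j = np.round(p[in_slab, 1] / pitch_cm).astype(int) + half
        ok = (i >= 0) & (i < size) & (j >= 0) & (j < size)
        np.add.at(tally, (j[ok], i[ok]), de[in_slab][ok])

    while e.size or pending_pos:
        if not e.size:
            pos = np.concatenate(pending_pos)
            e = np.concatenate(pending_e)
            m = e.size
            # isotropic secondaries (annihilation quanta)
            cos_t = rng.uniform(-1, 1, m)
            phi = rng.uniform(0, 2 * np.pi, m)
            sin_t = np.sqrt(1 - cos_t ** 2)
            dirn = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)
            primary = np.zeros(m, bool)
            pending_pos, pending_e = [], []

        mu = xs.mu_total_cm(e)
        step = rng.exponential(1.0 / mu)
        new_pos = pos + dirn * step[:, None]

        crossed = primary & (pos[:, 2] < depth_cm) & (new_pos[:, 2] >= depth_cm)
        n_primary += int(crossed.sum())

        out = ((np.abs(new_pos[:, 0]) > BOX_HALF_CM)
               | (np.abs(new_pos[:, 1]) > BOX_HALF_CM)
               | (new_pos[:, 2] < 0) | (new_pos[:, 2] > BOX_DEPTH_CM))
        escaped += float(e[out].sum())

        pos, dirn, e, primary = new_pos[~out], dirn[~out], e[~out], primary[~out]
        if not e.size:
            continue

        frac = xs.channel_fractions(e)
        u = rng.random(e.size)
        is_pair = (u >= frac[:, 0] + frac[:, 1]) & (e > PAIR_THRESHOLD_MEV)
        is_pe = (u >= frac[:, 0]) & ~is_pair
        is_co = ~is_pe & ~is_pair

        if is_pe.any():
            score(pos[is_pe], e[is_pe])
        if is_pair.any():
            score(pos[is_pair], e[is_pair] - PAIR_THRESHOLD_MEV)
            p2 = np.repeat(pos[is_pair], 2, axis=0)
            pending_pos.append(p2)
            pending_e.append(np.full(p2.shape[0], ELECTRON_REST_MEV))
        if is_co.any():
            e_out, cos_t = sample_compton(e[is_co], rng)
            score(pos[is_co], e[is_co] - e_out)
            dir_co = _rotate_directions(dirn[is_co], cos_t, rng)
            low = e_out < ENERGY_CUTOFF_MEV
            if low.any():
                score(pos[is_co][low], e_out[low])
            keep = ~low
            pos, dirn, e = pos[is_co][keep], dir_co[keep], e_out[keep]
            primary = np.zeros(e.size, bool)
        else:
            pos = np.empty((0, 3)); dirn = np.empty((0, 3))
            e = np.empty(0); primary = np.empty(0, bool)

    return tally, launched, deposited, escaped, n_primary


def run_pencil_beam_mc(spectrum: PhotonSpectrum, xs: CrossSectionTable,
                       depth_cm: float, pitch_mm: float, half_size_px: int,
                       n_histories: int, seed: int, n_batches: int = 25,
                       ) -> PencilBeamResult:
    """Run the kerma-approximation pencil-beam Monte Carlo.

    A normally incident photon pencil enters a 30x30x30 cm water box at the
    origin.  Free paths are sampled from the total attenuation coefficient;
    at each interaction the channel (Compton / photoelectric / pair) is
    chosen from the partial coefficients, energy transferred to electrons
    is deposited at the interaction point (kerma approximation), and
    surviving photons are tracked until absorption, energy cutoff or escape.
    Dose is tallied on a 2D grid in a 2 mm slab centred at ``depth_cm``.
    Per-bin uncertainty comes from batch statistics over ``n_batches``
    equal batches; results are bit-reproducible for a given seed.
    """
    if n_histories < 10_000:
        raise ValueError("n_histories must be >= 1e4")
    if not 0 < depth_cm < BOX_DEPTH_CM:
        raise ValueError("depth beyond slab extent")
    rng = np.random.default_rng(seed)
    pitch_cm = pitch_mm / 10.0
    per_batch = n_histories // n_batches
    size = 2 * half_size_px + 1
    batch_tallies = np.zeros((n_batches, size, size))
    launched = deposited = escaped = 0.0
    n_primary = 0
    for b in range(n_batches):
        e0 = rng.choice(spectrum.energy_bins_MeV, size=per_batch, p=spectrum.weights)
        t, la, de, es, npri = _transport_batch(e0, xs, depth_cm, pitch_cm,
                                               half_size_px, rng)
        batch_tallies[b] = t
        launched += la; deposited += de; escaped += es; n_primary += npri

    tally = batch_tallies.sum(axis=0)
    mean_b = batch_tallies.mean(axis=0)
    var_b = batch_tallies.var(axis=0, ddof=1) / n_batches
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_unc = np.where(mean_b > 0, np.sqrt(var_b) / mean_b, np.nan)
    return PencilBeamResult(
        tally_MeV=tally, rel_uncertainty=rel_unc,
        launched_MeV=launched, deposited_MeV=deposited, escaped_MeV=escaped,
        primary_transmission=n_primary / (per_batch * n_batches),
        n_histories=per_batch * n_batches, pitch_mm=pitch_mm, depth_cm=depth_cm)


def generate_pencil_beam_kernel(spectrum: PhotonSpectrum, xs: CrossSectionTable,
                                depth_cm: float, pitch_mm: float,
                                half_size_px: int, n_histories: int,
                                seed: int) -> Kernel:
    """Monte-Carlo generate the sum-normalised water pencil-beam dose kernel.

    ``depth_cm`` should be the d_max of the energy mode.  The per-bin
    statistical uncertainty, energy ledger and RNG seed are recorded in
    ``Kernel.meta`` (the array under ``"rel_uncertainty"``).
    """
    res = run_pencil_beam_mc(spectrum, xs, depth_cm, pitch_mm, half_size_px,
                             n_histories, seed)
    total = res.tally_MeV.sum()
    if total <= 0:
        raise ValueError("no energy tallied in the scoring slab")
    values = res.tally_MeV / total
    meta = {
        "n_histories": res.n_histories,
        "seed": seed,
        "depth_cm": depth_cm,
        "launched_MeV": res.launched_MeV,
        "deposited_MeV": res.deposited_MeV,
        "escaped_MeV": res.escaped_MeV,
        "primary_transmission": res.primary_transmission,
        "rel_uncertainty": res.rel_uncertainty,
    }
    return Kernel(values, pitch_mm, "pencil_beam_K_pb", spectrum.mode_tag, meta=meta)
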