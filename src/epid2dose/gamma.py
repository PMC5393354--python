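"""2D gamma-index comparison of dose distributions.

The gamma index combines a dose-difference criterion (as a percentage of
the *global* maximum of the reference distribution) with a
distance-to-agreement (DTA) criterion.  For an evaluated point r_e,

    gamma(r_e) = min over r_r of sqrt( |r_e - r_r|^2 / dta^2
                                     + (D_e(r_e) - D_r(r_r))^2 / dD^2 )

with dD = dose_diff_pct/100 * max(D_r).  A point passes when gamma <= 1.
Only evaluated points with dose above a low-dose threshold (default 10 %
of the reference maximum) enter the pass rate.

The reference is bilinearly upsampled (default x4) for subpixel DTA and
searched over a disk of offsets.  The disk starts at
``search_radius_factor * dta`` and is expanded automatically for pixels
whose current minimum exceeds the radius guarantee (any candidate beyond
radius R has gamma >= R/dta), so the result equals an exhaustive search
over the whole upsampled grid.  Comparison is performed on the evaluated
grid; the two grids may have different pitches (e.g. a 10 mm ion-chamber
array versus a 0.2 mm EPID grid) and are aligned on their geometric
centres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .reconstruct import DoseMap
from .frames import FrameImage

__all__ = ["GammaCriteria", "GammaResult", "gamma_index", "gamma_report"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GammaCriteria:
    """Criteria of a gamma comparison, e.g. ``GammaCriteria(3, 3)`` for 3%/3mm."""

    dose_diff_pct: float
    dta_mm: float
    threshold_frac: float = 0.10
    search_radius_factor: float = 3.0
    interp_factor: int = 4

    def __post_init__(self) -> None:
        if self.dose_diff_pct <= 0 or self.dta_mm <= 0:
            raise ValueError("dose_diff_pct and dta_mm must be positive")
        if not 0 <= self.threshold_frac < 1:
            raise ValueError("threshold_frac must be in [0, 1)")
        if self.search_radius_factor <= 0:
            raise ValueError("search_radius_factor must be positive")
        if int(self.interp_factor) != self.interp_factor or self.interp_factor < 1:
            raise ValueError("interp_factor must be an integer >= 1")

    @property
    def label(self) -> str:
        def fmt(x: float) -> str:
            return f"{x:g}"
        return f"{fmt(self.dose_diff_pct)}%/{fmt(self.dta_mm)}mm"


@dataclass
class GammaResult:
    """Per-pixel gamma map, evaluated mask and pass rate of one comparison."""

    gamma_map: np.ndarray
    evaluated_mask: np.ndarray
    pass_rate_pct: float
    criteria: GammaCriteria

    def __post_init__(self) -> None:
        if not 0 <= self.pass_rate_pct <= 100:
            raise ValueError("pass_rate_pct out of range")


def _grid_positions(values: np.ndarray, pitch_mm: float,
                    ) -> tuple[np.ndarray, np.ndarray]:
    nr, nc = values.shape
    y = (np.arange(nr) - (nr - 1) / 2.0) * pitch_mm
    x = (np.arange(nc) - (nc - 1) / 2.0) * pitch_mm
    return y, x


def _values_pitch(d) -> tuple[np.ndarray, float]:
    if isinstance(d, FrameImage):
        return d.pixels, d.pixel_pitch_mm
    return d.values, d.pixel_pitch_mm


def _upsample(values: np.ndarray, y: np.ndarray, x: np.ndarray, factor: int,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bilinear upsample preserving the original sample positions."""
    if factor == 1:
        return values, y, x
    yf = np.linspace(y[0], y[-1], (y.size - 1) * factor + 1)
    xf = np.linspace(x[0], x[-1], (x.size - 1) * factor + 1)
    interp = RegularGridInterpolator((y, x), values, method="linear")
    yy, xx = np.meshgrid(yf, xf, indexing="ij")
    fine = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(yy.shape)
    return fine, yf, xf


def gamma_index(eval_dose: DoseMap | FrameImage, ref_dose: DoseMap | FrameImage,
                crit: GammaCriteria) -> GammaResult:
    """Compute the per-pixel gamma map of ``eval_dose`` against ``ref_dose``."""
    ev, ev_pitch = _values_pitch(eval_dose)
    rf, rf_pitch = _values_pitch(ref_dose)
    ref_max = rf.max()
    if ref_max <= 0:
        raise ValueError("reference maximum must be positive")
    d_norm = crit.dose_diff_pct / 100.0 * ref_max

    y_r, x_r = _grid_positions(rf, rf_pitch)
    fine, yf, xf = _upsample(rf, y_r, x_r, crit.interp_factor)
    hf = rf_pitch / crit.interp_factor
    if yf[0] > (_grid_positions(ev, ev_pitch)[0][-1]) or \
       yf[-1] < (_grid_positions(ev, ev_pitch)[0][0]):
        raise ValueError("dose grids do not overlap")

    y_e, x_e = _grid_positions(ev, ev_pitch)
    mask = ev > crit.threshold_frac * ref_max
    pr, pc = np.nonzero(mask)
    de = ev[pr, pc]
    py, px = y_e[pr], x_e[pc]

    # nearest fine-grid node and subpixel residual for each evaluated point
    i0 = np.round((py - yf[0]) / hf).astype(int)
    j0 = np.round((px - xf[0]) / hf).astype(int)
    # clamp so residuals stay meaningful for points just off the ref extent
    i0c = np.clip(i0, 0, yf.size - 1)
    j0c = np.clip(j0, 0, xf.size - 1)
    ry = yf[i0c] - py
    rx = xf[j0c] - px

    n = de.size
    best = np.full(n, np.inf)
    any_valid = np.zeros(n, bool)
    max_r = float(np.hypot(yf[-1] - yf[0], xf[-1] - xf[0])) + \
        float(np.hypot(ry, rx).max(initial=0.0)) + hf

    radius = crit.search_radius_factor * crit.dta_mm
    prev_radius2 = -1.0  # squared radius already searched; negative: none
    active = np.arange(n)
    while active.size:
        m = int(np.ceil(radius / hf))
        offs = np.arange(-m, m + 1)
        for di in offs:
            ii = i0c[active] + di
            ok_i = (ii >= 0) & (ii < yf.size)
            dy = ry[active] + di * hf
            for dj in offs:
                dist2 = dy ** 2 + (rx[active] + dj * hf) ** 2
                in_prev = dist2 <= prev_radius2
                jj = j0c[active] + dj
                ok = ok_i & (jj >= 0) & (jj < xf.size) & (dist2 <= radius ** 2) \
                    & ~in_prev
                if not ok.any():
                    continue
                idx = active[ok]
                g2 = dist2[ok] / crit.dta_mm ** 2 + \
                    (de[idx] - fine[ii[ok], jj[ok]]) ** 2 / d_norm ** 2
                np.minimum.at(best, idx, g2)
                any_valid[idx] = True
        gam = np.sqrt(best[active])
        unresolved = any_valid[active] & (gam > radius / crit.dta_mm)
        no_candidate = ~any_valid[active]
        if radius >= max_r:
            break
        active = active[unresolved | no_candidate]
        prev_radius2 = radius ** 2
        radius = min(radius * 2, max_r)

    gamma_map = np.full(ev.shape, np.nan)
    valid = any_valid
    gamma_map[pr[valid], pc[valid]] = np.sqrt(best[valid])
    n_dropped = int((~valid).sum())
    if n_dropped:
        log.info("%d above-threshold pixels had no reference candidates "
                 "(outside overlap); excluded", n_dropped)

    evaluated = np.zeros(ev.shape, bool)
    evaluated[pr[valid], pc[valid]] = True
    n_eval = int(evaluated.sum())
    passed = int(np.count_nonzero(gamma_map[evaluated] <= 1.0))
    pass_rate = 100.0 * passed / n_eval if n_eval else 0.0
    return GammaResult(gamma_map, evaluated, pass_rate, crit)


def gamma_report(results: list[GammaResult], label: str = "") -> pd.DataFrame:
    """Tabulate pass rates per criterion (one row per comparison label layout)."""
    rows = [{"label": label, "criterion": r.criteria.label,
             "pass_rate_pct": r.pass_rate_pct,
             "n_evaluated": int(r.evaluated_mask.sum())} for r in results]
    return pd.DataFrame(rows)
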