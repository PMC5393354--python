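"""Detector frame data model and cine-stack I/O.

A flat-panel EPID operated in cine mode delivers an ordered stack of 2D
frames recorded over the whole beam-on time.  This module holds the grid
data model shared by every stage of the pipeline (:class:`FrameImage`,
:class:`CineStack`, :class:`EnergyMode`), the frame arithmetic used to
build integrated/averaged images, 1D profile extraction, and readers and
writers for multi-page TIFF stacks and headerless raw binary dumps with a
JSON sidecar.

Grid convention
---------------
Positions are expressed in millimetres relative to the grid centre.  For a
grid with ``n`` pixels along an axis the centre sits at index ``(n-1)/2``:
for odd ``n`` that is a pixel centre, for even ``n`` the midpoint between
the two central pixels.  Every operation in this module preserves geometry
(pixel pitch and dimensions).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "EnergyMode",
    "FrameImage",
    "CineStack",
    "average_frames",
    "integrate_frames",
    "extract_profile",
    "read_stack",
    "write_stack",
    "profile_to_csv",
]

#: default panel geometry: 1024 x 1024 pixels at 0.2 mm pitch (20.48 cm square)
DEFAULT_PITCH_MM = 0.2
DEFAULT_PANEL_PX = 1024
MAX_FRAME_RATE_FPS = 50.0


class EnergyMode(enum.Enum):
    """Photon energy mode of a C-arm linac, with or without flattening filter.

    The depth of dose maximum ``d_max`` in water is the plane at which
    absolute dose is reconstructed: 1.5 cm for 6 MV (WFF and FFF), 2.5 cm
    for 10 MV (WFF and FFF), 3.0 cm for 15 MV.
    """

    MV6_WFF = "6MV_WFF"
    MV10_WFF = "10MV_WFF"
    MV15_WFF = "15MV_WFF"
    MV6_FFF = "6MV_FFF"
    MV10_FFF = "10MV_FFF"

    @property
    def d_max_cm(self) -> float:
        return _D_MAX_CM[self]

    @property
    def has_flattening_filter(self) -> bool:
        return self.value.endswith("WFF")

    @property
    def nominal_mv(self) -> float:
        """Nominal accelerating potential in MV (maximum photon energy in MeV)."""
        return float(self.value.split("MV")[0])

    @classmethod
    def parse(cls, name: str) -> "EnergyMode":
        for m in cls:
            if m.value == name or m.name == name:
                return m
        raise ValueError(f"unknown energy mode {name!r}; expected one of "
                         f"{[m.value for m in cls]}")


_D_MAX_CM = {
    EnergyMode.MV6_WFF: 1.5,
    EnergyMode.MV6_FFF: 1.5,
    EnergyMode.MV10_WFF: 2.5,
    EnergyMode.MV10_FFF: 2.5,
    EnergyMode.MV15_WFF: 3.0,
}

#: valid unit tags for a FrameImage
UNITS = ("ADU", "relative", "cGy")


@dataclass
class FrameImage:
    """One 2D detector or dose grid.

    Parameters
    ----------
    pixels
        2D array of values.  Detector counts (ADU) for raw frames,
        dimensionless after flood/dark correction, cGy for dose maps.
    pixel_pitch_mm
        Pixel spacing in mm (0.2 mm for the physical panel).
    units_tag
        One of ``"ADU"``, ``"relative"``, ``"cGy"``.
    """

    pixels: np.ndarray
    pixel_pitch_mm: float = DEFAULT_PITCH_MM
    units_tag: str = "ADU"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError(f"grid must be at least 8x8, got {self.pixels.shape}")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        if self.units_tag not in UNITS:
            raise ValueError(f"units_tag must be one of {UNITS}")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    def row_positions_mm(self) -> np.ndarray:
        """Row-centre positions in mm relative to the grid centre (in-plane axis)."""
        return (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * self.pixel_pitch_mm

    def col_positions_mm(self) -> np.ndarray:
        """Column-centre positions in mm relative to the grid centre (cross-plane axis)."""
        return (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.pixel_pitch_mm

    def same_geometry(self, other: "FrameImage") -> bool:
        return (self.pixels.shape == other.pixels.shape
                and np.isclose(self.pixel_pitch_mm, other.pixel_pitch_mm))

    def with_pixels(self, pixels: np.ndarray, units_tag: str | None = None) -> "FrameImage":
        return replace(self, pixels=pixels,
                       units_tag=self.units_tag if units_tag is None else units_tag)


@dataclass
class CineStack:
    """Ordered list of frames with identical geometry acquired in cine mode."""

    frames: list[FrameImage]
    frame_rate_fps: float = MAX_FRAME_RATE_FPS
    mode_tag: EnergyMode | None = None

    def __post_init__(self) -> None:
        if not (0 < self.frame_rate_fps <= MAX_FRAME_RATE_FPS):
            raise ValueError(
                f"frame_rate_fps must be in (0, {MAX_FRAME_RATE_FPS}], "
                f"got {self.frame_rate_fps}")
        if self.frames:
            first = self.frames[0]
            for i, f in enumerate(self.frames):
                if not first.same_geometry(f):
                    raise ValueError(f"frame {i} geometry {f.pixels.shape} differs "
                                     f"from frame 0 {first.pixels.shape}")

    def __len__(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        """Frames stacked into a (n_frames, rows, cols) array."""
        return np.stack([f.pixels for f in self.frames])


# ---------------------------------------------------------------------------
# frame arithmetic


def average_frames(stack: CineStack) -> FrameImage:
    """Per-pixel arithmetic mean over the stack (e.g. the 300-frame dark/flood averages)."""
    if len(stack) == 0:
        raise ValueError("cannot average an empty stack")
    mean = stack.as_array().mean(axis=0)
    return stack.frames[0].with_pixels(mean)


def integrate_frames(stack: CineStack) -> FrameImage:
    """Per-pixel sum over frames: the integrated image of a delivery.

    Equals ``len(stack) * average_frames(stack)`` exactly in exact arithmetic.
    Integration (not averaging) is the default input to dose conversion since
    the delivered dose is proportional to the total collected signal.
    """
    if len(stack) == 0:
        raise ValueError("cannot integrate an empty stack")
    total = stack.as_array().sum(axis=0)
    return stack.frames[0].with_pixels(total)


def extract_profile(img: FrameImage, axis: str, offset_mm: float = 0.0,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Extract a 1D dose/signal profile along a principal axis.

    Parameters
    ----------
    axis
        ``"crossplane"``: profile along a row (varying column position), taken
        at the row nearest ``offset_mm`` from centre.  ``"inplane"``: profile
        along a column at the column nearest ``offset_mm``.
    offset_mm
        Perpendicular distance of the profile line from the grid centre.

    Returns
    -------
    positions_mm, values
        Nearest-row/column extraction, no interpolation; positions relative
        to the grid centre.
    """
    if axis not in ("inplane", "crossplane"):
        raise ValueError("axis must be 'inplane' or 'crossplane'")
    if axis == "crossplane":
        n_perp, pos = img.n_rows, img.col_positions_mm()
    else:
        n_perp, pos = img.n_cols, img.row_positions_mm()
    idx_f = (n_perp - 1) / 2.0 + offset_mm / img.pixel_pitch_mm
    idx = int(round(idx_f))
    if idx < 0 or idx >= n_perp:
        raise ValueError(f"offset {offset_mm} mm lies outside the grid")
    values = img.pixels[idx, :] if axis == "crossplane" else img.pixels[:, idx]
    return pos, values.copy()


def profile_to_csv(positions_mm: np.ndarray, values: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"position_mm": positions_mm, "value": values}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stack I/O

_RAW_DTYPE = np.dtype("<u2")  # unsigned 16-bit little-endian, row-major


def _sidecar_dict(stack: CineStack) -> dict:
    f0 = stack.frames[0]
    return {
        "rows": f0.n_rows,
        "cols": f0.n_cols,
        "pitch_mm": f0.pixel_pitch_mm,
        "frames": len(stack),
        "energy_mode": stack.mode_tag.value if stack.mode_tag else None,
        "frame_rate_fps": stack.frame_rate_fps,
    }


def write_stack(stack: CineStack, path: str | Path, fmt: str = "tiff_stack") -> None:
    """Write a cine stack as a multi-page TIFF or raw uint16 binary, plus JSON sidecar.

    The sidecar is written next to the data file as ``<path>.json``.  TIFF
    stacks store uint16 when all values are non-negative integers within
    range (bit-exact for detector counts), float32 otherwise.  The raw
    dialect is uint16 little-endian, row-major, frames concatenated.
    """
    path = Path(path)
    if len(stack) == 0:
        raise ValueError("cannot write an empty stack")
    arr = stack.as_array()
    if fmt == "tiff_stack":
        if np.all(arr >= 0) and np.all(arr == np.round(arr)) and arr.max() <= 65535:
            tifffile.imwrite(path, arr.astype(np.uint16), photometric="minisblack")
        else:
            tifffile.imwrite(path, arr.astype(np.float32), photometric="minisblack")
    elif fmt == "raw_binary":
        if not (np.all(arr >= 0) and np.all(arr == np.round(arr)) and arr.max() <= 65535):
            raise ValueError("raw_binary stores uint16; values must be integers in [0, 65535]")
        path.write_bytes(arr.astype(_RAW_DTYPE).tobytes())
    else:
        raise ValueError(f"unknown format {fmt!r}")
    with open(str(path) + ".json", "w") as fh:
        json.dump(_sidecar_dict(stack), fh, indent=1)


def read_stack(path: str | Path, fmt: str = "tiff_stack",
               sidecar: str | Path | dict | None = None) -> CineStack:
    """Read a cine stack written by :func:`write_stack` (bit-exact round trip).

    Parameters
    ----------
    sidecar
        JSON metadata path or pre-parsed dict.  Defaults to ``<path>.json``.
        Mandatory for ``raw_binary`` (it has no header); optional for TIFF,
        where it supplies pitch/energy-mode/frame-rate metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict | None
    if isinstance(sidecar, dict):
        meta = sidecar
    else:
        sc_path = Path(sidecar) if sidecar is not None else Path(str(path) + ".json")
        meta = json.loads(sc_path.read_text()) if sc_path.exists() else None

    if fmt == "tiff_stack":
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if meta is not None and arr.shape[1:] != (meta["rows"], meta["cols"]):
            raise ValueError(f"TIFF frame shape {arr.shape[1:]} does not match sidecar "
                             f"({meta['rows']}, {meta['cols']})")
    elif fmt == "raw_binary":
        if meta is None:
            raise ValueError("raw_binary requires a JSON sidecar with rows/cols/frames")
        rows, cols, n_frames = meta["rows"], meta["cols"], meta["frames"]
        buf = np.frombuffer(path.read_bytes(), dtype=_RAW_DTYPE)
        frame_px = rows * cols
        if buf.size != n_frames * frame_px:
            n_complete, rem = divmod(buf.size, frame_px)
            if rem:
                raise ValueError(
                    f"file truncated mid-frame: frame {n_complete} is incomplete "
                    f"({rem} of {frame_px} pixels)")
            raise ValueError(f"expected {n_frames} frames, file holds {n_complete}")
        arr = buf.reshape(n_frames, rows, cols)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    pitch = meta.get("pitch_mm", DEFAULT_PITCH_MM) if meta else DEFAULT_PITCH_MM
    mode = None
    if meta and meta.get("energy_mode"):
        mode = EnergyMode.parse(meta["energy_mode"])
    fps = meta.get("frame_rate_fps", MAX_FRAME_RATE_FPS) if meta else MAX_FRAME_RATE_FPS
    frames = [FrameImage(arr[i], pixel_pitch_mm=pitch) for i in range(arr.shape[0])]
    return CineStack(frames, frame_rate_fps=fps, mode_tag=mode)
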