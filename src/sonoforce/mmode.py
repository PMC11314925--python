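"""M-mode image container, B-mode scanline extraction, and file I/O.

An M-mode image is a depth-by-time intensity matrix: rows are depth
(shallow at row 0), columns are frames.  Images are written as 16-bit
grayscale PNG/TIFF with a JSON sidecar carrying the float scale, the
depth axis, frame rate and provenance, so that write -> read round-trips
are lossless to one quantization step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ForceTrace",
    "MModeImage",
    "BModeStack",
    "FormatError",
    "pixel_centers",
    "bmode_to_mmode",
    "read_mmode",
    "write_mmode",
    "read_force",
    "write_force",
]

PROVENANCES = ("clinical_scanline", "chirp", "synthetic")

_QUANT_LEVELS = 65535  # 16-bit grayscale


class FormatError(ValueError):
    """Raised when an on-disk image/force file violates the format contract."""


def pixel_centers(depth_px: int, imaging_depth_cm: float) -> np.ndarray:
    """Depth (cm) of each pixel center: pixel j maps to (j + 0.5) * depth / n.

    This pixel-center convention is used everywhere a depth axis is built.
    """
    if depth_px < 1:
        raise ValueError(f"depth_px must be >= 1, got {depth_px}")
    if imaging_depth_cm <= 0:
        raise ValueError(f"imaging depth must be positive, got {imaging_depth_cm}")
    return (np.arange(depth_px) + 0.5) * (imaging_depth_cm / depth_px)


@dataclass
class ForceTrace:
    """Sampled ground-reaction force in Newtons.

    Attributes
    ----------
    samples : ndarray
        Force values (N), finite.
    rate : float
        Sampling frequency (Hz), > 0.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("force samples must be a 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("force samples must be finite")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return len(self.samples) / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class MModeImage:
    """Depth x time ultrasound intensity image with a physical depth axis.

    Attributes
    ----------
    intensities : ndarray, shape (depth_px, frames)
        Nonnegative echo intensities; rows are depth (shallow first),
        columns are time.
    depth_axis : ndarray, shape (depth_px,)
        Strictly increasing per-pixel depth in cm.
    frame_rate : float
        Frames per second.
    site : str
        Sensor-site label (e.g. "vl").
    provenance : str
        One of "clinical_scanline", "chirp", "synthetic".
    """

    intensities: np.ndarray
    depth_axis: np.ndarray
    frame_rate: float
    site: str = ""
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D (depth x time) matrix")
        if self.intensities.shape[1] < 1:
            raise ValueError("image must contain at least one frame")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        if self.depth_axis.shape != (self.intensities.shape[0],):
            raise ValueError(
                f"depth axis length {self.depth_axis.shape} does not match "
                f"depth_px {self.intensities.shape[0]}"
            )
        if np.any(np.diff(self.depth_axis) <= 0):
            raise ValueError("depth axis must be strictly increasing")
        if self.frame_rate <= 0:
            raise ValueError(f"frame rate must be positive, got {self.frame_rate}")
        if self.provenance not in PROVENANCES:
            raise ValueError(
                f"provenance must be one of {PROVENANCES}, got {self.provenance!r}"
            )

    @property
    def depth_px(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[1]


@dataclass
class BModeStack:
    """Time series of 2-D brightness-mode frames (depth_px x lateral_px)."""

    frames: np.ndarray  # (n_frames, depth_px, lateral_px)
    depth_axis: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, depth, lateral) array")
        if self.frames.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if self.depth_axis.shape != (self.frames.shape[1],):
            raise ValueError("depth axis length does not match frame depth")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def lateral_px(self) -> int:
        return self.frames.shape[2]


def bmode_to_mmode(
    stack: BModeStack, scanline_index: int | None = None, site: str = ""
) -> MModeImage:
    """Collapse a B-mode stack to an M-mode by tracking one scanline over time.

    Column ``t`` of the output is lateral column ``scanline_index`` of frame
    ``t``.  The default scanline is the central one, ``floor(lateral_px / 2)``.
    """
    if scanline_index is None:
        scanline_index = stack.lateral_px // 2
    if not 0 <= scanline_index < stack.lateral_px:
        raise IndexError(
            f"scanline index {scanline_index} out of range "
            f"[0, {stack.lateral_px})"
        )
    intensities = stack.frames[:, :, scanline_index].T.copy()
    return MModeImage(
        intensities=np.maximum(intensities, 0.0),
        depth_axis=stack.depth_axis,
        frame_rate=stack.frame_rate,
        site=site,
        provenance="clinical_scanline",
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_mmode(image: MModeImage, path: str | Path) -> Path:
    """Write an M-mode as 16-bit grayscale PNG/TIFF plus a JSON sidecar.

    Intensities are min-max scaled to the 16-bit range; the scale is
    recorded in the sidecar so reads recover floats to one quantization
    step ((hi - lo) / 65535).
    """
    path = Path(path)
    lo = float(image.intensities.min())
    hi = float(image.intensities.max())
    if hi > lo:
        quantized = np.round(
            (image.intensities - lo) / (hi - lo) * _QUANT_LEVELS
        ).astype(np.uint16)
    else:
        quantized = np.zeros(image.intensities.shape, dtype=np.uint16)
    iio.imwrite(path, quantized)
    sidecar = {
        "scale_min": lo,
        "scale_max": hi,
        "depth_axis_cm": image.depth_axis.tolist(),
        "frame_rate_hz": image.frame_rate,
        "site": image.site,
        "provenance": image.provenance,
        "orientation": "rows=depth (shallow at row 0), columns=time",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def read_mmode(path: str | Path) -> MModeImage:
    """Read an M-mode written by :func:`write_mmode`; sidecar is mandatory."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar for {path}: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    raw = np.asarray(iio.imread(path))
    if raw.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel 2-D image")
    depth_axis = np.asarray(meta["depth_axis_cm"], dtype=float)
    if raw.shape[0] != len(depth_axis):
        raise FormatError(
            f"{path}: image depth {raw.shape[0]} does not match sidecar "
            f"depth axis length {len(depth_axis)}"
        )
    lo, hi = float(meta["scale_min"]), float(meta["scale_max"])
    intensities = lo + raw.astype(float) / _QUANT_LEVELS * (hi - lo)
    if np.any(intensities < 0):
        # lo < 0 would violate the nonnegativity contract baked into writes
        raise FormatError(f"{path}: negative intensities after descaling")
    return MModeImage(
        intensities=intensities,
        depth_axis=depth_axis,
        frame_rate=float(meta["frame_rate_hz"]),
        site=meta.get("site", ""),
        provenance=meta.get("provenance", "synthetic"),
    )


def write_force(trace: ForceTrace, path: str | Path) -> Path:
    """Write a force trace as a 2-column CSV (time_s, force_N)."""
    path = Path(path)
    data = np.column_stack([trace.times, trace.samples])
    np.savetxt(
        path,
        data,
        delimiter=",",
        header="time_s,force_N",
        comments="",
        fmt="%.10g",
    )
    return path


def read_force(path: str | Path) -> ForceTrace:
    """Read a 2-column (time_s, force_N) CSV back into a ForceTrace."""
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns (time_s, force_N)")
    times, samples = data[:, 0], data[:, 1]
    if len(times) < 2:
        raise FormatError(f"{path}: need at least 2 samples to infer rate")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    rate = 1.0 / float(np.median(dt))
    # snap to an integer rate when within float round-off of one
    if math.isclose(rate, round(rate), rel_tol=1e-6):
        rate = float(round(rate))
    return ForceTrace(samples=samples, rate=rate)
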