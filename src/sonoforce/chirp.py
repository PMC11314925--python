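"""Frequency-sweep (FMCW) acquisition model.

A linear frequency sweep of known rate is transmitted; after mixing with
the echo, each reflector appears in the baseband record as a sinusoid
whose beat frequency is proportional to its round-trip delay — shallow
reflectors map to low frequencies, deep ones to high frequencies.  An FFT
over the sweep window recovers the frequency components and hence the
depth profile (one A-line per sweep); stacking A-lines at the frame rate
yields an M-mode.

Internally all lengths are in meters; M-mode depth axes are exported in
cm to match the rest of the package.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import get_window

from .mmode import MModeImage, pixel_centers

__all__ = [
    "ChirpConfig",
    "EchoScene",
    "AliasingError",
    "beat_frequency",
    "depth_from_beat",
    "range_bin",
    "simulate_sweep",
    "demodulate_aline",
    "acquire_mmode",
    "scenes_from_trajectories",
]

_FFT_PAD = 4  # zero-padding factor for finer spectral peak sampling


class AliasingError(ValueError):
    """A reflector's beat frequency exceeds the baseband Nyquist rate."""


@dataclass(frozen=True)
class ChirpConfig:
    """Sweep, sampling and geometry parameters of the acquisition.

    Sweep bandwidth and baseband sample rate are engineering defaults
    (2 MHz and 100 kHz): the bandwidth sets the range resolution
    c / (2B) ~ 0.39 mm over 4 cm and keeps beat frequencies in the kHz
    band; the sample rate is Nyquist-safe for the full imaging depth.
    """

    sweep_duration: float = 0.010  # s
    sweep_bandwidth: float = 2.0e6  # Hz
    center_frequency: float = 4.25e6  # Hz
    sample_rate: float = 100.0e3  # Hz
    sound_speed: float = 1540.0  # m/s
    imaging_depth: float = 0.04  # m
    frame_rate: float = 50.0  # Hz

    def __post_init__(self) -> None:
        for name in ("sweep_duration", "sweep_bandwidth", "center_frequency",
                     "sample_rate", "sound_speed", "imaging_depth", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.frame_rate > 1.0 / self.sweep_duration:
            raise ValueError(
                f"frame rate {self.frame_rate} Hz exceeds 1/sweep_duration "
                f"({1.0 / self.sweep_duration:.1f} Hz)"
            )

    @property
    def sweep_rate(self) -> float:
        """Frequency ramp rate in Hz/s."""
        return self.sweep_bandwidth / self.sweep_duration

    @property
    def n_samples(self) -> int:
        """Baseband record length per sweep."""
        return round(self.sweep_duration * self.sample_rate)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChirpConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class EchoScene:
    """Discrete-reflector stand-in for tissue interfaces.

    ``reflectors`` is a list of (depth_m, amplitude) pairs with
    0 < depth < imaging window and amplitude >= 0.
    """

    reflectors: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for depth, amplitude in self.reflectors:
            if amplitude < 0:
                raise ValueError(f"reflector amplitude must be >= 0, got {amplitude}")
            if depth <= 0:
                raise ValueError(f"reflector depth must be > 0 m, got {depth}")

    @property
    def depths(self) -> np.ndarray:
        return np.array([d for d, _ in self.reflectors], dtype=float)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for _, a in self.reflectors], dtype=float)


def beat_frequency(config: ChirpConfig, depth: float | np.ndarray) -> float | np.ndarray:
    """Beat frequency (Hz) of a reflector: sweep_rate * (2 * depth / c).

    Strictly increasing in depth, so the demodulated spectrum maps
    one-to-one onto the depth axis.
    """
    depth_arr = np.asarray(depth, dtype=float)
    if np.any(depth_arr <= 0) or np.any(depth_arr >= config.imaging_depth):
        raise ValueError(
            f"depth must lie in (0, {config.imaging_depth}) m, got {depth}"
        )
    out = config.sweep_rate * (2.0 * depth_arr / config.sound_speed)
    return float(out) if np.isscalar(depth) else out


def depth_from_beat(config: ChirpConfig, freq: np.ndarray) -> np.ndarray:
    """Inverse of :func:`beat_frequency` (meters)."""
    return np.asarray(freq, dtype=float) * config.sound_speed / (2.0 * config.sweep_rate)


def range_bin(config: ChirpConfig) -> float:
    """Range resolution c / (2 * bandwidth), in meters."""
    return config.sound_speed / (2.0 * config.sweep_bandwidth)


def simulate_sweep(
    config: ChirpConfig,
    scene: EchoScene,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Down-mixed baseband record for one sweep over a reflector scene.

    The record is a sum over reflectors of
    ``a * cos(2*pi*f_beat(d)*t + phi(d))`` with the fixed phase convention
    ``phi(d) = 2*pi*center_frequency*(2*d/c)`` (the carrier phase of the
    round trip; only magnitude spectra are used downstream, so the
    convention is inert), plus white Gaussian noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    n = config.n_samples
    t = np.arange(n) / config.sample_rate
    record = np.zeros(n)
    nyquist = config.sample_rate / 2.0
    for depth, amplitude in scene.reflectors:
        f_beat = beat_frequency(config, depth)
        if f_beat >= nyquist:
            raise AliasingError(
                f"reflector at {depth * 100:.2f} cm has beat frequency "
                f"{f_beat:.1f} Hz >= Nyquist {nyquist:.1f} Hz; raise the "
                "sample rate or lower the sweep rate"
            )
        phase = 2.0 * np.pi * config.center_frequency * (2.0 * depth / config.sound_speed)
        record += amplitude * np.cos(2.0 * np.pi * f_beat * t + phase)
    if noise_sd > 0:
        record = record + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return record


def demodulate_aline(
    config: ChirpConfig, record: np.ndarray, depth_px: int = 128
) -> np.ndarray:
    """Recover an A-line intensity profile over depth from one sweep record.

    A Hann window controls spectral leakage between nearby interfaces,
    the FFT is zero-padded 4x for finer peak sampling, and the magnitude
    spectrum over the depth-mapped band is linearly interpolated onto
    ``depth_px`` pixel-center depths.  Output is nonnegative.
    """
    record = np.asarray(record, dtype=float)
    n = config.n_samples
    if len(record) != n:
        raise ValueError(
            f"record length {len(record)} does not match sweep_duration x "
            f"sample_rate = {n}"
        )
    window = get_window("hann", n, fftbins=True)
    nfft = _FFT_PAD * n
    spectrum = np.abs(np.fft.rfft(record * window, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / config.sample_rate)
    # pixel-center depths in meters (pixel_centers works in cm-agnostic units)
    depths_m = pixel_centers(depth_px, config.imaging_depth)
    pixel_freqs = config.sweep_rate * (2.0 * depths_m / config.sound_speed)
    return np.interp(pixel_freqs, freqs, spectrum)


def scenes_from_trajectories(
    trajectories_cm: np.ndarray, amplitudes: np.ndarray | None = None
) -> list[EchoScene]:
    """Convert (n_interfaces, n_frames) cm trajectories to per-frame scenes."""
    trajectories_cm = np.atleast_2d(np.asarray(trajectories_cm, dtype=float))
    n_interfaces, n_frames = trajectories_cm.shape
    if amplitudes is None:
        amplitudes = np.ones(n_interfaces)
    return [
        EchoScene(
            reflectors=[
                (trajectories_cm[j, t] / 100.0, float(amplitudes[j]))
                for j in range(n_interfaces)
            ]
        )
        for t in range(n_frames)
    ]


def acquire_mmode(
    config: ChirpConfig,
    scene_sequence: list[EchoScene],
    noise_sd: float = 0.0,
    seed: int = 0,
    depth_px: int = 128,
    site: str = "",
) -> MModeImage:
    """Acquire an M-mode: one sweep + FFT demodulation per frame.

    Each frame draws independent noise from a seed tree rooted at
    ``seed``; columns are demodulated A-lines and the depth axis follows
    the pixel-center convention (in cm).
    """
    if len(scene_sequence) < 1:
        raise ValueError("need at least one frame")
    frame_seeds = np.random.SeedSequence(seed).spawn(len(scene_sequence))
    columns = []
    for scene, fseed in zip(scene_sequence, frame_seeds):
        record = simulate_sweep(
            config, scene, noise_sd=noise_sd, seed=int(fseed.generate_state(1)[0])
        )
        columns.append(demodulate_aline(config, record, depth_px=depth_px))
    return MModeImage(
        intensities=np.column_stack(columns),
        depth_axis=pixel_centers(depth_px, config.imaging_depth * 100.0),
        frame_rate=config.frame_rate,
        site=site,
        provenance="chirp",
    )
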