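"""Synthetic multi-muscle contraction phantom.

Generates everything the downstream pipeline consumes without any
external data: a trapezoidal maximum-effort force profile, per-site
tissue-interface trajectories that displace linearly with force, speckled
M-mode imagery rendered from those trajectories, and multi-trial datasets
with a train/test trial split (last trial held out for testing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .mmode import (
    ForceTrace,
    MModeImage,
    pixel_centers,
    read_force,
    read_mmode,
    write_force,
    write_mmode,
)

__all__ = [
    "MusclePhantom",
    "Trial",
    "TrialDataset",
    "TrajectoryRangeError",
    "SITE_ORDER",
    "CLINICAL_KEY",
    "default_phantom",
    "generate_mvc_force",
    "interface_trajectory",
    "render_mmode",
    "block_mean_resample",
    "generate_trial_dataset",
    "save_trial_dataset",
    "load_trial_dataset",
]

#: canonical sensor-site order: vastus lateralis, rectus femoris,
#: medial hamstring, vastus medialis (oblique)
SITE_ORDER = ("vl", "rf", "mh", "vmo")

#: image-stream key for the clinical-style scanline (co-located with VL)
CLINICAL_KEY = "clinical"

# unit-mean Rayleigh scale: E[Rayleigh(s)] = s * sqrt(pi/2)
_RAYLEIGH_UNIT_MEAN_SCALE = float(np.sqrt(2.0 / np.pi))


class TrajectoryRangeError(ValueError):
    """An interface trajectory left the imaging window."""


@dataclass
class MusclePhantom:
    """Parametric description of four instrumented muscle sites.

    Each site has a set of tissue-interface rest depths (cm, strictly
    increasing, inside the imaging window), a displacement-per-force gain
    (cm/N, sign free), and a nonnegative contribution weight; weights sum
    to 1 and describe each site's share of the total force.  Noise is a
    speckle contrast in [0, 1] (0 = none, 1 = fully developed Rayleigh
    speckle) and an additive-noise SNR in dB (``inf`` = noise-free).
    """

    interface_rest_depths: dict[str, tuple[float, ...]]
    gains: dict[str, float]
    contribution_weights: dict[str, float]
    speckle_contrast: float = 0.5
    snr_db: float = 30.0
    imaging_depth_cm: float = 4.0
    band_sigma_cm: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        sites = list(self.interface_rest_depths)
        for mapping, name in (
            (self.gains, "gains"),
            (self.contribution_weights, "contribution_weights"),
        ):
            if set(mapping) != set(sites):
                raise ValueError(f"{name} must cover exactly the sites {sites}")
        for site, depths in self.interface_rest_depths.items():
            arr = np.asarray(depths, dtype=float)
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"site {site!r}: rest depths must be strictly increasing")
            if np.any(arr <= 0) or np.any(arr >= self.imaging_depth_cm):
                raise ValueError(
                    f"site {site!r}: rest depths must lie inside "
                    f"(0, {self.imaging_depth_cm}) cm"
                )
        weights = np.array([self.contribution_weights[s] for s in sites])
        if np.any(weights < 0):
            raise ValueError("contribution weights must be nonnegative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"contribution weights must sum to 1, got {weights.sum()}")
        if not 0.0 <= self.speckle_contrast <= 1.0:
            raise ValueError("speckle contrast must be in [0, 1]")
        if self.imaging_depth_cm <= 0:
            raise ValueError("imaging depth must be positive")

    @property
    def site_names(self) -> tuple[str, ...]:
        return tuple(self.interface_rest_depths)


def default_phantom(
    speckle_contrast: float = 0.5, snr_db: float = 30.0, seed: int = 0
) -> MusclePhantom:
    """Four-site phantom with equal contribution weights and mixed-sign gains.

    Gains are sized so a 1500 N peak displaces interfaces by a few mm
    while every trajectory stays inside the 4 cm imaging window.
    """
    return MusclePhantom(
        interface_rest_depths={
            "vl": (0.8, 1.8, 3.0),
            "rf": (0.7, 1.6, 2.8),
            "mh": (1.0, 2.2, 3.2),
            "vmo": (0.8, 1.9, 3.1),
        },
        gains={"vl": 4.0e-4, "rf": -3.0e-4, "mh": 3.5e-4, "vmo": -2.5e-4},
        contribution_weights={s: 0.25 for s in SITE_ORDER},
        speckle_contrast=speckle_contrast,
        snr_db=snr_db,
        seed=seed,
    )


def generate_mvc_force(
    duration_s: float,
    rate: float,
    peak: float,
    ramp_s: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ForceTrace:
    """Trapezoidal maximum-effort force profile plus Gaussian noise.

    The profile rises linearly from 0 to ``peak`` over ``ramp_s``, holds,
    then falls back to 0, reaching baseline at the final sample (the fall
    completes one sample period early so the sampled trace ends at 0).

    Parameters
    ----------
    duration_s, rate, peak
        Trace length (s), sampling rate (Hz), plateau force (N); all > 0
        and ``duration_s > 2 * ramp_s``.
    ramp_s
        Rise/fall duration in seconds.
    noise_sd
        Standard deviation of additive Gaussian noise (N).
    seed
        RNG seed; identical seeds give bit-identical traces.
    """
    if duration_s <= 0 or rate <= 0 or peak <= 0:
        raise ValueError(
            "duration_s, rate and peak must all be positive "
            f"(got {duration_s}, {rate}, {peak})"
        )
    if duration_s <= 2 * ramp_s:
        raise ValueError(
            f"duration_s ({duration_s}) must exceed twice ramp_s ({ramp_s})"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    n = round(rate * duration_s)
    t = np.arange(n) / rate
    fall_end = duration_s - 1.0 / rate
    knots_t = [0.0, ramp_s, duration_s - ramp_s, fall_end]
    samples = np.interp(t, knots_t, [0.0, peak, peak, 0.0])
    if noise_sd > 0:
        samples = samples + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return ForceTrace(samples=samples, rate=rate)


def interface_trajectory(
    phantom: MusclePhantom, site: str, force: ForceTrace | np.ndarray
) -> np.ndarray:
    """Per-interface depth time series for one site, shape (n_interfaces, n).

    depth_j(t) = rest_depth_j + gain_site * force(t); every depth must
    remain inside (0, imaging_depth) or :class:`TrajectoryRangeError` is
    raised naming the site and the first offending time index.
    """
    if site not in phantom.site_names:
        raise KeyError(f"unknown site {site!r}; phantom has {phantom.site_names}")
    force_vals = force.samples if isinstance(force, ForceTrace) else np.asarray(force, float)
    rest = np.asarray(phantom.interface_rest_depths[site], dtype=float)
    traj = rest[:, None] + phantom.gains[site] * force_vals[None, :]
    out_of_range = (traj <= 0) | (traj >= phantom.imaging_depth_cm)
    if np.any(out_of_range):
        bad_t = int(np.argmax(np.any(out_of_range, axis=0)))
        raise TrajectoryRangeError(
            f"site {site!r}: interface trajectory leaves the imaging window "
            f"(0, {phantom.imaging_depth_cm}) cm at time index {bad_t}"
        )
    return traj


def render_mmode(
    trajectories: np.ndarray,
    frame_rate: float,
    depth_px: int,
    imaging_depth_cm: float = 4.0,
    speckle_contrast: float = 0.0,
    snr_db: float = np.inf,
    seed: int = 0,
    band_sigma_cm: float = 0.05,
    amplitudes: np.ndarray | None = None,
    site: str = "",
    provenance: str = "synthetic",
) -> MModeImage:
    """Render an M-mode from interface-depth trajectories.

    Each frame (column) contains a bright band with a Gaussian depth
    cross-section centered on each interface depth.  The clean frame is
    multiplied by a per-pixel unit-mean speckle field — a convex blend
    ``(1 - c) + c * Rayleigh`` with contrast ``c`` — then white Gaussian
    noise at the requested SNR (dB, relative to clean-image RMS) is added
    and the result is clipped at zero.

    Parameters
    ----------
    trajectories : ndarray, shape (n_interfaces, n_frames)
        Interface depths in cm, one row per interface, already sampled at
        the frame rate.
    """
    trajectories = np.atleast_2d(np.asarray(trajectories, dtype=float))
    if depth_px < 64:
        raise ValueError(f"depth_px must be >= 64, got {depth_px}")
    if frame_rate <= 0:
        raise ValueError("frame rate must be positive")
    n_interfaces, n_frames = trajectories.shape
    if amplitudes is None:
        amplitudes = np.ones(n_interfaces)
    amplitudes = np.asarray(amplitudes, dtype=float)
    depth = pixel_centers(depth_px, imaging_depth_cm)  # (P,)
    # (P, n_if, T) Gaussian bands summed over interfaces
    diff = depth[:, None, None] - trajectories[None, :, :]
    clean = np.einsum(
        "j,pjt->pt", amplitudes, np.exp(-0.5 * (diff / band_sigma_cm) ** 2)
    )
    rng = np.random.default_rng(seed)
    img = clean
    if speckle_contrast > 0:
        speckle = rng.rayleigh(scale=_RAYLEIGH_UNIT_MEAN_SCALE, size=clean.shape)
        img = img * ((1.0 - speckle_contrast) + speckle_contrast * speckle)
    if np.isfinite(snr_db):
        rms = float(np.sqrt(np.mean(clean**2)))
        noise_sd = rms / 10.0 ** (snr_db / 20.0)
        img = img + rng.normal(0.0, noise_sd, clean.shape)
    return MModeImage(
        intensities=np.maximum(img, 0.0),
        depth_axis=depth,
        frame_rate=frame_rate,
        site=site,
        provenance=provenance,
    )


def block_mean_resample(x: np.ndarray, factor: int) -> np.ndarray:
    """Decimate by averaging consecutive non-overlapping blocks of ``factor``.

    Trailing samples that do not fill a block are dropped.  This is the
    anti-aliasing convention used to align high-rate force with the
    imaging frame rate (e.g. 1600 Hz -> 50 Hz with factor 32).
    """
    if factor < 1:
        raise ValueError("resampling factor must be >= 1")
    x = np.asarray(x, dtype=float)
    n_blocks = len(x) // factor
    if n_blocks == 0:
        raise ValueError(f"trace of length {len(x)} shorter than one block ({factor})")
    return x[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)


@dataclass
class Trial:
    """One contraction trial: per-stream M-modes plus the force trace.

    ``images`` maps stream keys ("clinical" plus the four site codes) to
    M-mode images; ``frame_force`` is the force block-mean resampled to
    the imaging frame rate (the per-frame regression target).
    """

    index: int
    role: str  # "train" | "test"
    images: dict[str, MModeImage]
    force: ForceTrace
    frame_force: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in ("train", "test"):
            raise ValueError(f"role must be 'train' or 'test', got {self.role!r}")
        counts = {k: im.n_frames for k, im in self.images.items()}
        if len(set(counts.values())) > 1:
            raise ValueError(f"streams disagree on frame count: {counts}")
        n_frames = next(iter(counts.values()))
        self.frame_force = np.asarray(self.frame_force, dtype=float)
        if len(self.frame_force) != n_frames:
            raise ValueError(
                f"frame-aligned force length {len(self.frame_force)} does not "
                f"match frame count {n_frames}"
            )

    @property
    def n_frames(self) -> int:
        return next(iter(self.images.values())).n_frames


@dataclass
class TrialDataset:
    """Per-subject bundle of trials with train/test roles."""

    subject_id: str
    trials: list[Trial]

    def train_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.role == "train"]

    def test_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.role == "test"]


def generate_trial_dataset(
    phantom: MusclePhantom,
    n_trials: int = 3,
    frame_rate: float = 50.0,
    force_rate: float = 1600.0,
    depth_px: int = 128,
    clinical_depth_px: int = 256,
    duration_s: float = 5.0,
    peak_force: float = 1500.0,
    ramp_s: float = 1.0,
    force_noise_sd: float = 10.0,
    seed: int = 0,
    subject_id: str = "synthetic-subject",
) -> TrialDataset:
    """Simulate a multi-trial session; the last trial is the held-out test.

    Every trial draws independent force noise and speckle from a seed tree
    rooted at ``seed``, so the whole dataset is a pure function of its
    arguments.  Each trial carries five image streams: a clinical-style
    higher-resolution scanline co-located with the VL site, plus the four
    distributed-site images.
    """
    if n_trials < 2:
        raise ValueError(
            f"need at least 2 trials to form a train/test split, got {n_trials}"
        )
    factor = round(force_rate / frame_rate)
    root = np.random.SeedSequence(seed)
    trial_seeds = root.spawn(n_trials)
    trials: list[Trial] = []
    for i in range(n_trials):
        streams = trial_seeds[i].spawn(len(phantom.site_names) + 2)
        force = generate_mvc_force(
            duration_s,
            force_rate,
            peak_force,
            ramp_s=ramp_s,
            noise_sd=force_noise_sd,
            seed=int(streams[0].generate_state(1)[0]),
        )
        frame_force = block_mean_resample(force.samples, factor)
        images: dict[str, MModeImage] = {}
        for j, site in enumerate(phantom.site_names):
            traj = interface_trajectory(phantom, site, frame_force)
            images[site] = render_mmode(
                traj,
                frame_rate,
                depth_px,
                imaging_depth_cm=phantom.imaging_depth_cm,
                speckle_contrast=phantom.speckle_contrast,
                snr_db=phantom.snr_db,
                seed=int(streams[j + 1].generate_state(1)[0]),
                band_sigma_cm=phantom.band_sigma_cm,
                site=site,
            )
        clin_traj = interface_trajectory(phantom, "vl", frame_force)
        images[CLINICAL_KEY] = render_mmode(
            clin_traj,
            frame_rate,
            clinical_depth_px,
            imaging_depth_cm=phantom.imaging_depth_cm,
            speckle_contrast=phantom.speckle_contrast,
            snr_db=phantom.snr_db,
            seed=int(streams[-1].generate_state(1)[0]),
            band_sigma_cm=phantom.band_sigma_cm,
            site="vl",
            provenance="clinical_scanline",
        )
        role = "test" if i == n_trials - 1 else "train"
        trials.append(
            Trial(index=i + 1, role=role, images=images, force=force,
                  frame_force=frame_force)
        )
    return TrialDataset(subject_id=subject_id, trials=trials)


def save_trial_dataset(dataset: TrialDataset, out_dir: str | Path) -> Path:
    """Write a dataset as PNG+sidecar images, force CSVs and a YAML manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subject_id": dataset.subject_id, "trials": []}
    for trial in dataset.trials:
        tdir = out_dir / f"trial{trial.index:02d}"
        tdir.mkdir(exist_ok=True)
        entry: dict = {
            "index": trial.index,
            "role": trial.role,
            "force": str((tdir / "force.csv").relative_to(out_dir)),
            "images": {},
        }
        write_force(trial.force, tdir / "force.csv")
        for key, image in trial.images.items():
            img_path = tdir / f"{key}.png"
            write_mmode(image, img_path)
            entry["images"][key] = str(img_path.relative_to(out_dir))
        manifest["trials"].append(entry)
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def load_trial_dataset(manifest_path: str | Path) -> TrialDataset:
    """Load a dataset written by :func:`save_trial_dataset`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    trials: list[Trial] = []
    for entry in manifest["trials"]:
        force = read_force(root / entry["force"])
        images = {key: read_mmode(root / rel) for key, rel in entry["images"].items()}
        n_frames = next(iter(images.values())).n_frames
        frame_rate = next(iter(images.values())).frame_rate
        factor = round(force.rate / frame_rate)
        frame_force = block_mean_resample(force.samples, factor)[:n_frames]
        trials.append(
            Trial(
                index=int(entry["index"]),
                role=entry["role"],
                images=images,
                force=force,
                frame_force=frame_force,
            )
        )
    return TrialDataset(subject_id=manifest["subject_id"], trials=trials)
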