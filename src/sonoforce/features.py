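"""Feature extraction: windowed mean depth, z-scoring, PCA truncation.

The per-window feature is the intensity-weighted mean depth

    mean_depth = sum_i(A_i * D_i) / sum_i(A_i)

computed over a moving 25-pixel depth window with 50% overlap down each
A-line (column) of the M-mode.  Per-frame feature vectors are z-scored
with training-set statistics and projected onto the leading principal
components that explain 99% of the training variance.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mmode import MModeImage

__all__ = [
    "FeatureMatrix",
    "FeatureTransform",
    "DegenerateWindowWarning",
    "mean_depth",
    "window_starts",
    "extract_frame_features",
    "extract_features",
    "fit_feature_transform",
    "apply_feature_transform",
    "concat_sites",
]

DEFAULT_WINDOW_PX = 25
DEFAULT_OVERLAP = 0.5
DEFAULT_VARIANCE_THRESHOLD = 0.99


class DegenerateWindowWarning(UserWarning):
    """A window with zero total intensity fell back to its central depth."""


@dataclass
class FeatureMatrix:
    """Frames x features numeric matrix with (site, window) labels."""

    values: np.ndarray
    feature_labels: list[tuple[str, int]]
    frame_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (frames x features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if len(self.feature_labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.feature_labels)} labels for "
                f"{self.values.shape[1]} features"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def mean_depth(window_intensities: np.ndarray, window_depths: np.ndarray) -> float:
    """Intensity-weighted mean depth of one window.

    Parameters
    ----------
    window_intensities : array (A)
        Nonnegative pixel intensities with a positive sum.
    window_depths : array (D)
        Pixel depths, same length as the intensities.

    Returns
    -------
    float
        sum(A * D) / sum(A); always within [min(D), max(D)].
    """
    A = np.asarray(window_intensities, dtype=float)
    D = np.asarray(window_depths, dtype=float)
    if A.shape != D.shape:
        raise ValueError(f"length mismatch: {A.shape} intensities, {D.shape} depths")
    if np.any(A < 0):
        raise ValueError("intensities must be nonnegative")
    total = math.fsum(A)
    if total == 0:
        raise ValueError("window has zero total intensity (degenerate window)")
    # exactly-rounded sums: the result is independent of accumulation order
    return math.fsum(A * D) / total


def window_starts(n_px: int, window_px: int, overlap: float) -> tuple[np.ndarray, int]:
    """Start indices and stride of the moving depth windows.

    Stride is ``round(window_px * (1 - overlap))`` (12 px for the default
    25-px window at 50% overlap); only full windows are kept, giving
    ``floor((n_px - window_px) / stride) + 1`` windows.
    """
    if window_px < 1:
        raise ValueError("window_px must be >= 1")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    if n_px < window_px:
        raise ValueError(f"A-line of {n_px} px is shorter than one {window_px}-px window")
    stride = max(1, round(window_px * (1.0 - overlap)))
    return np.arange(0, n_px - window_px + 1, stride), stride


def extract_frame_features(
    aline: np.ndarray,
    depth_axis: np.ndarray,
    window_px: int = DEFAULT_WINDOW_PX,
    overlap: float = DEFAULT_OVERLAP,
) -> np.ndarray:
    """Per-window mean depths for one A-line.

    Zero-intensity windows fall back to their central depth (the uniform
    mean of the window's depths) with a :class:`DegenerateWindowWarning`,
    so NaNs never propagate downstream.
    """
    aline = np.asarray(aline, dtype=float)
    depth_axis = np.asarray(depth_axis, dtype=float)
    starts, _ = window_starts(len(aline), window_px, overlap)
    out = np.empty(len(starts))
    for w, s in enumerate(starts):
        A = aline[s : s + window_px]
        D = depth_axis[s : s + window_px]
        if A.sum() == 0:
            warnings.warn(
                f"window {w} (pixels {s}:{s + window_px}) has zero total "
                "intensity; using its central depth",
                DegenerateWindowWarning,
                stacklevel=2,
            )
            out[w] = D.mean()
        else:
            out[w] = mean_depth(A, D)
    return out


def extract_features(
    image: MModeImage,
    window_px: int = DEFAULT_WINDOW_PX,
    overlap: float = DEFAULT_OVERLAP,
) -> FeatureMatrix:
    """Windowed mean-depth features for every frame of an M-mode.

    Row ``t`` of the result is the feature vector of column ``t``.
    """
    starts, _ = window_starts(image.depth_px, window_px, overlap)
    X = image.intensities  # (P, T)
    D = image.depth_axis
    n_windows = len(starts)
    values = np.empty((image.n_frames, n_windows))
    degenerate = 0
    for w, s in enumerate(starts):
        block = X[s : s + window_px, :]  # (window, T)
        d = D[s : s + window_px]
        totals = block.sum(axis=0)
        weighted = d @ block
        zero = totals == 0
        degenerate += int(zero.sum())
        safe_totals = np.where(zero, 1.0, totals)
        col = weighted / safe_totals
        col[zero] = d.mean()
        values[:, w] = col
    if degenerate:
        warnings.warn(
            f"{degenerate} zero-intensity windows fell back to their central depth",
            DegenerateWindowWarning,
            stacklevel=2,
        )
    labels = [(image.site, int(w)) for w in range(n_windows)]
    return FeatureMatrix(values=values, feature_labels=labels, frame_rate=image.frame_rate)


@dataclass
class FeatureTransform:
    """Z-score statistics + PCA loadings learned on training rows only.

    ``pca_components`` has orthonormal rows (components x features); each
    component's sign is fixed so its largest-magnitude loading is
    positive, making the transform deterministic.
    """

    z_means: np.ndarray
    z_sds: np.ndarray
    pca_components: np.ndarray
    explained_variance_ratio: np.ndarray
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD

    @property
    def n_components(self) -> int:
        return self.pca_components.shape[0]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "z_means": self.z_means.tolist(),
                    "z_sds": self.z_sds.tolist(),
                    "pca_components": self.pca_components.tolist(),
                    "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                    "variance_threshold": self.variance_threshold,
                }
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            z_means=np.asarray(d["z_means"]),
            z_sds=np.asarray(d["z_sds"]),
            pca_components=np.asarray(d["pca_components"]),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"]),
            variance_threshold=d["variance_threshold"],
        )


def _fix_component_signs(components: np.ndarray) -> np.ndarray:
    flips = np.sign(components[np.arange(len(components)),
                               np.argmax(np.abs(components), axis=1)])
    flips[flips == 0] = 1.0
    return components * flips[:, None]


def fit_feature_transform(
    train: FeatureMatrix | np.ndarray,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> FeatureTransform:
    """Learn z-score statistics and a truncated PCA from training rows.

    Columns are standardized with training means/SDs (a zero-variance
    column gets SD 1, becoming the constant 0); PCA is computed on the
    z-scored rows and the smallest number of components whose cumulative
    explained-variance ratio reaches ``variance_threshold`` is retained
    (threshold 1.0 keeps every component with nonzero eigenvalue).
    """
    X = train.values if isinstance(train, FeatureMatrix) else np.asarray(train, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit a transform")
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    Z = (X - means) / sds
    # Z has exact zero column means, so SVD of Z is the PCA of its covariance
    _, singular_values, vt = np.linalg.svd(Z, full_matrices=False)
    explained = singular_values**2
    total = explained.sum()
    if total == 0:  # all-constant input: keep a single trivial component
        ratio = np.zeros(1)
        components = _fix_component_signs(vt[:1])
    else:
        ratio = explained / total
        if variance_threshold >= 1.0:
            n_keep = int(np.sum(singular_values > singular_values[0] * 1e-12))
        else:
            n_keep = int(np.searchsorted(np.cumsum(ratio), variance_threshold) + 1)
            n_keep = min(n_keep, len(ratio))
        components = _fix_component_signs(vt[:n_keep])
        ratio = ratio[:n_keep]
    return FeatureTransform(
        z_means=means,
        z_sds=sds,
        pca_components=components,
        explained_variance_ratio=ratio,
        variance_threshold=variance_threshold,
    )


def apply_feature_transform(
    transform: FeatureTransform, matrix: FeatureMatrix | np.ndarray
) -> FeatureMatrix:
    """Project a feature matrix through a learned transform.

    Computes ``((values - z_means) / z_sds) @ pca_components.T``; purely
    deterministic, never refits.
    """
    if isinstance(matrix, FeatureMatrix):
        X, frame_rate = matrix.values, matrix.frame_rate
    else:
        X, frame_rate = np.asarray(matrix, float), float("nan")
    if X.shape[1] != len(transform.z_means):
        raise ValueError(
            f"matrix has {X.shape[1]} features but transform expects "
            f"{len(transform.z_means)}"
        )
    scores = ((X - transform.z_means) / transform.z_sds) @ transform.pca_components.T
    labels = [("pca", i) for i in range(scores.shape[1])]
    return FeatureMatrix(values=scores, feature_labels=labels, frame_rate=frame_rate)


def concat_sites(matrices: list[FeatureMatrix]) -> FeatureMatrix:
    """Horizontally concatenate per-site feature matrices (canonical order).

    All inputs must share the frame count; labels are preserved.
    """
    if not matrices:
        raise ValueError("need at least one feature matrix")
    counts = [m.n_frames for m in matrices]
    if len(set(counts)) > 1:
        detail = ", ".join(
            f"{m.feature_labels[0][0] or '?'}={c}" for m, c in zip(matrices, counts)
        )
        raise ValueError(f"frame-count mismatch across sites: {detail}")
    values = np.hstack([m.values for m in matrices])
    labels = [lab for m in matrices for lab in m.feature_labels]
    return FeatureMatrix(
        values=values, feature_labels=labels, frame_rate=matrices[0].frame_rate
    )
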