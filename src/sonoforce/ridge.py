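"""Closed-form ridge regression, prediction smoothing, and R-squared.

The coefficient vector solves (Xc'Xc + k*I) beta = Xc'y_c on centered
data, with the intercept recovered from the means; this is exactly the
minimizer of the penalized least-squares objective

    min over (beta0, beta) of  sum_i (y_i - beta0 - x_i'beta)^2
                               + k * sum_j beta_j^2

where only the slope coefficients are penalized.  No scaling happens
inside the fit: features are expected to be z-scored / PCA-projected
upstream, which is what gives the ridge parameter its meaning here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .features import FeatureMatrix, FeatureTransform

__all__ = [
    "RidgeModel",
    "DEFAULT_RIDGE_K",
    "DEFAULT_SMOOTH_WINDOW",
    "fit_ridge",
    "predict",
    "smooth_prediction",
    "r_squared",
]

DEFAULT_RIDGE_K = 5.0
DEFAULT_SMOOTH_WINDOW = 25


@dataclass
class RidgeModel:
    """Fitted ridge coefficients plus the feature transform used at fit time."""

    beta0: float
    beta: np.ndarray
    k: float = DEFAULT_RIDGE_K
    feature_transform: FeatureTransform | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)) or not np.isfinite(self.beta0):
            raise ValueError("coefficients must be finite")
        if self.k < 0:
            raise ValueError(f"ridge parameter must be >= 0, got {self.k}")

    def predict(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        return predict(self, X)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps({"beta0": self.beta0, "beta": self.beta.tolist(), "k": self.k})
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RidgeModel":
        d = json.loads(Path(path).read_text())
        return cls(beta0=d["beta0"], beta=np.asarray(d["beta"]), k=d["k"])


def _as_array(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def fit_ridge(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    k: float = DEFAULT_RIDGE_K,
    feature_transform: FeatureTransform | None = None,
) -> RidgeModel:
    """Fit ridge regression in closed form.

    X and y are centered; ``beta`` solves the symmetric positive
    (semi-)definite system (Xc'Xc + k*I) beta = Xc'y_c via a stable
    linear solve — never an explicit matrix inverse — and
    ``beta0 = mean(y) - mean(X) . beta``.  At k = 0 with a rank-deficient
    design the minimum-norm least-squares solution is returned with a
    warning.
    """
    Xa = _as_array(X)
    y = np.asarray(y, dtype=float)
    if Xa.ndim != 2:
        raise ValueError("X must be 2-D (observations x features)")
    if Xa.shape[0] != len(y):
        raise ValueError(f"X has {Xa.shape[0]} rows but y has {len(y)} entries")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    if k < 0:
        raise ValueError(f"ridge parameter must be >= 0, got {k}")
    x_means = Xa.mean(axis=0)
    y_mean = float(y.mean())
    Xc = Xa - x_means
    yc = y - y_mean
    p = Xa.shape[1]
    if k > 0:
        gram = Xc.T @ Xc + k * np.eye(p)
        beta = scipy.linalg.solve(gram, Xc.T @ yc, assume_a="pos")
    else:
        beta, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
        if rank < p:
            warnings.warn(
                f"design matrix is rank-deficient (rank {rank} < {p}) at k=0; "
                "returning the minimum-norm least-squares solution",
                stacklevel=2,
            )
    beta0 = y_mean - float(x_means @ beta)
    return RidgeModel(beta0=beta0, beta=beta, k=k, feature_transform=feature_transform)


def predict(model: RidgeModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Predicted force (N): beta0 + X . beta."""
    Xa = _as_array(X)
    if Xa.shape[1] != len(model.beta):
        raise ValueError(
            f"X has {Xa.shape[1]} features but model expects {len(model.beta)}"
        )
    return model.beta0 + Xa @ model.beta


def smooth_prediction(pred: np.ndarray, window: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average; windows shrink at the edges.

    Each output sample averages the input over a centered window of the
    requested size, truncated where the window would run past either end
    (keeping output length equal to input length with no phase lag).
    Window 1 is the identity.
    """
    if window < 1:
        raise ValueError(f"smoothing window must be >= 1, got {window}")
    pred = np.asarray(pred, dtype=float)
    n = len(pred)
    if window == 1 or n == 0:
        return pred.copy()
    idx = np.arange(n)
    lo = np.maximum(0, idx - (window - 1) // 2)
    hi = np.minimum(n, idx + window // 2 + 1)  # even windows trail by one
    csum = np.concatenate([[0.0], np.cumsum(pred)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (may be negative)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if len(y_true) < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 is undefined for zero-variance ground truth")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot
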