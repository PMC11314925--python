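"""Six-model comparison: 5-fold cross-validation and held-out-trial testing.

The model registry covers six input categories: the clinical-style
scanline, the four distributed sites pooled, and each site alone.  For
every model, frames from the training trials are pooled and randomly
partitioned into five near-equal folds; each fold is held out once while
a feature transform (z-score + PCA) and ridge model are fit on the rest.
The last trial is reserved for testing: the prediction is moving-average
filtered before the R-squared is computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    DEFAULT_OVERLAP,
    DEFAULT_VARIANCE_THRESHOLD,
    DEFAULT_WINDOW_PX,
    FeatureMatrix,
    apply_feature_transform,
    concat_sites,
    extract_features,
    fit_feature_transform,
)
from .phantom import CLINICAL_KEY, SITE_ORDER, Trial, TrialDataset
from .ridge import (
    DEFAULT_RIDGE_K,
    DEFAULT_SMOOTH_WINDOW,
    fit_ridge,
    predict,
    r_squared,
    smooth_prediction,
)

__all__ = [
    "ModelSpec",
    "EvaluationReport",
    "MODEL_SPECS",
    "default_model_specs",
    "assemble_features",
    "kfold_cv",
    "train_test",
    "run_comparison",
]


@dataclass(frozen=True)
class ModelSpec:
    """One model-input category: which image streams feed the features."""

    name: str
    sites: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sites) == 0:
            raise ValueError(f"model {self.name!r} needs at least one site")


#: the six model-input categories compared by the pipeline
MODEL_SPECS: tuple[ModelSpec, ...] = (
    ModelSpec("clinical", (CLINICAL_KEY,)),
    ModelSpec("distributed", SITE_ORDER),
    ModelSpec("vl", ("vl",)),
    ModelSpec("rf", ("rf",)),
    ModelSpec("mh", ("mh",)),
    ModelSpec("vmo", ("vmo",)),
)


def default_model_specs() -> tuple[ModelSpec, ...]:
    return MODEL_SPECS


def assemble_features(
    trials: list[Trial],
    spec: ModelSpec,
    window_px: int = DEFAULT_WINDOW_PX,
    overlap: float = DEFAULT_OVERLAP,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Pooled (features, force) over trials for one model's input streams."""
    blocks = []
    forces = []
    for trial in trials:
        missing = [s for s in spec.sites if s not in trial.images]
        if missing:
            raise ValueError(
                f"model {spec.name!r}: trial {trial.index} is missing image "
                f"streams {missing}"
            )
        per_site = [
            extract_features(trial.images[s], window_px=window_px, overlap=overlap)
            for s in spec.sites
        ]
        blocks.append(concat_sites(per_site))
        forces.append(trial.frame_force)
    values = np.vstack([b.values for b in blocks])
    fm = FeatureMatrix(
        values=values,
        feature_labels=blocks[0].feature_labels,
        frame_rate=blocks[0].frame_rate,
    )
    return fm, np.concatenate(forces)


def _fold_indices(
    n: int, k_folds: int, rng: np.random.Generator, blocked: bool
) -> list[np.ndarray]:
    """Partition 0..n-1 into k near-equal folds (sizes differ by <= 1)."""
    if blocked:
        # contiguous segments, leakage-resistant for autocorrelated frames
        return [np.asarray(f) for f in np.array_split(np.arange(n), k_folds)]
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k_folds)]


def kfold_cv(
    dataset: TrialDataset,
    spec: ModelSpec,
    k_folds: int = 5,
    k_ridge: float = DEFAULT_RIDGE_K,
    seed: int = 0,
    window_px: int = DEFAULT_WINDOW_PX,
    overlap: float = DEFAULT_OVERLAP,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    refit_transform_per_fold: bool = True,
    blocked: bool = False,
    smooth_window: int | None = None,
    y_permutation_seed: int | None = None,
) -> np.ndarray:
    """Fold-wise validation R-squared on the pooled training-trial frames.

    Frames from the training trials are pooled and randomly partitioned
    into ``k_folds`` near-equal subsets; each subset is held out once
    while the feature transform and ridge model are fit on the others.

    Parameters
    ----------
    refit_transform_per_fold
        If True (default, leakage-safe) the z-score/PCA transform is
        refit on each fold's training rows; if False it is fit once on
        all pooled frames before splitting.
    blocked
        Use contiguous-segment folds instead of uniform random frames.
    smooth_window
        Optionally moving-average the validation predictions before
        scoring (off by default; smoothing normally applies only to the
        held-out-trial test path).
    y_permutation_seed
        Diagnostic null model: permute the force targets against the
        features before cross-validating.
    """
    train = dataset.train_trials()
    if not train:
        raise ValueError("dataset has no training trials")
    X, y = assemble_features(train, spec, window_px=window_px, overlap=overlap)
    n = X.n_frames
    if n < k_folds:
        raise ValueError(f"{n} frames is fewer than {k_folds} folds")
    if y_permutation_seed is not None:
        y = np.random.default_rng(y_permutation_seed).permutation(y)
    rng = np.random.default_rng(seed)
    folds = _fold_indices(n, k_folds, rng, blocked)
    global_transform = (
        None
        if refit_transform_per_fold
        else fit_feature_transform(X, variance_threshold=variance_threshold)
    )
    scores = np.empty(k_folds)
    for i, held_out in enumerate(folds):
        fit_rows = np.setdiff1d(np.arange(n), held_out)
        transform = global_transform or fit_feature_transform(
            X.values[fit_rows], variance_threshold=variance_threshold
        )
        Z_fit = apply_feature_transform(transform, X.values[fit_rows])
        model = fit_ridge(Z_fit, y[fit_rows], k=k_ridge, feature_transform=transform)
        Z_val = apply_feature_transform(transform, X.values[held_out])
        pred = predict(model, Z_val)
        if smooth_window is not None:
            pred = smooth_prediction(pred, smooth_window)
        scores[i] = r_squared(y[held_out], pred)
    return scores


def train_test(
    dataset: TrialDataset,
    spec: ModelSpec,
    k_ridge: float = DEFAULT_RIDGE_K,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    window_px: int = DEFAULT_WINDOW_PX,
    overlap: float = DEFAULT_OVERLAP,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> float:
    """Held-out-trial test R-squared for one model.

    The transform and ridge model are fit on all training-trial frames;
    the test-trial prediction is moving-average filtered before scoring.
    Returns the mean over test trials (there is normally exactly one).
    """
    train = dataset.train_trials()
    test = dataset.test_trials()
    if not train:
        raise ValueError("dataset has no training trials")
    if not test:
        raise ValueError("dataset has no test trial")
    X_train, y_train = assemble_features(train, spec, window_px=window_px, overlap=overlap)
    transform = fit_feature_transform(X_train, variance_threshold=variance_threshold)
    Z_train = apply_feature_transform(transform, X_train)
    model = fit_ridge(Z_train, y_train, k=k_ridge, feature_transform=transform)
    scores = []
    for trial in test:
        X_test, y_test = assemble_features([trial], spec, window_px=window_px,
                                           overlap=overlap)
        pred = predict(model, apply_feature_transform(transform, X_test))
        pred = smooth_prediction(pred, smooth_window)
        scores.append(r_squared(y_test, pred))
    return float(np.mean(scores))


@dataclass
class EvaluationReport:
    """Per-model CV and test metrics, fully reproducible from seed + config."""

    subject_id: str
    seed: int
    config: dict
    cv_r2: dict[str, list[float]]  # model name -> fold scores
    test_r2: dict[str, float]

    def cv_mean(self, name: str) -> float:
        return float(np.mean(self.cv_r2[name]))

    def cv_sd(self, name: str) -> float:
        return float(np.std(self.cv_r2[name], ddof=1))

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "seed": self.seed,
            "config": self.config,
            "models": {
                name: {
                    "cv_r2_folds": list(map(float, folds)),
                    "cv_r2_mean": self.cv_mean(name),
                    "cv_r2_sd": self.cv_sd(name),
                    "test_r2": float(self.test_r2[name]),
                }
                for name, folds in self.cv_r2.items()
            },
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        d = json.loads(Path(path).read_text())
        return cls(
            subject_id=d["subject_id"],
            seed=d["seed"],
            config=d["config"],
            cv_r2={n: m["cv_r2_folds"] for n, m in d["models"].items()},
            test_r2={n: m["test_r2"] for n, m in d["models"].items()},
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat (model, fold, split, r2) table for external statistics."""
        rows = []
        for name, folds in self.cv_r2.items():
            for i, r2 in enumerate(folds):
                rows.append({"model": name, "fold": i, "split": "cv", "r2": float(r2)})
            rows.append(
                {"model": name, "fold": -1, "split": "test",
                 "r2": float(self.test_r2[name])}
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def run_comparison(
    dataset: TrialDataset,
    specs: tuple[ModelSpec, ...] | None = None,
    seed: int = 0,
    k_folds: int = 5,
    k_ridge: float = DEFAULT_RIDGE_K,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    window_px: int = DEFAULT_WINDOW_PX,
    overlap: float = DEFAULT_OVERLAP,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    blocked: bool = False,
) -> EvaluationReport:
    """Run CV + test for every model spec and assemble one report.

    Deterministic given ``seed``: each model's fold partition is drawn
    from a per-model child seed so that adding or removing models does
    not perturb the others.
    """
    if specs is None:
        specs = MODEL_SPECS
    root = np.random.SeedSequence(seed)
    model_seeds = root.spawn(len(specs))
    cv_r2: dict[str, list[float]] = {}
    test_r2: dict[str, float] = {}
    for spec, child in zip(specs, model_seeds):
        fold_seed = int(child.generate_state(1)[0])
        scores = kfold_cv(
            dataset,
            spec,
            k_folds=k_folds,
            k_ridge=k_ridge,
            seed=fold_seed,
            window_px=window_px,
            overlap=overlap,
            variance_threshold=variance_threshold,
            blocked=blocked,
        )
        cv_r2[spec.name] = [float(s) for s in scores]
        test_r2[spec.name] = train_test(
            dataset,
            spec,
            k_ridge=k_ridge,
            smooth_window=smooth_window,
            window_px=window_px,
            overlap=overlap,
            variance_threshold=variance_threshold,
        )
    config = {
        "k_folds": k_folds,
        "k_ridge": k_ridge,
        "smooth_window": smooth_window,
        "window_px": window_px,
        "overlap": overlap,
        "variance_threshold": variance_threshold,
        "blocked": blocked,
    }
    return EvaluationReport(
        subject_id=dataset.subject_id,
        seed=seed,
        config=config,
        cv_r2=cv_r2,
        test_r2=test_r2,
    )
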