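"""Pixelwise SVM classification of normalized QUS parametric maps.

Feature vectors are [hk_log10_alpha, nakagami_m, hnse] read at identical
pixel positions of the three normalized maps (values already in [0, 1],
so no further scaling).  Training samples 100 pixels per class per frame;
the RBF-kernel SVM's (C, gamma) are chosen by grid search with seeded
stratified 10-fold cross-validation, ties broken toward the smallest C
then the smallest gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .config import ParameterError
from .mapping import ParametricMap

FEATURE_ORDER = ("hk_log10_alpha", "nakagami_m", "hnse")

#: exponential (C, gamma) search grids
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 4))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 2, 4))


def _feature_stack(maps: dict[str, ParametricMap]) -> np.ndarray:
    missing = [k for k in FEATURE_ORDER if k not in maps]
    if missing:
        raise ParameterError(f"missing parametric maps: {missing}")
    layers = []
    for name in FEATURE_ORDER:
        values = maps[name].normalized_values
        if values is None:
            raise ParameterError(f"map {name} is not normalized")
        layers.append(values)
    shapes = {layer.shape for layer in layers}
    if len(shapes) != 1:
        raise ParameterError(f"maps are not co-registered: shapes {shapes}")
    return np.stack(layers, axis=-1)


@dataclass
class FeatureSet:
    """N x 3 features in [0, 1] with binary labels (1 = lesion/inclusion)."""

    features: np.ndarray
    labels: np.ndarray
    frame_ids: np.ndarray
    positions: np.ndarray  # (N, 2) row, col
    seed: object = None

    def __post_init__(self) -> None:
        if self.features.ndim != 2 or self.features.shape[1] != len(FEATURE_ORDER):
            raise ParameterError("features must be N x 3")

    def concat(self, other: "FeatureSet") -> "FeatureSet":
        return FeatureSet(
            features=np.vstack([self.features, other.features]),
            labels=np.concatenate([self.labels, other.labels]),
            frame_ids=np.concatenate([self.frame_ids, other.frame_ids]),
            positions=np.vstack([self.positions, other.positions]),
            seed=self.seed,
        )

    def subsample(self, n: int, seed=None) -> "FeatureSet":
        """Seeded class-balanced subsample to ``n`` rows."""
        if n >= len(self.labels):
            return self
        rng = np.random.default_rng(seed)
        keep = []
        for label in (0, 1):
            idx = np.flatnonzero(self.labels == label)
            take = min(len(idx), n // 2)
            keep.append(rng.choice(idx, size=take, replace=False))
        keep = np.sort(np.concatenate(keep))
        return FeatureSet(
            features=self.features[keep],
            labels=self.labels[keep],
            frame_ids=self.frame_ids[keep],
            positions=self.positions[keep],
            seed=seed,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(FEATURE_ORDER))
        df.insert(0, "frame_id", self.frame_ids)
        df["row"] = self.positions[:, 0]
        df["col"] = self.positions[:, 1]
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureSet":
        df = pd.read_csv(path)
        return cls(
            features=df[list(FEATURE_ORDER)].to_numpy(),
            labels=df["label"].to_numpy(),
            frame_ids=df["frame_id"].to_numpy(),
            positions=df[["row", "col"]].to_numpy(),
        )


def extract_region_features(
    maps: dict[str, ParametricMap],
    truth_mask: np.ndarray,
    n_per_class: int = 100,
    seed=None,
    frame_id=0,
) -> FeatureSet:
    """Sample ``n_per_class`` pixels per class and read the three features.

    Positions are drawn uniformly without replacement, anywhere inside each
    region; labels are 1 inside the truth mask, 0 outside.
    """
    stack = _feature_stack(maps)
    truth = np.asarray(truth_mask).astype(bool)
    if truth.shape != stack.shape[:2]:
        raise ParameterError("truth mask does not match map shape")
    rng = np.random.default_rng(seed)
    rows_list, labels_list = [], []
    for label, region in ((1, truth), (0, ~truth)):
        idx = np.flatnonzero(region.ravel())
        if len(idx) < n_per_class:
            raise ParameterError(
                f"class {label} has {len(idx)} pixels < n_per_class={n_per_class}"
            )
        pick = rng.choice(idx, size=n_per_class, replace=False)
        rows_list.append(np.column_stack(np.unravel_index(pick, truth.shape)))
        labels_list.append(np.full(n_per_class, label, dtype=int))
    positions = np.vstack(rows_list)
    labels = np.concatenate(labels_list)
    features = stack[positions[:, 0], positions[:, 1], :]
    return FeatureSet(
        features=features,
        labels=labels,
        frame_ids=np.full(len(labels), frame_id),
        positions=positions,
        seed=seed,
    )


@dataclass
class TrainedClassifier:
    """RBF-SVM with the grid-search record and its 10-fold CV accuracy."""

    model: SVC
    C: float
    gamma_kernel: float
    cv_accuracy: float
    grid_record: pd.DataFrame
    seed: object = None
    feature_order: tuple = FEATURE_ORDER


def train_classifier(
    train: FeatureSet,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    folds: int = 10,
    seed=None,
    cv_max_iter: int = 200_000,
    final_max_iter: int = 2_000_000,
) -> TrainedClassifier:
    """Grid-search (C, gamma) by seeded stratified k-fold CV and refit.

    CV fits are capped at ``cv_max_iter`` SMO iterations: ill-conditioned
    corners of the exponential grid (large C with a wide kernel on
    overlapping classes) otherwise dominate the search time while never
    winning the selection.
    """
    X, y = train.features, train.labels
    if len(np.unique(y)) < 2:
        raise ParameterError("training set must contain both classes")
    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise ParameterError("search grids must be nonempty")
    n_folds = min(folds, int(np.bincount(y).min()))
    if n_folds < 2:
        raise ParameterError("too few samples per class for cross-validation")

    seed_int = int(np.random.default_rng(seed).integers(2**31 - 1))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed_int)
    splits = list(skf.split(X, y))

    records = []
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for C in C_grid:
            for g in gamma_grid:
                correct = 0
                for tr_idx, te_idx in splits:
                    clf = SVC(
                        kernel="rbf", C=C, gamma=g,
                        max_iter=cv_max_iter, cache_size=500,
                    )
                    clf.fit(X[tr_idx], y[tr_idx])
                    correct += int((clf.predict(X[te_idx]) == y[te_idx]).sum())
                acc = correct / len(y)
                records.append({"C": C, "gamma": g, "cv_accuracy": acc})
                # ties broken toward smaller C, then smaller gamma (scan order)
                if best is None or acc > best[0]:
                    best = (acc, C, g)
        cv_accuracy, C_best, g_best = best
        final = SVC(
            kernel="rbf", C=C_best, gamma=g_best,
            max_iter=final_max_iter, cache_size=500,
        )
        final.fit(X, y)
    return TrainedClassifier(
        model=final,
        C=C_best,
        gamma_kernel=g_best,
        cv_accuracy=cv_accuracy,
        grid_record=pd.DataFrame(records),
        seed=seed,
    )


def predict_pixelwise(
    maps: dict[str, ParametricMap],
    classifier: TrainedClassifier,
    chunk: int = 200_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify every pixel; returns (binary mask, decision-score map)."""
    stack = _feature_stack(maps)
    shape = stack.shape[:2]
    X = stack.reshape(-1, stack.shape[-1])
    labels = np.empty(len(X), dtype=np.uint8)
    scores = np.empty(len(X))
    for start in range(0, len(X), chunk):
        sl = slice(start, start + chunk)
        scores[sl] = classifier.model.decision_function(X[sl])
        labels[sl] = (scores[sl] > 0).astype(np.uint8)
    return labels.reshape(shape), scores.reshape(shape)
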