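"""PCA + random-forest behavior classifiers for both plate formats.

The pipeline trains one model per plate format over aligned, normalized
behavior windows.  Training is deliberately plain: a stratified 90/10
split, PCA fit on the training split only (random state 2023, no
whitening, retaining components for 95% of the variance), and a random
forest on the projected features.  No hyperparameter search is performed.
The two plate formats differ only in their class set — 24-well resolves
scoot and turn, 96-well merges them into "movement" — and in the frozen
normalization scalars; there is no code fork.

A :class:`ClassifierBundle` is the deployable unit: normalization scalars,
fitted PCA, fitted forest, the ordered class set (which also fixes vote
tie-breaking downstream), the flattening-order descriptor, and training
provenance.  Saved as a directory of JSON metadata plus joblib artifacts.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import train_test_split

from . import __version__
from .features import DEFAULT_WINDOW, FeatureMatrix, flatten_windows
from .smoothing import UNKNOWN

PCA_SEED = 2023
PCA_VARIANCE = 0.95
FLATTEN_ORDER = "timepoint-major,keypoint,(x,y)"


class StratificationError(ValueError):
    pass


class ShapeError(ValueError):
    pass


@dataclass(frozen=True)
class ClassSet:
    """Ordered behavior labels for one plate format.

    The order is load-bearing: majority voting breaks ties by it, with
    stationary first so ties default to the least eventful call.
    """

    plate_format: int
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("class labels must be unique")

    @classmethod
    def for_plate(cls, plate_format: int) -> "ClassSet":
        if plate_format == 24:
            return cls(24, ("stationary", "scoot", "turn", "AsLB", "VsLB"))
        if plate_format == 96:
            return cls(96, ("stationary", "movement", "AsLB", "VsLB"))
        raise ValueError(f"plate_format must be 24 or 96, got {plate_format}")


@dataclass
class ClassifierBundle:
    """Everything needed to reproduce training-time inference."""

    class_set: ClassSet
    norm_max: float
    norm_mean: float
    pca: PCA
    forest: RandomForestClassifier
    width: int = DEFAULT_WINDOW
    flatten_order: str = FLATTEN_ORDER
    provenance: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.width * 8 * 2

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "plate_format": self.class_set.plate_format,
            "labels": list(self.class_set.labels),
            "norm_max": self.norm_max,
            "norm_mean": self.norm_mean,
            "width": self.width,
            "flatten_order": self.flatten_order,
            "provenance": self.provenance,
        }
        (out_dir / "bundle.json").write_text(json.dumps(meta, indent=1))
        joblib.dump(self.pca, out_dir / "pca.joblib")
        joblib.dump(self.forest, out_dir / "forest.joblib")
        return out_dir

    @classmethod
    def load(cls, in_dir: str | Path) -> "ClassifierBundle":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "bundle.json").read_text())
        return cls(
            class_set=ClassSet(meta["plate_format"], tuple(meta["labels"])),
            norm_max=meta["norm_max"],
            norm_mean=meta["norm_mean"],
            pca=joblib.load(in_dir / "pca.joblib"),
            forest=joblib.load(in_dir / "forest.joblib"),
            width=meta["width"],
            flatten_order=meta["flatten_order"],
            provenance=meta["provenance"],
        )


def split_dataset(
    vectors: np.ndarray,
    labels: np.ndarray,
    train_frac: float = 0.9,
    seed: int = 0,
):
    """Stratified train/test split (default 90%/10%), seeded.

    Returns ``(X_train, X_test, y_train, y_test)``.  Raises
    :class:`StratificationError` when any class has fewer than 2 examples.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise StratificationError(
            "every class needs >= 2 examples for a stratified split"
        )
    return train_test_split(
        np.asarray(vectors),
        labels,
        train_size=train_frac,
        random_state=seed,
        stratify=labels,
    )


def train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    class_set: ClassSet,
    stats: tuple[float, float],
    pca_seed: int = PCA_SEED,
    rfc_seed: int = 0,
    n_estimators: int = 100,
    pca_variance: float = PCA_VARIANCE,
) -> ClassifierBundle:
    """Fit PCA (training data only) then the random forest; return a bundle.

    ``stats`` are the frozen (norm_max, norm_mean) scalars the training
    vectors were normalized with; they travel with the bundle so inference
    reproduces training-time scaling.
    """
    X_train = np.asarray(X_train)
    y_train = np.asarray(y_train)
    unknown = set(y_train) - set(class_set.labels)
    if unknown:
        raise ValueError(f"labels outside class set: {sorted(unknown)}")
    pca = PCA(
        n_components=pca_variance,
        whiten=False,
        random_state=pca_seed,
        svd_solver="full",
    ).fit(X_train)
    Z = pca.transform(X_train)
    forest = RandomForestClassifier(
        n_estimators=n_estimators, criterion="gini", random_state=rfc_seed
    ).fit(Z, y_train)
    counts = pd.Series(y_train).value_counts().to_dict()
    return ClassifierBundle(
        class_set=class_set,
        norm_max=float(stats[0]),
        norm_mean=float(stats[1]),
        pca=pca,
        forest=forest,
        provenance={
            "training_counts": {str(k): int(v) for k, v in counts.items()},
            "pca_seed": pca_seed,
            "rfc_seed": rfc_seed,
            "n_estimators": n_estimators,
            "pca_variance_target": pca_variance,
            "pca_variance_retained": float(
                pca.explained_variance_ratio_.sum()
            ),
            "date": datetime.date.today().isoformat(),
            "software": f"fishbout {__version__}",
        },
    )


def _vectors_from(bundle: ClassifierBundle, windows) -> tuple[np.ndarray, np.ndarray]:
    """Normalize input windows / matrices with the bundle's frozen stats."""
    if isinstance(windows, FeatureMatrix):
        return windows.vectors, windows.usable
    if isinstance(windows, list):  # list of BehaviorWindow
        stack = np.stack([w.coords for w in windows])
        usable = np.array([w.usable for w in windows], dtype=bool)
        vectors = flatten_windows(stack) / bundle.norm_max - bundle.norm_mean
        return vectors, usable
    arr = np.asarray(windows, dtype=float)
    if arr.ndim == 4:  # raw aligned windows (n, W, 8, 2)
        vectors = flatten_windows(arr) / bundle.norm_max - bundle.norm_mean
        return vectors, np.ones(arr.shape[0], dtype=bool)
    return arr, np.ones(arr.shape[0], dtype=bool)  # pre-normalized vectors


def predict(
    bundle: ClassifierBundle, windows
) -> tuple[np.ndarray, np.ndarray]:
    """Label windows with the bundle; returns (labels, probabilities).

    Accepts a :class:`FeatureMatrix` (already normalized with the bundle's
    stats), a list of aligned :class:`BehaviorWindow`, a raw (n, W, 8, 2)
    aligned stack, or pre-normalized vectors.  Unusable windows get the
    label ``"unknown"`` and a zero probability row; probability columns
    follow ``bundle.class_set.labels`` order and sum to 1 per usable
    window.
    """
    vectors, usable = _vectors_from(bundle, windows)
    if vectors.shape[1] != bundle.n_features:
        raise ShapeError(
            f"feature length {vectors.shape[1]} != expected "
            f"{bundle.n_features}"
        )
    n = vectors.shape[0]
    labels = np.full(n, UNKNOWN, dtype=object)
    proba = np.zeros((n, len(bundle.class_set.labels)))
    if usable.any():
        Z = bundle.pca.transform(vectors[usable])
        raw = bundle.forest.predict_proba(Z)
        order = [
            list(bundle.forest.classes_).index(c)
            for c in bundle.class_set.labels
            if c in bundle.forest.classes_
        ]
        cols = [
            i
            for i, c in enumerate(bundle.class_set.labels)
            if c in bundle.forest.classes_
        ]
        proba[np.ix_(np.flatnonzero(usable), cols)] = raw[:, order]
        labels[usable] = bundle.forest.classes_[raw.argmax(axis=1)]
    return labels, proba


@dataclass
class EvaluationReport:
    """Confusion matrix and F1 scores on a held-out test set."""

    confusion: pd.DataFrame  # rows = true, cols = predicted, raw counts
    per_class_f1: dict[str, float | None]
    macro_f1: float

    def normalized_confusion(self) -> pd.DataFrame:
        """Row-normalized proportions (rows with no examples stay zero)."""
        totals = self.confusion.sum(axis=1)
        return self.confusion.div(totals.where(totals > 0, 1), axis=0)


def evaluate(
    bundle: ClassifierBundle,
    X_test: np.ndarray,
    y_test: np.ndarray,
) -> EvaluationReport:
    """Confusion matrix, per-class F1 and macro-F1 on held-out data.

    A class absent from the test set gets ``None`` (missing, not zero) as
    its per-class F1 and is excluded from the macro average.
    """
    y_test = np.asarray(y_test)
    pred, _ = predict(bundle, X_test)
    labels = list(bundle.class_set.labels)
    cm = confusion_matrix(y_test, pred, labels=labels)
    confusion = pd.DataFrame(cm, index=labels, columns=labels)
    present = [c for c in labels if (y_test == c).any()]
    scores = f1_score(
        y_test, pred, labels=present, average=None, zero_division=0
    )
    per_class = {c: None for c in labels}
    per_class.update(dict(zip(present, map(float, scores))))
    macro = float(np.mean(scores))
    return EvaluationReport(
        confusion=confusion, per_class_f1=per_class, macro_f1=macro
    )
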