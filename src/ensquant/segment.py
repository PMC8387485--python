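"""Trainable pixel classification of the fibre network, WEKA-style.

A multiscale feature bank (Gaussian smoothings, gradient magnitude,
Laplacian, Hessian eigenvalues, difference of Gaussians, structure-tensor
eigenvalues) feeds a random forest trained on sparse annotations.  A
non-learned Otsu auto-threshold is provided as a fallback segmenter and for
soma scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_laplace
from skimage.feature import hessian_matrix, hessian_matrix_eigvals, structure_tensor
from skimage.filters import (
    threshold_isodata,
    threshold_li,
    threshold_mean,
    threshold_otsu,
)
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "FeatureStack",
    "PixelClassifier",
    "compute_features",
    "train_classifier",
    "classify",
    "binarize_prob",
    "auto_threshold",
    "save_classifier",
    "load_classifier",
]

DEFAULT_SCALES = (1.0, 2.0, 4.0, 8.0)

_THRESHOLD_METHODS = {
    "otsu": threshold_otsu,
    "isodata": threshold_isodata,
    "li": threshold_li,
    "mean": threshold_mean,
}


@dataclass
class FeatureStack:
    """Per-pixel feature vectors: array of shape (rows, cols, n_features)."""

    data: np.ndarray
    feature_names: list[str]
    scales: tuple[float, ...]

    def as_matrix(self) -> np.ndarray:
        return self.data.reshape(-1, self.data.shape[-1])


def compute_features(image: np.ndarray, scales=DEFAULT_SCALES) -> FeatureStack:
    """Multiscale feature bank for pixel classification.

    Per scale sigma: Gaussian smoothing, Gaussian-derivative gradient
    magnitude, Laplacian of Gaussian, the two Hessian eigenvalues, a
    difference of Gaussians (sigma vs 2*sigma), and the two structure-tensor
    eigenvalues.  The raw intensity is always the first feature.  Feature
    order is fixed by ``feature_names`` so a serialized classifier fully
    describes its inputs.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("compute_features expects a 2D image")
    scales = tuple(float(s) for s in scales)
    if any(s <= 0 for s in scales) or list(scales) != sorted(scales):
        raise ValueError("scales must be positive and sorted ascending")
    if min(image.shape) < int(4 * max(scales)) + 1:
        raise ValueError(
            f"image {image.shape} smaller than largest feature kernel "
            f"(sigma {max(scales)})"
        )
    planes = [image]
    names = ["intensity"]
    for s in scales:
        sm = gaussian_filter(image, s, mode="reflect")
        planes.append(sm)
        names.append(f"gaussian_s{s:g}")
        planes.append(
            np.hypot(
                gaussian_filter(image, s, order=(0, 1), mode="reflect"),
                gaussian_filter(image, s, order=(1, 0), mode="reflect"),
            )
        )
        names.append(f"gradient_s{s:g}")
        planes.append(gaussian_laplace(image, s, mode="reflect"))
        names.append(f"laplacian_s{s:g}")
        H = hessian_matrix(
            image, sigma=s, order="rc", mode="reflect", use_gaussian_derivatives=True
        )
        e1, e2 = hessian_matrix_eigvals(H)
        planes.extend([e1, e2])
        names.extend([f"hessian1_s{s:g}", f"hessian2_s{s:g}"])
        planes.append(sm - gaussian_filter(image, 2 * s, mode="reflect"))
        names.append(f"dog_s{s:g}")
        A = structure_tensor(image, sigma=s, mode="reflect", order="rc")
        t1, t2 = _tensor_eigvals(*A)
        planes.extend([t1, t2])
        names.extend([f"st1_s{s:g}", f"st2_s{s:g}"])
    data = np.stack(planes, axis=-1).astype(np.float32)
    return FeatureStack(data=data, feature_names=names, scales=scales)


def _tensor_eigvals(arr, arc, acc):
    tr = arr + acc
    disc = np.sqrt(((arr - acc) / 2.0) ** 2 + arc**2)
    return tr / 2.0 + disc, tr / 2.0 - disc


@dataclass
class PixelClassifier:
    """Random forest plus the descriptor of the feature bank it was fit on."""

    model: RandomForestClassifier
    scales: tuple[float, ...]
    feature_names: list[str]
    classes: tuple[str, str] = ("background", "network")
    hyperparams: dict = field(default_factory=dict)
    training_accuracy: float | None = None

    def check_features(self, feats: FeatureStack) -> None:
        if list(feats.feature_names) != list(self.feature_names):
            raise ValueError("feature descriptor mismatch between image and classifier")


def _collect_training_pixels(images, annotations, scales):
    X, y = [], []
    for idx, image in enumerate(images):
        ann = annotations[annotations["image"] == idx]
        if ann.empty:
            continue
        feats = compute_features(image, scales)
        rows = ann["row"].to_numpy(int)
        cols = ann["col"].to_numpy(int)
        X.append(feats.data[rows, cols, :])
        y.append(ann["label"].to_numpy())
    if not X:
        raise ValueError("no annotated pixels found")
    return np.concatenate(X), np.concatenate(y)


def train_classifier(
    images,
    annotations: pd.DataFrame,
    scales=DEFAULT_SCALES,
    n_trees: int = 200,
    max_depth: int | None = None,
    seed: int = 0,
) -> PixelClassifier:
    """Fit the pixel classifier on sparse annotations.

    ``annotations`` is a table with columns ``image`` (index into
    ``images``), ``row``, ``col``, ``label`` (class name).  Both classes
    must be represented.  Training is deterministic for a fixed seed
    (single-threaded forest with ``random_state``).
    """
    if isinstance(images, np.ndarray) and images.ndim == 2:
        images = [images]
    X, y = _collect_training_pixels(images, annotations, scales)
    labels = np.unique(y)
    if len(labels) < 2:
        raise ValueError("annotations must cover at least two classes")
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    acc = float((model.predict(X) == y).mean())
    names = compute_features(np.zeros((64, 64)), scales).feature_names
    return PixelClassifier(
        model=model,
        scales=tuple(float(s) for s in scales),
        feature_names=names,
        classes=tuple(sorted(labels)),
        hyperparams={"n_trees": n_trees, "max_depth": max_depth, "seed": seed},
        training_accuracy=acc,
    )


def classify(
    image: np.ndarray, classifier: PixelClassifier, positive_class: str = "network"
) -> np.ndarray:
    """Per-pixel probability of the positive (network) class."""
    feats = compute_features(image, classifier.scales)
    classifier.check_features(feats)
    proba = classifier.model.predict_proba(feats.as_matrix())
    classes = list(classifier.model.classes_)
    if positive_class not in classes:
        raise ValueError(f"classifier has no class {positive_class!r}; has {classes}")
    col = classes.index(positive_class)
    return proba[:, col].reshape(image.shape)


def binarize_prob(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Mask = positive-class probability >= threshold."""
    return np.asarray(prob) >= threshold


def auto_threshold(image: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Non-learned foreground mask via a global histogram threshold."""
    image = np.asarray(image, dtype=np.float64)
    if method not in _THRESHOLD_METHODS:
        raise ValueError(f"unknown threshold method {method!r}")
    if np.ptp(image) == 0:
        raise ValueError("constant image: histogram threshold is degenerate")
    t = _THRESHOLD_METHODS[method](image)
    return image > t


def save_classifier(classifier: PixelClassifier, path) -> None:
    joblib.dump(
        {
            "format_version": 1,
            "model": classifier.model,
            "scales": classifier.scales,
            "feature_names": classifier.feature_names,
            "classes": classifier.classes,
            "hyperparams": classifier.hyperparams,
            "training_accuracy": classifier.training_accuracy,
        },
        str(path),
    )


def load_classifier(path) -> PixelClassifier:
    blob = joblib.load(str(path))
    if blob.get("format_version") != 1:
        raise ValueError("unrecognized classifier file version")
    return PixelClassifier(
        model=blob["model"],
        scales=tuple(blob["scales"]),
        feature_names=list(blob["feature_names"]),
        classes=tuple(blob["classes"]),
        hyperparams=dict(blob["hyperparams"]),
        training_accuracy=blob["training_accuracy"],
    )
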