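"""Linear-SVM comparison protocol over the five feature spaces.

Every feature space (autocorrelation, GLCM, LBP, distance
distribution, Ripley Khat) is evaluated with the same classifier — a
linear-kernel SVM — under stratified 10-fold cross-validation, swept
over PSF widths for the two binary tasks:

* ``density`` — C1 vs C2 (0.30 vs 0.33 markers/px^2);
* ``organization`` — C1 vs C3 (Gaussian cloud vs clustered field).

Per fold, z-score standardization and (for feature spaces wider than
five dimensions) PCA to 5 components are fitted on the training part
only.  Pointillist features are computed from detected markers by
default, mirroring the localize-then-describe pipeline; ground-truth
markers are available as an ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .detect import DetectorSettings, default_matching_tolerance, detect_markers, evaluate_detection
from .pointillist import DistanceDistributionFeatures, RipleyKFeatures
from .simulate import (
    DEFAULT_CROP_SIZE,
    DEFAULT_D_MIN,
    ClassParams,
    InvalidParameterError,
    MarkerField,
    PSFModel,
    default_class_params,
    render_image,
    sample_field,
)
from .textural import AutocorrelationFeatures, GLCMFeatures, LBPHistogramFeatures

#: the five compared feature spaces
METHODS = ("autocorrelation", "glcm", "lbp", "distance-distribution", "ripley")
TASKS: Mapping[str, tuple[str, str]] = {
    "density": ("C1", "C2"),
    "organization": ("C1", "C3"),
}

_CLASSIFIERS = {
    "svm": lambda: SVC(kernel="linear", C=1.0),
    "tree": lambda: DecisionTreeClassifier(random_state=0),
    "logistic": lambda: LogisticRegression(max_iter=1000),
    "knn": lambda: KNeighborsClassifier(),
}


def make_classifier_pipeline(
    n_features: int, classifier: str = "svm", reduce_dim: int = 5
) -> Pipeline:
    """Standardize -> (PCA to 5 when wider) -> classifier."""
    if classifier not in _CLASSIFIERS:
        raise InvalidParameterError(f"unknown classifier {classifier!r}")
    steps: list = [("scale", StandardScaler())]
    if n_features > reduce_dim:
        steps.append(("pca", PCA(n_components=reduce_dim, svd_solver="full")))
    steps.append(("clf", _CLASSIFIERS[classifier]()))
    return Pipeline(steps)


def crossval_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    classifier: str = "svm",
    seed: int = 0,
    reduce_dim: int = 5,
) -> tuple[float, float]:
    """Stratified k-fold accuracy (mean, std) with leakage-free scaling/PCA."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InvalidParameterError("need two classes")
    if counts.min() < folds:
        raise InvalidParameterError(f"folds={folds} exceeds smallest class size {counts.min()}")
    pipe = make_classifier_pipeline(X.shape[1], classifier, reduce_dim)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(pipe, X, y, cv=cv, scoring="accuracy")
    return float(scores.mean()), float(scores.std())


def holdout_accuracy(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    classifier: str = "svm",
    reduce_dim: int = 5,
) -> float:
    """Train on the training pool, report held-out test accuracy."""
    pipe = make_classifier_pipeline(np.asarray(X_train).shape[1], classifier, reduce_dim)
    pipe.fit(X_train, y_train)
    return float(pipe.score(X_test, y_test))


def permutation_null_accuracy(
    X: np.ndarray, y: np.ndarray, folds: int = 10, classifier: str = "svm", seed: int = 0
) -> tuple[float, float]:
    """Cross-validated accuracy after shuffling labels: the chance level."""
    rng = np.random.default_rng(seed)
    y_perm = rng.permutation(np.asarray(y))
    return crossval_accuracy(X, y_perm, folds=folds, classifier=classifier, seed=seed)


# ---------------------------------------------------------------------------
# in-memory experiment pipeline
# ---------------------------------------------------------------------------


@dataclass
class ConditionData:
    """Rendered images + detected marker fields for one (class, sigma)."""

    class_id: str
    sigma_psf: float
    images: list = field(default_factory=list)  # CellImage
    markers: list = field(default_factory=list)  # MarkerField (detected or truth)


def _condition_rng(seed: int, class_id: str, sigma_psf: float, index: int) -> np.random.Generator:
    ent = [int(seed), sum(ord(c) for c in class_id), int(round(sigma_psf * 1_000_000)), index]
    return np.random.default_rng(np.random.SeedSequence(ent))


def simulate_condition(
    class_id: str,
    sigma_psf: float,
    n_images: int,
    seed: int = 0,
    crop_size: int = DEFAULT_CROP_SIZE,
    class_params: Mapping[str, ClassParams] | None = None,
    detector: DetectorSettings | None = None,
    use_truth: bool = False,
) -> ConditionData:
    """Simulate, render and localize ``n_images`` images of one class at
    one PSF width.  ``use_truth=True`` substitutes ground-truth markers
    for detections (ablation)."""
    params = (class_params or {}).get(class_id) or default_class_params(class_id)
    psf = PSFModel(sigma_psf=float(sigma_psf))
    cond = ConditionData(class_id=class_id, sigma_psf=float(sigma_psf))
    for i in range(n_images):
        rng = _condition_rng(seed, class_id, sigma_psf, i)
        fld = sample_field(params, rng)
        img = render_image(fld, psf, crop=crop_size)
        cond.images.append(img)
        if use_truth:
            cond.markers.append(img.truth_in_crop())
        else:
            cond.markers.append(detect_markers(img, sigma_psf, detector).detected)
    return cond


_EXTRACTORS = {
    "autocorrelation": lambda cond, kw: AutocorrelationFeatures().fit([]).transform(cond.images),
    "glcm": lambda cond, kw: GLCMFeatures(**kw.get("glcm", {})).fit([]).transform(cond.images),
    "lbp": lambda cond, kw: LBPHistogramFeatures(**kw.get("lbp", {})).fit([]).transform(cond.images),
    "distance-distribution": lambda cond, kw: DistanceDistributionFeatures()
    .fit([])
    .transform(cond.markers),
    "ripley": lambda cond, kw: RipleyKFeatures(**kw.get("ripley", {}))
    .fit([])
    .transform(cond.markers),
}


def condition_features(cond: ConditionData, method: str, **feature_kw) -> np.ndarray:
    """Feature matrix of one condition for one method (LBP stays at its
    native 256 bins; the per-fold PCA happens inside the classifier
    pipeline)."""
    if method not in _EXTRACTORS:
        raise InvalidParameterError(f"unknown method {method!r}")
    return _EXTRACTORS[method](cond, feature_kw)


def run_sweep(
    sigma_psf: Sequence[float],
    methods: Sequence[str] = METHODS,
    tasks: Sequence[str] = ("density", "organization"),
    n_images_per_class: int = 200,
    seed: int = 0,
    folds: int = 10,
    classifier: str = "svm",
    d_min: float = DEFAULT_D_MIN,
    crop_size: int = DEFAULT_CROP_SIZE,
    use_truth: bool = False,
    class_params: Mapping[str, ClassParams] | None = None,
    detector: DetectorSettings | None = None,
    feature_kw: Mapping | None = None,
) -> pd.DataFrame:
    """One report row per (task, method, sigma_psf): cross-validated
    accuracy mean +/- std under the shared linear-SVM protocol."""
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise InvalidParameterError(f"unknown methods: {unknown}")
    bad_tasks = [t for t in tasks if t not in TASKS]
    if bad_tasks:
        raise InvalidParameterError(f"unknown tasks: {bad_tasks}")
    feature_kw = dict(feature_kw or {})
    needed_classes = sorted({c for t in tasks for c in TASKS[t]})
    rows = []
    for sigma in sigma_psf:
        conds = {
            c: simulate_condition(
                c, sigma, n_images_per_class, seed, crop_size, class_params, detector, use_truth
            )
            for c in needed_classes
        }
        feats: dict[tuple[str, str], np.ndarray] = {}
        for task in tasks:
            ca, cb = TASKS[task]
            for method in methods:
                for c in (ca, cb):
                    if (c, method) not in feats:
                        feats[(c, method)] = condition_features(conds[c], method, **feature_kw)
                X = np.vstack([feats[(ca, method)], feats[(cb, method)]])
                y = np.array([0] * n_images_per_class + [1] * n_images_per_class)
                mean, std = crossval_accuracy(X, y, folds=folds, classifier=classifier, seed=seed)
                rows.append(
                    {
                        "task": task,
                        "method": method,
                        "sigma_psf": float(sigma),
                        "k": d_min / float(sigma),
                        "accuracy_mean": mean,
                        "accuracy_std": std,
                        "n_train": 2 * n_images_per_class,
                        "n_test": 0,
                        "folds": folds,
                    }
                )
    return pd.DataFrame(rows)


def detection_rate_curve(
    sigma_psf: Sequence[float],
    class_id: str = "C1",
    n_images: int = 20,
    seed: int = 0,
    crop_size: int = DEFAULT_CROP_SIZE,
    d_min: float = DEFAULT_D_MIN,
    detector: DetectorSettings | None = None,
    tol: float | None = None,
) -> pd.DataFrame:
    """Mean detection rate (recall vs ground truth) per PSF width —
    the detection-performance curve of the surrogate localizer."""
    rows = []
    for sigma in sigma_psf:
        rates = []
        cond = simulate_condition(
            class_id, sigma, n_images, seed, crop_size, detector=detector
        )
        for img, det in zip(cond.images, cond.markers):
            truth = img.truth_in_crop()
            t = tol if tol is not None else default_matching_tolerance(sigma)
            score = evaluate_detection(det, truth, t)
            rates.append(score.detection_rate)
        rows.append(
            {
                "class_id": class_id,
                "sigma_psf": float(sigma),
                "k": d_min / float(sigma),
                "detection_rate": float(np.mean(rates)),
                "n_images": n_images,
            }
        )
    return pd.DataFrame(rows)
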