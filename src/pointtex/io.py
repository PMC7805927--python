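"""Configuration, file formats and manifests.

A single YAML file configures the whole experiment; every default
equals the study's printed parameters (3,000 markers, 300x10 clusters,
mu_D = 35 px, 256x256 frame, 72x72 texture windows, 5 features, 10
folds, 11 PSF widths, d_min = 1.02).  Unknown keys are rejected so
typos fail loudly.  Coordinates travel as CSV (header ``x,y``, 1-based
pixel units), images as single-channel float32 TIFF, features and
reports as CSV, manifests and PCA loadings as JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .detect import DetectorSettings
from .simulate import (
    DEFAULT_CROP_SIZE,
    DEFAULT_D_MIN,
    CellImage,
    ClassParams,
    InvalidParameterError,
    SimulationConfig,
    default_class_params,
    default_sigma_grid,
)

logger = logging.getLogger("pointtex")

__version__ = "0.1.0"


class ConfigError(ValueError):
    """A configuration file violates the schema."""


@dataclass(frozen=True)
class FeatureSettings:
    glcm_distance: int = 1
    glcm_levels: int = 32
    window_size: int = 72  # GLCM window and LBP region side
    k_radius_points: int = 100
    candidate_families: tuple[str, ...] | None = None
    use_truth_markers: bool = False  # ablation: bypass the detector


@dataclass(frozen=True)
class ClassificationSettings:
    folds: int = 10
    classifier: str = "svm"
    scale: str = "small"  # small | full (the complete 4,000/500 protocol)
    n_images_per_class_small: int = 200


@dataclass(frozen=True)
class ExperimentConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detector: DetectorSettings = field(default_factory=DetectorSettings)
    features: FeatureSettings = field(default_factory=FeatureSettings)
    classification: ClassificationSettings = field(default_factory=ClassificationSettings)
    seed: int = 0


# ---------------------------------------------------------------------------
# (de)serialization with unknown-key rejection
# ---------------------------------------------------------------------------


def _build(cls, data: Mapping, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{path}'")
    return data


def _config_from_dict(data: Mapping | None) -> ExperimentConfig:
    data = dict(data or {})
    _build(ExperimentConfig, data, "")
    sim_d = dict(data.get("simulation") or {})
    _build(SimulationConfig, sim_d, "simulation")
    if "class_params" in sim_d:
        cp = {}
        for cid, pd_ in sim_d["class_params"].items():
            base = dataclasses.asdict(default_class_params(cid))
            _build(ClassParams, pd_, f"simulation.class_params.{cid}")
            base.update(pd_)
            cp[cid] = ClassParams(**base)
        sim_d["class_params"] = cp
    if "sigma_psf" in sim_d:
        sim_d["sigma_psf"] = tuple(float(s) for s in sim_d["sigma_psf"])
    sim = SimulationConfig(**sim_d)
    det = DetectorSettings(**_build(DetectorSettings, dict(data.get("detector") or {}), "detector"))
    feat_d = dict(data.get("features") or {})
    _build(FeatureSettings, feat_d, "features")
    if feat_d.get("candidate_families") is not None:
        feat_d["candidate_families"] = tuple(feat_d["candidate_families"])
    feat = FeatureSettings(**feat_d)
    clf = ClassificationSettings(
        **_build(ClassificationSettings, dict(data.get("classification") or {}), "classification")
    )
    return ExperimentConfig(
        simulation=sim, detector=det, features=feat, classification=clf,
        seed=int(data.get("seed", 0)),
    )


def config_to_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["simulation"]["sigma_psf"] = [float(s) for s in cfg.simulation.sigma_psf]
    return d


def load_config(path: str | Path | None) -> ExperimentConfig:
    """Load and validate a YAML experiment config; an empty (or absent)
    file yields the full default configuration — the study's printed
    parameters."""
    if path is None:
        return ExperimentConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _config_from_dict(data)


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable digest of the canonicalized config."""
    payload = json.dumps(config_to_dict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)  # stage -> {inputs, outputs, timestamp}

    def record(self, stage: str, inputs: Sequence[str], outputs: Sequence[str]) -> None:
        self.stages[stage] = {
            "inputs": list(map(str, inputs)),
            "outputs": list(map(str, outputs)),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


# ---------------------------------------------------------------------------
# real-image ingestion
# ---------------------------------------------------------------------------


def ingest_real_images(directory: str | Path) -> list[tuple[CellImage, str]]:
    """Load user-supplied single-cell images for the feature path.

    Immediate subdirectories are class labels; TIFF and PNG files are
    accepted.  Multi-channel or empty files are skipped with a warning
    (an error is raised only when nothing loads).  Intensities are
    min-max normalized to [0, 1] per image.
    """
    import imageio.v3 as iio
    import tifffile

    root = Path(directory)
    if not root.is_dir():
        raise InvalidParameterError(f"{root} is not a directory")
    out: list[tuple[CellImage, str]] = []
    subdirs = [d for d in sorted(root.iterdir()) if d.is_dir()] or [root]
    for sub in subdirs:
        label = sub.name if sub != root else ""
        for f in sorted(sub.iterdir()):
            if f.suffix.lower() not in (".tif", ".tiff", ".png"):
                continue
            try:
                arr = (
                    tifffile.imread(f)
                    if f.suffix.lower() in (".tif", ".tiff")
                    else np.asarray(iio.imread(f))
                )
            except Exception as exc:
                warnings.warn(f"skipping unreadable {f.name}: {exc}", stacklevel=2)
                continue
            if arr.ndim != 2 or arr.size == 0:
                warnings.warn(f"skipping non-single-channel {f.name}", stacklevel=2)
                continue
            arr = arr.astype(float)
            lo, hi = arr.min(), arr.max()
            if hi > lo:
                arr = (arr - lo) / (hi - lo)
            else:
                arr = np.zeros_like(arr)
            out.append((CellImage(pixels=arr, source="real"), label))
    if not out:
        raise InvalidParameterError(f"no usable images under {root}")
    logger.info("ingested %d real images from %s", len(out), root)
    return out


# ---------------------------------------------------------------------------
# features table
# ---------------------------------------------------------------------------


def features_dataframe(
    images: Sequence[CellImage],
    markers: Sequence,
    labels: Sequence[str],
    sigma_psf: float,
    methods: Sequence[str],
    d_min: float = DEFAULT_D_MIN,
    fit_mask: np.ndarray | None = None,
    feature_kw: Mapping | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Flat features table (image_id, method, f1..f5, label, sigma_psf, k).

    Feature spaces wider than 5 (the LBP histogram) are reduced by PCA
    whose projection is fitted on the rows selected by ``fit_mask``
    (the training split); the loadings are returned for persistence.
    """
    from .classify import ConditionData, condition_features
    from .textural import pca_reduce

    cond = ConditionData("", sigma_psf, list(images), list(markers))
    k = d_min / sigma_psf if sigma_psf > 0 else float("inf")
    rows, loadings = [], {}
    for method in methods:
        X = condition_features(cond, method, **(dict(feature_kw or {})))
        if X.shape[1] > 5:
            fit_idx = None if fit_mask is None else np.flatnonzero(fit_mask)
            X, pca = pca_reduce(X, 5, fit_indices=fit_idx)
            loadings[method] = {
                "components": pca.components_.tolist(),
                "mean": pca.mean_.tolist(),
                "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
            }
        for i, (vec, label) in enumerate(zip(X, labels)):
            row = {"image_id": i, "method": method, "label": label,
                   "sigma_psf": sigma_psf, "k": k}
            row.update({f"f{j + 1}": float(v) for j, v in enumerate(vec)})
            rows.append(row)
    cols = ["image_id", "method", "f1", "f2", "f3", "f4", "f5", "label", "sigma_psf", "k"]
    return pd.DataFrame(rows)[cols], loadings
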