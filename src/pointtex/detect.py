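"""Spot localization and detection scoring.

The detector is a scale-matched Laplacian-of-Gaussian (LoG) blob
finder: the image is filtered with a negated LoG at the PSF scale,
local maxima above a relative response threshold are extracted, and
each peak is refined to sub-pixel precision by an intensity-weighted
centroid of the response in its neighborhood.  Only the PSF width
``sigma_psf`` is required as prior knowledge of the optical setup.

Scoring matches detections to ground truth one-to-one by greedy
nearest-neighbor pairing in increasing-distance order; the detection
rate is the matched fraction of true markers (recall).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_laplace
from skimage.feature import peak_local_max

from .simulate import CellImage, InvalidParameterError, MarkerField


@dataclass(frozen=True)
class DetectorSettings:
    """LoG detector knobs.

    ``threshold_rel`` — minimum peak response as a fraction of the
    per-image maximum response.  ``min_distance`` — local-maxima
    exclusion radius in pixels; None picks ``max(1, round(sigma))``.
    """

    threshold_rel: float = 0.10
    min_distance: int | None = None

    def exclusion_radius(self, sigma_psf: float) -> int:
        if self.min_distance is not None:
            return self.min_distance
        return max(1, int(round(sigma_psf)))


@dataclass(frozen=True)
class DetectionResult:
    detected: MarkerField  # provenance="detected"
    scores: np.ndarray  # per-detection LoG response
    settings: DetectorSettings
    sigma_psf: float


@dataclass(frozen=True)
class DetectionScore:
    n_true: int
    n_detected: int
    n_matched: int
    detection_rate: float
    tolerance: float


class LoGDetector:
    """Laplacian-of-Gaussian surrogate spot detector.

    Parameters mirror :class:`DetectorSettings`; ``detect`` is
    deterministic for a fixed input image.
    """

    def __init__(self, threshold_rel: float = 0.10, min_distance: int | None = None):
        self.threshold_rel = threshold_rel
        self.min_distance = min_distance

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold_rel": self.threshold_rel, "min_distance": self.min_distance}

    def set_params(self, **params) -> "LoGDetector":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def settings(self) -> DetectorSettings:
        return DetectorSettings(self.threshold_rel, self.min_distance)

    def detect(self, image: CellImage | np.ndarray, sigma_psf: float) -> DetectionResult:
        if sigma_psf <= 0:
            raise InvalidParameterError("sigma_psf must be > 0")
        pixels = image.pixels if isinstance(image, CellImage) else np.asarray(image, float)
        H, W = pixels.shape
        settings = self.settings
        empty = DetectionResult(
            MarkerField.empty("", (W, H)), np.empty(0), settings, sigma_psf
        )
        if not pixels.any():
            return empty
        # scale-normalized negated LoG: positive response on bright blobs
        response = -(sigma_psf**2) * gaussian_laplace(pixels, sigma=sigma_psf)
        excl = settings.exclusion_radius(sigma_psf)
        peaks = peak_local_max(
            response,
            min_distance=excl,
            threshold_rel=settings.threshold_rel,
            exclude_border=False,
        )
        if peaks.shape[0] == 0:
            return empty
        rows, cols = peaks[:, 0], peaks[:, 1]
        scores = response[rows, cols]
        ref_r, ref_c = _refine_centroids(response, rows, cols, sigma_psf)
        coords = np.column_stack([ref_c + 1.0, ref_r + 1.0])  # 1-based (x, y)
        coords[:, 0] = np.clip(coords[:, 0], 1, W)
        coords[:, 1] = np.clip(coords[:, 1], 1, H)
        field = MarkerField(coords, "", (W, H), provenance="detected")
        return DetectionResult(field, scores, settings, sigma_psf)


def _refine_centroids(
    response: np.ndarray, rows: np.ndarray, cols: np.ndarray, sigma_psf: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sub-pixel refinement: weighted centroid of the clipped-positive
    response in a (2*ceil(sigma)+1)^2 neighborhood around each peak."""
    half = int(np.ceil(sigma_psf))
    w = 2 * half + 1
    padded = np.pad(np.clip(response, 0.0, None), half, mode="constant")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (w, w))
    patches = windows[rows, cols]  # (npeaks, w, w)
    offs = np.arange(-half, half + 1, dtype=float)
    mass = patches.sum(axis=(1, 2))
    mass = np.where(mass > 0, mass, 1.0)
    dr = (patches.sum(axis=2) @ offs) / mass
    dc = (patches.sum(axis=1) @ offs) / mass
    return rows + dr, cols + dc


def detect_markers(
    image: CellImage | np.ndarray,
    sigma_psf: float,
    settings: DetectorSettings | None = None,
) -> DetectionResult:
    """Functional wrapper over :class:`LoGDetector`."""
    settings = settings or DetectorSettings()
    det = LoGDetector(settings.threshold_rel, settings.min_distance)
    return det.detect(image, sigma_psf)


def evaluate_detection(
    result: DetectionResult | MarkerField, truth: MarkerField, tol: float
) -> DetectionScore:
    """Greedy one-to-one nearest matching within ``tol`` pixels.

    Candidate (truth, detection) pairs within tolerance are sorted by
    distance (ties broken by detection index) and accepted greedily so
    each truth marker and each detection is used at most once.
    """
    if tol <= 0:
        raise InvalidParameterError("tol must be > 0")
    if len(truth) == 0:
        raise InvalidParameterError("truth must be non-empty")
    detected = result.detected if isinstance(result, DetectionResult) else result
    n_true, n_det = len(truth), len(detected)
    if n_det == 0:
        return DetectionScore(n_true, 0, 0, 0.0, tol)

    from scipy.spatial import cKDTree

    tree = cKDTree(detected.coords)
    pairs = tree.query_ball_point(truth.coords, r=tol)
    cand = [
        (np.hypot(*(truth.coords[ti] - detected.coords[di])), di, ti)
        for ti, dis in enumerate(pairs)
        for di in dis
    ]
    cand.sort(key=lambda t: (t[0], t[1]))
    used_t: set[int] = set()
    used_d: set[int] = set()
    matched = 0
    for _, di, ti in cand:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        matched += 1
    return DetectionScore(n_true, n_det, matched, matched / n_true, tol)


def default_matching_tolerance(sigma_psf: float) -> float:
    """max(1, sigma_psf) px — matches should not be stricter than the PSF."""
    return max(1.0, float(sigma_psf))
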