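"""Textural feature spaces computed directly on the blurred intensity
image: autocorrelation, gray-level co-occurrence (GLCM/Haralick) and
local binary patterns (LBP), each reduced to exactly 5 features so all
method spaces are compared at the same dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.feature import graycomatrix
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .simulate import CellImage, InvalidParameterError

DEFAULT_WINDOW_SIZE = 72  # GLCM window / LBP region side, in pixels


def _pixels(image: CellImage | np.ndarray) -> np.ndarray:
    px = image.pixels if isinstance(image, CellImage) else np.asarray(image, float)
    if px.ndim != 2 or px.size == 0:
        raise InvalidParameterError("image must be a non-empty 2-D grid")
    return px


# ---------------------------------------------------------------------------
# autocorrelation (Wiener-Khinchin)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AutocorrSurface:
    """Circular autocorrelation of an image, zero lag at the center."""

    G: np.ndarray  # fftshifted autocorrelation surface
    power_spectrum: np.ndarray
    radial_profile: np.ndarray  # p(rho) at 1-px annular bins
    rho: np.ndarray

    @property
    def zero_lag(self) -> tuple[int, int]:
        return (self.G.shape[0] // 2, self.G.shape[1] // 2)


def autocorrelation(image: CellImage | np.ndarray) -> AutocorrSurface:
    """Circular autocorrelation via the Wiener-Khinchin identity:
    G = F^-1[|F[i]|^2], equal to the direct circular double sum
    G(a,b) = sum_xy i(x,y) i(x-a, y-b)."""
    px = _pixels(image)
    ps = np.abs(np.fft.fft2(px)) ** 2
    G = np.fft.ifft2(ps).real
    Gs = np.fft.fftshift(G)
    rho, prof = _radial_profile(Gs)
    return AutocorrSurface(G=Gs, power_spectrum=ps, radial_profile=prof, rho=rho)


def _radial_profile(surface: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Annular average of a centered surface at 1-px radius bins."""
    H, W = surface.shape
    cy, cx = H // 2, W // 2
    yy, xx = np.indices((H, W))
    r = np.hypot(yy - cy, xx - cx)
    bins = np.rint(r).astype(int)
    count = np.bincount(bins.ravel())
    total = np.bincount(bins.ravel(), weights=surface.ravel())
    prof = total / count
    return np.arange(len(prof), dtype=float), prof


@dataclass(frozen=True)
class TexturalFeatureVector:
    method: str  # autocorrelation | glcm | lbp
    values: np.ndarray  # exactly 5 finite reals
    provenance: str = "named"  # "named" or "pca"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, float)
        if vals.shape != (5,) or not np.all(np.isfinite(vals)):
            raise InvalidParameterError("feature vector must be 5 finite values")
        object.__setattr__(self, "values", vals)


def autocorr_features(surface: AutocorrSurface | CellImage | np.ndarray) -> TexturalFeatureVector:
    """Five radial-profile descriptors of the autocorrelation.

    (max value p(0); FWHM by linear interpolation of the half-maximum
    crossing; max and min finite-difference gradients of p; variance
    of the profile tail beyond twice the central peak's HWHM.)
    """
    if not isinstance(surface, AutocorrSurface):
        surface = autocorrelation(surface)
    p, rho = surface.radial_profile, surface.rho
    pmax = p[0]
    half = pmax / 2.0
    below = np.flatnonzero(p < half)
    if below.size == 0:
        warnings.warn("profile never crosses half maximum; FWHM set to full length", stacklevel=2)
        hwhm = float(rho[-1])
    else:
        j = below[0]
        # linear interpolation between the last point above and first below
        r0, r1, p0, p1 = rho[j - 1], rho[j], p[j - 1], p[j]
        hwhm = float(r0 + (p0 - half) / (p0 - p1) * (r1 - r0)) if p0 != p1 else float(r1)
    fwhm = 2.0 * hwhm
    grad = np.gradient(p, rho)
    tail = p[rho > 2.0 * hwhm]
    tail_var = float(np.var(tail)) if tail.size else 0.0
    return TexturalFeatureVector(
        method="autocorrelation",
        values=np.array([float(pmax), fwhm, float(grad.max()), float(grad.min()), tail_var]),
    )


# ---------------------------------------------------------------------------
# GLCM / Haralick
# ---------------------------------------------------------------------------

GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)  # 0, 45, 90, 135 degrees

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "max_correlation_coeff",
)

#: the five named coefficients used as the default GLCM feature space
GLCM_NAMED_TOP5 = ("contrast", "variance", "sum_variance", "difference_variance", "sum_average")


@dataclass(frozen=True)
class GLCMSet:
    """Per-window co-occurrence matrices, one per orientation."""

    matrices: np.ndarray  # (levels, levels, 1, n_angles), normalized
    distance: int
    levels: int
    window_size: int


def quantize(image: np.ndarray, levels: int = 32) -> np.ndarray:
    """Per-image min-max quantization to integer gray levels [0, levels)."""
    img = np.asarray(image, float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm_matrices(
    window: np.ndarray, distance: int = 1, levels: int = 32
) -> GLCMSet:
    """Symmetric, normalized co-occurrence matrices at the four angles."""
    q = window if window.dtype == np.uint8 else quantize(window, levels)
    mats = graycomatrix(
        q, distances=[distance], angles=list(GLCM_ANGLES), levels=levels,
        symmetric=True, normed=True,
    )
    return GLCMSet(matrices=mats, distance=distance, levels=levels, window_size=window.shape[0])


def haralick_coefficients(P: np.ndarray) -> np.ndarray:
    """The 14 classical Haralick coefficients of one normalized,
    symmetric co-occurrence matrix (gray levels indexed 1..Ng).

    The maximal correlation coefficient (f14) is guarded: degenerate
    matrices (fewer than two occupied gray levels) yield 0.
    """
    P = np.asarray(P, float)
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((i - mu_y) ** 2) @ py))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    # p_{x+y}(k), k = 2..2Ng ; p_{x-y}(k), k = 0..Ng-1
    ksum = (ii + jj).astype(int)
    kdiff = np.abs(ii - jj).astype(int)
    p_sum = np.bincount(ksum.ravel(), weights=P.ravel(), minlength=2 * Ng + 1)[2:]
    p_diff = np.bincount(kdiff.ravel(), weights=P.ravel(), minlength=Ng)
    ks = np.arange(2, 2 * Ng + 1, dtype=float)
    kd = np.arange(0, Ng, dtype=float)

    def entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    f1 = float((P**2).sum())
    f2 = float((kd**2) @ p_diff)
    f3 = (
        float((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y)
        if sd_x > 0 and sd_y > 0
        else 0.0
    )
    f4 = float((((ii - mu_x) ** 2) * P).sum())
    f5 = float((P / (1.0 + (ii - jj) ** 2)).sum())
    f6 = float(ks @ p_sum)
    f7 = float(((ks - f6) ** 2) @ p_sum)
    f8 = entropy(p_sum)
    f9 = entropy(P.ravel())
    mu_diff = float(kd @ p_diff)
    f10 = float(((kd - mu_diff) ** 2) @ p_diff)
    f11 = entropy(p_diff)
    # information measures of correlation
    with np.errstate(divide="ignore", invalid="ignore"):
        pxy = np.outer(px, py)
        mask = (P > 0) & (pxy > 0)
        hxy1 = float(-(P[mask] * np.log(pxy[mask])).sum())
        mask2 = pxy > 0
        hxy2 = float(-(pxy[mask2] * np.log(pxy[mask2])).sum())
    hx, hy = entropy(px), entropy(py)
    denom = max(hx, hy)
    f12 = (f9 - hxy1) / denom if denom > 0 else 0.0
    f13 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - f9)))))
    f14 = _max_correlation_coeff(P, px, py)
    return np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13, f14])


def _max_correlation_coeff(P: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """sqrt of the second-largest eigenvalue of Q(i,j) = sum_k
    P(i,k)P(j,k)/(px(i)py(k)); 0 for degenerate matrices."""
    occ = px > 0
    if occ.sum() < 2:
        return 0.0
    Psub = P[np.ix_(occ, occ)]
    pxs, pys = px[occ], py[occ]
    Q = (Psub / pxs[:, None]) @ (Psub / pys[:, None]).T
    try:
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))[::-1]
    except np.linalg.LinAlgError:
        return 0.0
    if len(ev) < 2:
        return 0.0
    return float(np.sqrt(max(0.0, min(ev[1], 1.0))))


def tile_windows(image: np.ndarray, size: int) -> list[np.ndarray]:
    """Non-overlapping, top-left-anchored tiles; partial edge tiles
    are discarded.  Errors when the image holds no full tile."""
    H, W = image.shape
    if size > H or size > W:
        raise InvalidParameterError("window larger than image")
    return [
        image[r : r + size, c : c + size]
        for r in range(0, H - size + 1, size)
        for c in range(0, W - size + 1, size)
    ]


def glcm_features(
    image: CellImage | np.ndarray,
    distance: int = 1,
    levels: int = 32,
    window_size: int = DEFAULT_WINDOW_SIZE,
    mode: str = "named",
) -> TexturalFeatureVector | np.ndarray:
    """GLCM/Haralick descriptor of an image.

    The image is tiled into non-overlapping ``window_size`` squares;
    per window the 14 Haralick coefficients are computed at the four
    orientations and averaged over angles, then averaged over windows.
    ``mode="named"`` (default) returns the five named coefficients
    (contrast, variance, sum variance, difference variance, sum
    average); ``mode="full"`` returns all 14 (for downstream PCA).
    """
    px = _pixels(image)
    q = quantize(px, levels)
    feats = []
    for win in tile_windows(q, window_size):
        mats = glcm_matrices(win, distance=distance, levels=levels).matrices
        per_angle = np.stack(
            [haralick_coefficients(mats[:, :, 0, a]) for a in range(mats.shape[3])]
        )
        feats.append(per_angle.mean(axis=0))
    mean14 = np.mean(feats, axis=0)
    if mode == "full":
        return mean14
    idx = [HARALICK_NAMES.index(n) for n in GLCM_NAMED_TOP5]
    return TexturalFeatureVector(method="glcm", values=mean14[idx])


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

# neighbor order: top-left then clockwise; bit n carries weight 2^n
LBP_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


def lbp_codes(image: np.ndarray) -> np.ndarray:
    """8-bit local binary pattern codes of the interior pixels.

    Bit n is set when the n-th neighbor (top-left, clockwise) is >=
    the center (ties set the bit: b(0) = 1).  Output is (H-2, W-2).
    """
    img = np.asarray(image, float)
    H, W = img.shape
    if H < 3 or W < 3:
        raise InvalidParameterError("image must be at least 3x3")
    center = img[1 : H - 1, 1 : W - 1]
    codes = np.zeros(center.shape, dtype=np.uint8)
    for n, (dr, dc) in enumerate(LBP_OFFSETS):
        nb = img[1 + dr : H - 1 + dr, 1 + dc : W - 1 + dc]
        codes |= ((nb >= center).astype(np.uint8)) << n
    return codes


def lbp_histogram(
    image: CellImage | np.ndarray, region_size: int = DEFAULT_WINDOW_SIZE
) -> np.ndarray:
    """Normalized 256-bin LBP code histogram, averaged over the image's
    non-overlapping ``region_size`` regions (codes computed on each
    region's interior)."""
    px = _pixels(image)
    hists = []
    for region in tile_windows(px, region_size):
        codes = lbp_codes(region)
        h = np.bincount(codes.ravel(), minlength=256).astype(float)
        hists.append(h / h.sum())
    return np.mean(hists, axis=0)


def lbp_features(
    images: Sequence[CellImage | np.ndarray],
    region_size: int = DEFAULT_WINDOW_SIZE,
    n_components: int = 5,
    fit_indices: Sequence[int] | None = None,
) -> tuple[np.ndarray, PCA]:
    """LBP histograms of a batch reduced to ``n_components`` by PCA.

    The projection is learned on ``fit_indices`` only (default: all),
    so held-out data can be transformed without leakage.
    """
    H = np.vstack([lbp_histogram(im, region_size) for im in images])
    return pca_reduce(H, n_components, fit_indices)


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------


def pca_reduce(
    table: np.ndarray, target_dim: int = 5, fit_indices: Sequence[int] | None = None
) -> tuple[np.ndarray, PCA]:
    """Reduce a per-image feature table to ``target_dim`` components.

    Centering and projection are learned on the rows named by
    ``fit_indices`` only (the training folds) and applied to every
    row; the fitted :class:`~sklearn.decomposition.PCA` is returned so
    its loadings can be persisted and reused on held-out data.
    """
    X = np.asarray(table, float)
    if X.ndim != 2 or X.shape[1] < target_dim:
        raise InvalidParameterError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else '?'} < target {target_dim}"
        )
    fit_rows = X if fit_indices is None else X[np.asarray(fit_indices, int)]
    if fit_rows.shape[0] == 0:
        raise InvalidParameterError("fit subset is empty")
    if fit_rows.shape[0] < target_dim:
        raise InvalidParameterError(
            f"fit subset of {fit_rows.shape[0]} rows cannot support {target_dim} components"
        )
    rank = np.linalg.matrix_rank(fit_rows - fit_rows.mean(axis=0))
    if rank < target_dim and fit_rows.shape[0] > target_dim:
        warnings.warn(
            f"fit subset rank {rank} < target dimension {target_dim}", stacklevel=2
        )
    pca = PCA(n_components=target_dim, svd_solver="full")
    pca.fit(fit_rows)
    return pca.transform(X), pca


# ---------------------------------------------------------------------------
# sklearn-style transformers
# ---------------------------------------------------------------------------


class AutocorrelationFeatures(TransformerMixin, BaseEstimator):
    """Stateless transformer: images -> (n, 5) autocorrelation features."""

    method = "autocorrelation"

    def fit(self, X, y=None):
        self.n_features_out_ = 5
        return self

    def transform(self, X: Sequence[CellImage | np.ndarray]) -> np.ndarray:
        return np.vstack([autocorr_features(im).values for im in X])

    def get_feature_names_out(self, input_features=None):
        return np.array(["max", "fwhm", "max_grad", "min_grad", "tail_var"])


class GLCMFeatures(TransformerMixin, BaseEstimator):
    """Transformer: images -> (n, 5) Haralick features.

    ``mode="named"`` emits the five named coefficients; ``mode="pca"``
    emits all 14 coefficients for PCA reduction inside a pipeline.
    """

    method = "glcm"

    def __init__(
        self,
        distance: int = 1,
        levels: int = 32,
        window_size: int = DEFAULT_WINDOW_SIZE,
        mode: str = "named",
    ):
        self.distance = distance
        self.levels = levels
        self.window_size = window_size
        self.mode = mode

    def fit(self, X, y=None):
        self.n_features_out_ = 5 if self.mode == "named" else 14
        return self

    def transform(self, X: Sequence[CellImage | np.ndarray]) -> np.ndarray:
        rows = []
        for im in X:
            out = glcm_features(
                im,
                distance=self.distance,
                levels=self.levels,
                window_size=self.window_size,
                mode="named" if self.mode == "named" else "full",
            )
            rows.append(out.values if isinstance(out, TexturalFeatureVector) else out)
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        if self.mode == "named":
            return np.array(GLCM_NAMED_TOP5)
        return np.array(HARALICK_NAMES)


class LBPHistogramFeatures(TransformerMixin, BaseEstimator):
    """Transformer: images -> (n, 256) normalized LBP histograms.

    Compose with :class:`~sklearn.decomposition.PCA` in a pipeline to
    reach the 5-dimensional comparison space; keeping the PCA in the
    pipeline confines its fit to the training folds.
    """

    method = "lbp"

    def __init__(self, region_size: int = DEFAULT_WINDOW_SIZE):
        self.region_size = region_size

    def fit(self, X, y=None):
        self.n_features_out_ = 256
        return self

    def transform(self, X: Sequence[CellImage | np.ndarray]) -> np.ndarray:
        return np.vstack([lbp_histogram(im, self.region_size) for im in X])

    def get_feature_names_out(self, input_features=None):
        return np.array([f"code_{i}" for i in range(256)])
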