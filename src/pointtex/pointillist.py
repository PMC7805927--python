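"""Pointillist feature spaces: distance-distribution parameters and
Besag-normalized Ripley K-curve descriptors of a marker field.

Two 5-dimensional descriptors are computed from localized marker
coordinates:

* **Distance distribution** — maximum-likelihood parameters of the
  families selected (by BIC over a pool of 16 common distributions)
  for three distance sets: Rayleigh scale ``sigma_R`` for inter-marker
  distances, exponential rate ``lambda_E`` for distances to the mean
  marker position, and the GEV triple ``(xi_G, sigma_G, mu_G)`` for
  nearest-neighbor distances.

* **Ripley K curve** — Ripley's K-function with the isotropic
  arc-fraction boundary correction on a rectangular window,
  variance-stabilized to Besag's L-form ``Khat(r) = sqrt(K(r)/pi) - r``
  (zero-centered under complete spatial randomness), summarized by its
  maximum, the pre-/post-peak extreme gradients, the argmax radius and
  the Spearman correlation of Khat with r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import scipy.stats as st
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import InvalidParameterError, MarkerField

# ---------------------------------------------------------------------------
# distance sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceSets:
    """The three distance samples extracted from a marker field."""

    pairwise: np.ndarray  # n(n-1)/2 inter-marker distances
    to_centroid: np.ndarray  # n distances to the mean marker position
    nearest_neighbor: np.ndarray  # n per-marker NN distances


def distance_sets(field: MarkerField) -> DistanceSets:
    """Euclidean pairwise, to-centroid and nearest-neighbor distances."""
    if len(field) < 2:
        raise InvalidParameterError("need >= 2 markers")
    pts = field.coords
    pw = pdist(pts)
    centroid = pts.mean(axis=0)
    to_c = np.hypot(*(pts - centroid).T)
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return DistanceSets(pairwise=pw, to_centroid=to_c, nearest_neighbor=d[:, 1])


# ---------------------------------------------------------------------------
# BIC model selection
# ---------------------------------------------------------------------------


class FitError(RuntimeError):
    """A maximum-likelihood fit failed; carries the family name."""

    def __init__(self, family: str, message: str = ""):
        self.family = family
        super().__init__(f"fit failed for family {family!r}" + (f": {message}" if message else ""))


@dataclass(frozen=True)
class FitCandidate:
    family: str
    params: tuple[float, ...]
    log_likelihood: float
    n_params: int
    n_obs: int
    bic: float


def bic_score(log_likelihood: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion: -2 ln L + p ln(nb)."""
    return -2.0 * log_likelihood + n_params * np.log(n_obs)


#: The 16-family candidate pool for BIC selection.  Positive-support
#: scale families are fitted with the location pinned at zero.
DEFAULT_FAMILIES: dict[str, tuple] = {
    "normal": (st.norm, {}),
    "lognormal": (st.lognorm, {"floc": 0}),
    "exponential": (st.expon, {"floc": 0}),
    "gamma": (st.gamma, {"floc": 0}),
    "weibull": (st.weibull_min, {"floc": 0}),
    "rayleigh": (st.rayleigh, {"floc": 0}),
    "gev": (st.genextreme, {}),
    "logistic": (st.logistic, {}),
    "log-logistic": (st.fisk, {"floc": 0}),
    "half-normal": (st.halfnorm, {"floc": 0}),
    "inverse-gaussian": (st.invgauss, {"floc": 0}),
    "nakagami": (st.nakagami, {"floc": 0}),
    "rician": (st.rice, {"floc": 0}),
    "birnbaum-saunders": (st.fatiguelife, {"floc": 0}),
    "t": (st.t, {}),
    "extreme-value": (st.gumbel_r, {}),
}


def fit_family(sample: np.ndarray, family: str) -> FitCandidate:
    """Maximum-likelihood fit of one named family; BIC per -2lnL + p ln nb."""
    dist, fixed = DEFAULT_FAMILIES[family]
    sample = np.asarray(sample, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            params = dist.fit(sample, **fixed)
        except Exception as exc:  # scipy raises a zoo of fit errors
            raise FitError(family, str(exc)) from exc
    loglik = float(np.sum(dist.logpdf(sample, *params)))
    if not np.isfinite(loglik):
        raise FitError(family, "non-finite log-likelihood")
    p = dist.numargs + 2 - len(fixed)
    return FitCandidate(
        family=family,
        params=tuple(float(v) for v in params),
        log_likelihood=loglik,
        n_params=p,
        n_obs=len(sample),
        bic=bic_score(loglik, p, len(sample)),
    )


def fit_and_select(
    sample: Sequence[float], candidates: Sequence[str] | None = None
) -> tuple[FitCandidate, list[FitCandidate]]:
    """Fit every candidate family and return (argmin-BIC, full table).

    Families that cannot be fitted on the sample (degenerate data,
    optimizer failure) are skipped with a warning; an error is raised
    only when no family fits.
    """
    sample = np.asarray(sample, float)
    if sample.size < 10:
        raise InvalidParameterError("need >= 10 observations")
    names = list(candidates) if candidates else list(DEFAULT_FAMILIES)
    if not names:
        raise InvalidParameterError("candidate list is empty")
    table: list[FitCandidate] = []
    for name in names:
        try:
            table.append(fit_family(sample, name))
        except FitError as err:
            warnings.warn(f"skipping family {name!r}: {err}", stacklevel=2)
    if not table:
        raise FitError("all", "no candidate family could be fitted")
    best = min(table, key=lambda c: c.bic)
    return best, table


# ---------------------------------------------------------------------------
# distance-distribution feature vector
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceFeatureVector:
    """(sigma_R, lambda_E, xi_G, sigma_G, mu_G); method id ``distance-distribution``."""

    sigma_R: float
    lambda_E: float
    xi_G: float
    sigma_G: float
    mu_G: float
    method: str = "distance-distribution"

    @property
    def values(self) -> np.ndarray:
        return np.array([self.sigma_R, self.lambda_E, self.xi_G, self.sigma_G, self.mu_G])


#: cap on the pairwise-distance sample used for the Rayleigh fit; above
#: it the sample is subsampled (the fit is insensitive at this size).
MAX_PAIRWISE_SAMPLE = 100_000


def distance_features(
    field: MarkerField, rng: np.random.Generator | None = None
) -> DistanceFeatureVector:
    """Fixed-family ML fits of the three distance sets.

    Rayleigh scale on inter-marker distances, exponential rate on
    centroid distances, GEV (shape reported in the standard xi = -c
    scipy convention) on nearest-neighbor distances.
    """
    sets = distance_sets(field)
    # coincident points yield zero distances, outside the support of the
    # zero-location scale families; they carry no distributional information
    pw = sets.pairwise[sets.pairwise > 0]
    if pw.size == 0:
        raise FitError("rayleigh", "all pairwise distances are zero")
    if pw.size > MAX_PAIRWISE_SAMPLE:
        rng = rng or np.random.default_rng(0)
        pw = rng.choice(pw, MAX_PAIRWISE_SAMPLE, replace=False)

    _, sigma_r = st.rayleigh.fit(pw, floc=0)
    _, expon_scale = st.expon.fit(sets.to_centroid, floc=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            c, loc, scale = st.genextreme.fit(sets.nearest_neighbor)
        except Exception as exc:
            raise FitError("gev", str(exc)) from exc
    for fam, vals in (
        ("rayleigh", (sigma_r,)),
        ("exponential", (expon_scale,)),
        ("gev", (c, loc, scale)),
    ):
        if not all(np.isfinite(v) for v in vals):
            raise FitError(fam, "non-finite parameter")
    if sigma_r <= 0 or expon_scale <= 0 or scale <= 0:
        raise FitError("scale", "non-positive fitted scale")
    return DistanceFeatureVector(
        sigma_R=float(sigma_r),
        lambda_E=float(1.0 / expon_scale),
        xi_G=float(-c),
        sigma_G=float(scale),
        mu_G=float(loc),
    )


# ---------------------------------------------------------------------------
# Ripley K / Besag L
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowGeometry:
    """Axis-aligned rectangular observation window."""

    xmin: float
    ymin: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidParameterError("window must have positive area")

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))

    @classmethod
    def from_image_dims(cls, dims: tuple[int, int]) -> "WindowGeometry":
        """The continuous support [1, M] x [1, N] of valid marker
        coordinates (width M-1 x N-1) — the window on which uniform
        fields are actually uniform."""
        M, N = dims
        return cls(1.0, 1.0, float(M - 1), float(N - 1))

    def contains(self, coords: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        x, y = coords[:, 0], coords[:, 1]
        return (
            (x >= self.xmin - atol)
            & (x <= self.xmin + self.width + atol)
            & (y >= self.ymin - atol)
            & (y <= self.ymin + self.height + atol)
        )


@dataclass(frozen=True)
class KFunctionCurve:
    radii: np.ndarray
    K: np.ndarray
    khat: np.ndarray | None
    n: int
    window: WindowGeometry
    pair_distances: np.ndarray | None = None
    pair_weights: np.ndarray | None = None


def default_radius_grid(window: WindowGeometry, n_points: int = 100) -> np.ndarray:
    """r from 0 to a quarter of the shorter window side."""
    return np.linspace(0.0, min(window.width, window.height) / 4.0, n_points)


def arc_inside_fraction(
    centers: np.ndarray, radii: np.ndarray, window: WindowGeometry
) -> np.ndarray:
    """Fraction of the circle ``|u - center| = r`` lying inside a
    rectangular window, by exact circle-rectangle arc geometry.

    For each window edge at distance d < r the circle loses an arc of
    angle 2*arccos(d/r); when the circle crosses a corner the two edge
    arcs overlap by max(0, a_i + a_j - pi/2), which is added back.
    """
    c = np.atleast_2d(centers)
    r = np.asarray(radii, float)
    dl = c[:, 0] - window.xmin
    dr_ = window.xmin + window.width - c[:, 0]
    db = c[:, 1] - window.ymin
    dt = window.ymin + window.height - c[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        angs = [
            np.arccos(np.clip(np.where(r > 0, d / np.maximum(r, 1e-300), np.inf), -1, 1))
            for d in (dl, dr_, db, dt)
        ]
    al, ar, ab, at = angs
    ext = 2.0 * (al + ar + ab + at)
    for a1, a2 in ((al, ab), (al, at), (ar, ab), (ar, at)):
        ext -= np.maximum(0.0, a1 + a2 - np.pi / 2.0)
    return np.clip(1.0 - ext / (2.0 * np.pi), 1e-12, 1.0)


def arc_inside_fraction_quadrature(
    center: np.ndarray,
    radius: float,
    window_contains,
    n_sectors: int = 4096,
) -> float:
    """Numerical angular quadrature fallback for non-rectangular windows:
    sample the circle at ``n_sectors`` angles and count points for which
    ``window_contains((x, y))`` is true."""
    if radius == 0:
        return 1.0
    theta = (np.arange(n_sectors) + 0.5) * (2.0 * np.pi / n_sectors)
    x = center[0] + radius * np.cos(theta)
    y = center[1] + radius * np.sin(theta)
    inside = np.fromiter((bool(window_contains((xi, yi))) for xi, yi in zip(x, y)), bool)
    return max(inside.mean(), 1e-12)


def ripley_k(
    field: MarkerField,
    window: WindowGeometry | None = None,
    radii: np.ndarray | None = None,
    correction: Literal["ripley", "none"] = "ripley",
    keep_pairs: bool = False,
) -> KFunctionCurve:
    """Ripley's K-function with the isotropic boundary correction.

    K(r) = |Omega| / (n(n-1)) * sum_{x != y} 1{|x-y| <= r} f(x, y)
    over ordered pairs, with f(x,y) = (P(x,y) + P(y,x)) / 2 and P the
    reciprocal of the in-window arc fraction of the circle centered at
    x through y.  Under CSR, E[K(r)] = pi r^2.
    """
    n = len(field)
    if n < 2:
        raise InvalidParameterError("need >= 2 markers")
    window = window or WindowGeometry.from_image_dims(field.image_dims)
    if not window.contains(field.coords).all():
        raise InvalidParameterError("all markers must lie inside the window")
    radii = default_radius_grid(window) if radii is None else np.asarray(radii, float)
    if np.any(np.diff(radii) <= 0):
        raise InvalidParameterError("radius grid must be strictly increasing")
    if radii[0] < 0 or radii[-1] > window.diagonal:
        raise InvalidParameterError("radii must lie in [0, window diagonal]")

    pts = field.coords
    ii, jj = np.triu_indices(n, k=1)
    d = pdist(pts)
    keep = d <= radii[-1]
    ii, jj, d = ii[keep], jj[keep], d[keep]
    if correction == "ripley":
        w = 0.5 * (
            1.0 / arc_inside_fraction(pts[ii], d, window)
            + 1.0 / arc_inside_fraction(pts[jj], d, window)
        )
    else:
        w = np.ones_like(d)
    # each unordered pair contributes twice (ordered sum), same weight
    bins = np.searchsorted(radii, d, side="left")
    contrib = np.bincount(bins, weights=2.0 * w, minlength=len(radii))[: len(radii)]
    K = window.area / (n * (n - 1)) * np.cumsum(contrib)
    return KFunctionCurve(
        radii=radii,
        K=K,
        khat=None,
        n=n,
        window=window,
        pair_distances=d if keep_pairs else None,
        pair_weights=w if keep_pairs else None,
    )


def besag_l(curve: KFunctionCurve) -> KFunctionCurve:
    """Besag's variance-stabilized normalization Khat = sqrt(K/pi) - r,
    zero-centered under complete spatial randomness."""
    if np.any(curve.K < 0):
        raise InvalidParameterError("K must be non-negative")
    khat = np.sqrt(curve.K / np.pi) - curve.radii
    return replace(curve, khat=khat)


@dataclass(frozen=True)
class KFeatureVector:
    """Five K-curve descriptors; method id ``ripley``."""

    max_khat: float
    max_gradient_pre_peak: float
    min_gradient_post_peak: float
    r_at_max: float
    spearman_khat_r: float
    method: str = "ripley"

    @property
    def values(self) -> np.ndarray:
        return np.array(
            [
                self.max_khat,
                self.max_gradient_pre_peak,
                self.min_gradient_post_peak,
                self.r_at_max,
                self.spearman_khat_r,
            ]
        )


def k_curve_features(curve: KFunctionCurve) -> KFeatureVector:
    """Summarize a Besag-normalized K curve by five scalars.

    Gradients are central finite differences (one-sided at the ends);
    argmax ties break toward the smallest radius; a constant curve has
    Spearman correlation defined as 0 (with a warning).
    """
    if curve.khat is None:
        curve = besag_l(curve)
    r, khat = curve.radii, curve.khat
    if len(r) < 3:
        raise InvalidParameterError("need >= 3 radii")
    grad = np.gradient(khat, r)
    imax = int(np.argmax(khat))
    pre = grad[: imax + 1]
    post = grad[imax:]
    if np.allclose(khat, khat[0]):
        warnings.warn("constant Khat curve; Spearman set to 0", stacklevel=2)
        rho = 0.0
    else:
        rho = float(st.spearmanr(khat, r).statistic)
    return KFeatureVector(
        max_khat=float(khat[imax]),
        max_gradient_pre_peak=float(pre.max()),
        min_gradient_post_peak=float(post.min()),
        r_at_max=float(r[imax]),
        spearman_khat_r=rho,
    )


# ---------------------------------------------------------------------------
# sklearn-style transformers
# ---------------------------------------------------------------------------


class DistanceDistributionFeatures(TransformerMixin, BaseEstimator):
    """Stateless transformer: marker fields -> (n, 5) distance features.

    Columns: sigma_R, lambda_E, xi_G, sigma_G, mu_G.
    """

    method = "distance-distribution"

    def __init__(self, subsample_seed: int = 0):
        self.subsample_seed = subsample_seed

    def fit(self, X: Sequence[MarkerField], y=None) -> "DistanceDistributionFeatures":
        self.n_features_out_ = 5
        return self

    def transform(self, X: Sequence[MarkerField]) -> np.ndarray:
        rng = np.random.default_rng(self.subsample_seed)
        return np.vstack([distance_features(f, rng=rng).values for f in X])

    def get_feature_names_out(self, input_features=None):
        return np.array(["sigma_R", "lambda_E", "xi_G", "sigma_G", "mu_G"])


class RipleyKFeatures(TransformerMixin, BaseEstimator):
    """Stateless transformer: marker fields -> (n, 5) Besag K-curve features."""

    method = "ripley"

    def __init__(self, radii: np.ndarray | None = None, correction: str = "ripley"):
        self.radii = radii
        self.correction = correction

    def fit(self, X: Sequence[MarkerField], y=None) -> "RipleyKFeatures":
        self.n_features_out_ = 5
        return self

    def transform(self, X: Sequence[MarkerField]) -> np.ndarray:
        rows = []
        for f in X:
            curve = ripley_k(f, radii=self.radii, correction=self.correction)
            rows.append(k_curve_features(besag_l(curve)).values)
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.array(
            ["max_khat", "max_grad_pre", "min_grad_post", "r_at_max", "spearman"]
        )
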