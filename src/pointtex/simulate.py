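"""Synthetic single-cell fluorescence image generator.

Three marker-field classes are simulated on a 256x256 pixel frame:

* ``C1`` ("healthy") -- markers drawn i.i.d. from an isotropic Gaussian
  cloud N(126, 100) in x and y, 3,000 markers, density 0.30 markers/px^2
  over the nominal 100x100 cell area.
* ``C2`` ("pathological") -- same cloud but with a reduced vertical
  spread N(126, 90), 3,000 markers, density 0.33 markers/px^2.
* ``C3`` (clustered) -- 300 seeds placed uniformly over the frame, each
  decorated with 10 markers at an exponential radial offset of mean
  ``mu_D`` = 35 px and a uniform angle, 3,000 markers in total.

Images are the convolution of the rasterized marker impulses with an
isotropic Gaussian point-spread function (PSF) of width ``sigma_psf``,
followed by a central crop that removes convolution boundary effects.
The resolution regime is summarized by the dimensionless ratio
``k = d_min / sigma_psf`` (k > 1 super-resolved, k < 1 sub-resolved),
with the characteristic inter-marker distance ``d_min`` = 1.02 px for
the default marker densities.

Coordinates are continuous 1-based pixel units: x in [1, M] runs along
columns, y in [1, N] along rows; ``pixels[y-1, x-1]`` addresses the
pixel under a marker after rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.signal import fftconvolve

FRAME_SIZE = 256
#: characteristic minimal inter-marker distance of the default C1/C2
#: marker densities, used to adimension the PSF width (k = d_min/sigma).
DEFAULT_D_MIN = 1.02
DEFAULT_CROP_SIZE = 216


class InvalidParameterError(ValueError):
    """A class/PSF parameter violates its contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassParams:
    """Generative parameters of one cell class.

    ``distribution`` selects the point process: ``"gaussian"`` uses
    (mean_x, mean_y, spread_x, spread_y, n_markers); ``"clustered"``
    uses (n_seeds, markers_per_seed, mean_radial_offset).  Spreads are
    standard deviations in pixels; ``mean_radial_offset`` is the mean
    ``mu_D`` of the exponential seed-to-marker distance (rate
    ``lambda_D = 1/mu_D``).
    """

    class_id: str
    distribution: Literal["gaussian", "clustered", "uniform"]
    mean_x: float = 126.0
    mean_y: float = 126.0
    spread_x: float = 100.0
    spread_y: float = 100.0
    n_markers: int = 3000
    n_seeds: int = 300
    markers_per_seed: int = 10
    mean_radial_offset: float = 35.0

    def validate(self) -> None:
        if self.distribution == "gaussian":
            if self.n_markers <= 0:
                raise InvalidParameterError("n_markers must be > 0")
            if self.spread_x <= 0 or self.spread_y <= 0:
                raise InvalidParameterError("spreads must be > 0")
        elif self.distribution == "clustered":
            if self.n_seeds <= 0 or self.markers_per_seed <= 0:
                raise InvalidParameterError("cluster counts must be > 0")
            if self.mean_radial_offset <= 0:
                raise InvalidParameterError("mean_radial_offset must be > 0")
        elif self.distribution == "uniform":
            if self.n_markers <= 0:
                raise InvalidParameterError("n_markers must be > 0")
        else:  # pragma: no cover - dataclass Literal guards this
            raise InvalidParameterError(f"unknown distribution {self.distribution!r}")

    @property
    def total_markers(self) -> int:
        if self.distribution == "clustered":
            return self.n_seeds * self.markers_per_seed
        return self.n_markers

    @property
    def density(self) -> float:
        """Marker density over the nominal cell area spread_x * spread_y."""
        if self.distribution != "gaussian":
            raise InvalidParameterError("density is defined for Gaussian classes")
        return self.n_markers / (self.spread_x * self.spread_y)


def default_class_params(class_id: str) -> ClassParams:
    """Parameters of the three study classes (C1, C2, C3)."""
    if class_id == "C1":
        return ClassParams("C1", "gaussian", spread_x=100.0, spread_y=100.0)
    if class_id == "C2":
        return ClassParams("C2", "gaussian", spread_x=100.0, spread_y=90.0)
    if class_id == "C3":
        return ClassParams("C3", "clustered")
    raise InvalidParameterError(f"unknown class id {class_id!r}")


@dataclass(frozen=True)
class MarkerField:
    """A set of continuous 2-D marker positions on a pixel frame."""

    coords: np.ndarray  # (n, 2) array of (x, y), 1-based pixel units
    class_id: str
    image_dims: tuple[int, int] = (FRAME_SIZE, FRAME_SIZE)  # (M, N) = (cols, rows)
    provenance: Literal["ground_truth", "detected"] = "ground_truth"

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.size == 0:
            coords = coords.reshape(0, 2)
        if coords.shape[1] != 2:
            raise InvalidParameterError("coords must be (n, 2)")
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]

    @staticmethod
    def empty(class_id: str = "", image_dims: tuple[int, int] = (FRAME_SIZE, FRAME_SIZE)) -> "MarkerField":
        return MarkerField(np.empty((0, 2)), class_id, image_dims)


@dataclass(frozen=True)
class PSFModel:
    """Isotropic Gaussian PSF; sigma_psf = 0 degenerates to a delta kernel."""

    sigma_psf: float
    kernel_truncation: float = 4.0  # kernel half-width in multiples of sigma

    def __post_init__(self) -> None:
        if self.sigma_psf < 0:
            raise InvalidParameterError("sigma_psf must be >= 0")
        if self.kernel_truncation <= 0:
            raise InvalidParameterError("kernel_truncation must be > 0")

    def kernel(self) -> np.ndarray:
        """Discretized unit-energy 2-D kernel (odd square, sums to 1)."""
        if self.sigma_psf == 0:
            return np.ones((1, 1))
        half = int(np.ceil(self.kernel_truncation * self.sigma_psf))
        ax = np.arange(-half, half + 1, dtype=float)
        g = np.exp(-0.5 * (ax / self.sigma_psf) ** 2)
        k2 = np.outer(g, g)
        return k2 / k2.sum()


@dataclass(frozen=True)
class ResolutionRatio:
    """Dimensionless resolution ratio k = d_min / sigma_psf."""

    d_min: float
    sigma_psf: float
    k: float

    @property
    def regime(self) -> str:
        return "super-resolved" if self.k > 1 else ("sub-resolved" if self.k < 1 else "switch")


@dataclass(frozen=True)
class CellImage:
    """A non-negative single-channel intensity image i(x, y).

    ``total_intensity`` is the mass of the full (untruncated) linear
    response of the rasterized markers to the PSF; for a normalized
    kernel it equals the rasterized marker count regardless of the crop
    or of markers near the frame edge.
    """

    pixels: np.ndarray
    crop_window: tuple[int, int, int, int] | None = None  # (row0, col0, h, w), 0-based
    source: Literal["synthetic", "real"] = "synthetic"
    truth: MarkerField | None = None
    total_intensity: float | None = None
    sigma_psf: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise InvalidParameterError("pixels must be a non-empty 2-D grid")
        if px.min() < 0:
            raise InvalidParameterError("pixel intensities must be >= 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def truth_in_crop(self) -> MarkerField:
        """Ground-truth markers inside the crop, in crop-local coordinates."""
        if self.truth is None:
            raise ValueError("image carries no ground truth")
        if self.crop_window is None:
            return self.truth
        r0, c0, h, w = self.crop_window
        x, y = self.truth.x, self.truth.y
        keep = (x >= c0 + 1) & (x <= c0 + w) & (y >= r0 + 1) & (y <= r0 + h)
        coords = np.column_stack([x[keep] - c0, y[keep] - r0])
        return MarkerField(coords, self.truth.class_id, (w, h), self.truth.provenance)


@dataclass(frozen=True)
class SimulationConfig:
    """Full generator configuration for a dataset sweep."""

    class_params: dict[str, ClassParams] = field(
        default_factory=lambda: {c: default_class_params(c) for c in ("C1", "C2", "C3")}
    )
    sigma_psf: tuple[float, ...] = ()
    images_per_class_train: int = 2000
    images_per_class_test: int = 250
    crop_size: int = DEFAULT_CROP_SIZE
    seed: int = 0
    density_only: bool = False
    d_min: float = DEFAULT_D_MIN

    def __post_init__(self) -> None:
        if not self.sigma_psf:
            object.__setattr__(self, "sigma_psf", tuple(default_sigma_grid()))

    def effective_class_params(self) -> dict[str, ClassParams]:
        """Class parameters with the density-only variant applied.

        In the density-only variant C1 and C2 share the same spatial
        law and differ only in marker count (same 0.30 vs 0.33 density
        over the nominal 100x100 area).
        """
        params = dict(self.class_params)
        if self.density_only:
            c1 = params["C1"]
            params["C2"] = replace(
                c1, class_id="C2", n_markers=int(round(0.33 * c1.spread_x * c1.spread_y))
            )
        return params


def default_sigma_grid(
    n: int = 11, k_min: float = 0.5, k_max: float = 2.0, d_min: float = DEFAULT_D_MIN
) -> np.ndarray:
    """PSF widths spanning the sub- to super-resolved transition.

    The grid is linear in k over [k_min, k_max] and mapped to
    sigma_psf = d_min / k (descending in sigma as k grows).
    """
    k = np.linspace(k_min, k_max, n)
    return d_min / k


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _resample_into_bounds(draw, dims: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample ``draw(m, rng) -> (m, 2)`` until all points land
    inside [1, M] x [1, N].  Preserves the requested count exactly."""
    M, N = dims
    out = draw(None, rng)
    bad = ~(
        (out[:, 0] >= 1) & (out[:, 0] <= M) & (out[:, 1] >= 1) & (out[:, 1] <= N)
    )
    while bad.any():
        out[bad] = draw(np.flatnonzero(bad), rng)
        bad = ~(
            (out[:, 0] >= 1) & (out[:, 0] <= M) & (out[:, 1] >= 1) & (out[:, 1] <= N)
        )
    return out


def sample_gaussian_field(
    params: ClassParams,
    rng: np.random.Generator,
    image_dims: tuple[int, int] = (FRAME_SIZE, FRAME_SIZE),
    truncate: bool = True,
) -> MarkerField:
    """Draw an i.i.d. Gaussian marker cloud (classes C1/C2).

    Out-of-frame draws are rejection-resampled so the field carries
    exactly ``n_markers`` markers; set ``truncate=False`` to keep the
    raw (unbounded) draws for distributional diagnostics.
    """
    params.validate()
    if params.distribution != "gaussian":
        raise InvalidParameterError("sample_gaussian_field needs a Gaussian class")

    def draw(idx, rng):
        m = params.n_markers if idx is None else len(idx)
        x = rng.normal(params.mean_x, params.spread_x, m)
        y = rng.normal(params.mean_y, params.spread_y, m)
        return np.column_stack([x, y])

    coords = draw(None, rng) if not truncate else None
    if coords is None:
        coords = _resample_into_bounds(draw, image_dims, rng)
    return MarkerField(coords, params.class_id, image_dims)


def sample_clustered_field(
    params: ClassParams,
    rng: np.random.Generator,
    image_dims: tuple[int, int] = (FRAME_SIZE, FRAME_SIZE),
) -> MarkerField:
    """Draw the clustered class C3: uniform seeds, each surrounded by
    ``markers_per_seed`` markers at Exponential(mean mu_D) radius and
    uniform angle.  Out-of-frame markers are resampled (their seed is
    kept fixed)."""
    params.validate()
    if params.distribution != "clustered":
        raise InvalidParameterError("sample_clustered_field needs the clustered class")
    M, N = image_dims
    seeds_x = rng.uniform(1, M, params.n_seeds)
    seeds_y = rng.uniform(1, N, params.n_seeds)
    per = params.markers_per_seed
    centers = np.repeat(np.column_stack([seeds_x, seeds_y]), per, axis=0)

    def draw(idx, rng):
        ctr = centers if idx is None else centers[idx]
        m = ctr.shape[0]
        r = rng.exponential(params.mean_radial_offset, m)
        theta = rng.uniform(0.0, 2.0 * np.pi, m)
        return ctr + np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    coords = _resample_into_bounds(draw, image_dims, rng)
    return MarkerField(coords, params.class_id, image_dims)


def sample_csr_field(
    n_markers: int,
    rng: np.random.Generator,
    image_dims: tuple[int, int] = (FRAME_SIZE, FRAME_SIZE),
    class_id: str = "CSR",
) -> MarkerField:
    """Complete spatial randomness: n i.i.d. uniform points on the frame.

    The homogeneous-Poisson null of the Ripley K analysis (conditioned
    on the point count)."""
    if n_markers <= 0:
        raise InvalidParameterError("n_markers must be > 0")
    M, N = image_dims
    coords = np.column_stack(
        [rng.uniform(1, M, n_markers), rng.uniform(1, N, n_markers)]
    )
    return MarkerField(coords, class_id, image_dims)


def sample_field(
    params: ClassParams,
    rng: np.random.Generator,
    image_dims: tuple[int, int] = (FRAME_SIZE, FRAME_SIZE),
) -> MarkerField:
    """Dispatch on the class distribution."""
    if params.distribution == "gaussian":
        return sample_gaussian_field(params, rng, image_dims)
    if params.distribution == "clustered":
        return sample_clustered_field(params, rng, image_dims)
    return sample_csr_field(params.n_markers, rng, image_dims, params.class_id)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def rasterize(field: MarkerField) -> np.ndarray:
    """Unit impulse per marker at its nearest integer pixel (counts grid)."""
    M, N = field.image_dims
    grid = np.zeros((N, M))
    if len(field):
        cols = np.clip(np.rint(field.x).astype(int) - 1, 0, M - 1)
        rows = np.clip(np.rint(field.y).astype(int) - 1, 0, N - 1)
        np.add.at(grid, (rows, cols), 1.0)
    return grid


def central_crop_window(shape: tuple[int, int], crop_size: int) -> tuple[int, int, int, int]:
    """Centered (row0, col0, h, w) crop rectangle."""
    H, W = shape
    if crop_size > H or crop_size > W:
        raise InvalidParameterError("crop exceeds image bounds")
    r0 = (H - crop_size) // 2
    c0 = (W - crop_size) // 2
    return (r0, c0, crop_size, crop_size)


def render_image(
    field: MarkerField,
    psf: PSFModel,
    crop: tuple[int, int, int, int] | int | None = None,
) -> CellImage:
    """Rasterize a marker field and blur it through the PSF.

    Markers become unit impulses at their nearest pixel; the image is
    the zero-padded same-size convolution with the normalized Gaussian
    kernel.  ``crop`` is either a (row0, col0, h, w) rectangle, an int
    (centered square side), or None for the uncropped frame; cropping
    is applied last and removes convolution boundary effects.
    """
    raster = rasterize(field)
    H, W = raster.shape
    if psf.sigma_psf == 0:
        full = raster
        same = raster
    else:
        kernel = psf.kernel()
        full = fftconvolve(raster, kernel, mode="full")
        half = kernel.shape[0] // 2
        same = full[half : half + H, half : half + W]
    total = float(full.sum())
    same = np.clip(same, 0.0, None)  # FFT round-off can leave tiny negatives

    window: tuple[int, int, int, int] | None
    if crop is None:
        window = None
        pixels = same
    else:
        if isinstance(crop, int):
            crop = central_crop_window((H, W), crop)
        r0, c0, h, w = crop
        if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W or h <= 0 or w <= 0:
            raise InvalidParameterError("crop outside image bounds")
        window = (r0, c0, h, w)
        pixels = same[r0 : r0 + h, c0 : c0 + w]
    return CellImage(
        pixels=pixels,
        crop_window=window,
        source="synthetic",
        truth=field,
        total_intensity=total,
        sigma_psf=psf.sigma_psf,
    )


# ---------------------------------------------------------------------------
# resolution ratio and d_min
# ---------------------------------------------------------------------------


def resolution_ratio(d_min: float, sigma_psf: float) -> ResolutionRatio:
    """k = d_min / sigma_psf; k > 1 is the super-resolved regime."""
    if d_min <= 0 or sigma_psf <= 0:
        raise InvalidParameterError("d_min and sigma_psf must be > 0")
    return ResolutionRatio(d_min=d_min, sigma_psf=sigma_psf, k=d_min / sigma_psf)


def estimate_dmin(
    fields_c1: Sequence[MarkerField],
    fields_c2: Sequence[MarkerField],
    method: Literal["mean_nn", "min_pair"] = "mean_nn",
) -> float:
    """Characteristic minimal inter-marker distance over two classes.

    ``mean_nn`` (default): per field, the mean nearest-neighbor
    distance; averaged over fields within a class; the smaller of the
    two class values is returned.  ``min_pair``: the literal smallest
    pairwise distance in either class.  The pipeline default bypasses
    this estimator and uses the constant ``DEFAULT_D_MIN`` = 1.02
    established for the default simulated densities.
    """
    from scipy.spatial import cKDTree

    if not fields_c1 or not fields_c2:
        raise InvalidParameterError("need at least one field per class")

    def per_class(fields: Sequence[MarkerField]) -> float:
        vals = []
        for f in fields:
            if len(f) < 2:
                raise InvalidParameterError("fields need >= 2 markers")
            tree = cKDTree(f.coords)
            dists, _ = tree.query(f.coords, k=2)
            nn = dists[:, 1]
            vals.append(nn.min() if method == "min_pair" else nn.mean())
        return float(min(vals) if method == "min_pair" else np.mean(vals))

    return min(per_class(fields_c1), per_class(fields_c2))


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def image_rng(root_seed: int, counter: int) -> np.random.Generator:
    """Per-image RNG stream derived from the root seed by counter, so any
    image is reproducible independently of generation order."""
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), int(counter)]))


def generate_dataset(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Write a full simulated dataset (images + truth + manifest).

    Layout: ``sigma_<s>/<split>/<class>/img_<i>.tif`` with a matching
    ``img_<i>.csv`` of ground-truth coordinates (header ``x,y``,
    1-based pixel units).  Returns the manifest dict (also written as
    ``manifest.json``).
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.effective_class_params()
    class_ids = sorted(params)
    entries = []
    counter = 0
    for si, sigma in enumerate(config.sigma_psf):
        psf = PSFModel(sigma_psf=float(sigma))
        k = config.d_min / sigma if sigma > 0 else float("inf")
        for split, n_img in (
            ("train", config.images_per_class_train),
            ("test", config.images_per_class_test),
        ):
            for class_id in class_ids:
                cdir = out / f"sigma_{si:02d}" / split / class_id
                cdir.mkdir(parents=True, exist_ok=True)
                for i in range(n_img):
                    rng = image_rng(config.seed, counter)
                    counter += 1
                    fld = sample_field(params[class_id], rng)
                    img = render_image(fld, psf, crop=config.crop_size)
                    tif = cdir / f"img_{i:05d}.tif"
                    csv = cdir / f"img_{i:05d}.csv"
                    tifffile.imwrite(tif, img.pixels.astype(np.float32))
                    write_coords(csv, fld)
                    entries.append(
                        {
                            "image": str(tif.relative_to(out)),
                            "truth": str(csv.relative_to(out)),
                            "class_id": class_id,
                            "split": split,
                            "sigma_psf": float(sigma),
                            "k": k,
                        }
                    )
    manifest = {
        "seed": config.seed,
        "d_min": config.d_min,
        "density_only": config.density_only,
        "crop_size": config.crop_size,
        "sigma_psf": [float(s) for s in config.sigma_psf],
        "k": [config.d_min / s if s > 0 else float("inf") for s in config.sigma_psf],
        "class_params": {
            c: {k_: v for k_, v in vars(p).items()} for c, p in params.items()
        },
        "entries": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def write_coords(path: str | Path, field: MarkerField) -> None:
    """CSV coordinate dialect shared by truth and detections: header
    ``x,y``, 1-based continuous pixel units."""
    arr = field.coords
    with open(path, "w") as fh:
        fh.write("x,y\n")
        for x, y in arr:
            fh.write(f"{x:.6f},{y:.6f}\n")


def read_coords(
    path: str | Path,
    class_id: str = "",
    image_dims: tuple[int, int] = (FRAME_SIZE, FRAME_SIZE),
    provenance: Literal["ground_truth", "detected"] = "ground_truth",
) -> MarkerField:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.size == 0:
        data = np.empty((0, 2))
    return MarkerField(data, class_id, image_dims, provenance)
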