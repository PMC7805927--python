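# pointtex

**Pointillist vs. textural feature spaces for fluorescent-marker
distributions in single-cell microscopy.**

When fluorescent markers inside a cell are imaged through a microscope,
the point spread function (PSF) decides what the image looks like: with
a small PSF every marker is resolved individually (super-resolved
regime), with a large one the markers merge into a texture
(sub-resolved regime). For tasks such as telling healthy from
pathological cells by a change in marker *density* or marker
*clustering*, two analysis philosophies compete:

* the **pointillist** approach — localize every marker, then describe
  the resulting point pattern statistically;
* the **textural** approach — describe the blurred intensity image
  directly, without localizing anything.

`pointtex` implements both pipelines end-to-end on simulated single
cells and compares them under one identical classification protocol,
sweeping the PSF width across the resolution transition. The regime is
summarized by the dimensionless ratio

```
k = d_min / sigma_psf        (k > 1 super-resolved, k < 1 sub-resolved)
```

where `d_min` is the characteristic minimal inter-marker distance
(1.02 px for the default marker densities) and `sigma_psf` the width of
the Gaussian PSF.

## What is simulated

Three classes of 256×256 px cells, 3,000 markers each:

| class | point process | purpose |
|---|---|---|
| C1 | Gaussian cloud, N(126, 100) in x and y — density 0.30 px⁻² | reference ("healthy") |
| C2 | same cloud, vertical spread 90 — density 0.33 px⁻² | **density** task vs C1 |
| C3 | 300 uniform seeds × 10 markers, exponential radial offset (mean 35 px) | **organization** task vs C1 |

Images are the convolution of the rasterized markers with a normalized
Gaussian kernel, centrally cropped to 216×216 px to remove boundary
effects. A Laplacian-of-Gaussian detector (scale-matched to the PSF,
sub-pixel centroid refinement) supplies marker coordinates for the
pointillist path.

## The five feature spaces (all 5-dimensional)

**Pointillist** (from detected coordinates):

1. *Distance distribution* — maximum-likelihood parameters
   (σ_R, λ_E, ξ_G, σ_G, μ_G) of a Rayleigh fit to inter-marker
   distances, an exponential fit to distances from the centroid, and a
   generalized-extreme-value fit to nearest-neighbor distances; the
   families are selected by the Bayesian information criterion,
   BIC = −2 ln L + p ln n, over a pool of 16 common distributions.
2. *Ripley K curve* — the edge-corrected K-function
   `K(r) = |Ω|/(n(n−1)) Σ_{x≠y} 1{|x−y|≤r} f(x,y)` with Ripley's
   isotropic arc-fraction correction `f`, normalized to Besag's
   variance-stabilized form `K̂(r) = √(K(r)/π) − r` (zero under
   complete spatial randomness), summarized by max K̂, pre-/post-peak
   extreme gradients, argmax radius, and Spearman ρ(K̂, r).

**Textural** (from the intensity image):

3. *Autocorrelation* — `G = F⁻¹[|F[i]|²]` (Wiener–Khinchin), radial
   profile summarized by maximum, FWHM, extreme gradients, and
   tail variance beyond the central peak.
4. *GLCM / Haralick* — co-occurrence matrices at 4 orientations on
   72×72 windows; the five named Haralick coefficients (contrast,
   variance, sum variance, difference variance, sum average), with all
   14 + PCA as an option.
5. *LBP* — 8-neighbor local binary pattern codes (ties set the bit),
   256-bin histograms per 72×72 region, PCA to 5 components fitted on
   training folds only.

Every space feeds the same linear-kernel SVM under stratified 10-fold
cross-validation with per-fold z-scoring (and per-fold PCA where the
native dimension exceeds 5).

## Worked example

```python
import numpy as np
from pointtex import (
    default_class_params, sample_gaussian_field, render_image, PSFModel,
    resolution_ratio, detect_markers, ripley_k, besag_l, k_curve_features,
    distance_features, run_sweep,
)

rng = np.random.default_rng(0)
field = sample_gaussian_field(default_class_params("C1"), rng)
ratio = resolution_ratio(1.02, 0.8)
print(f"C1 field: {len(field)} markers, k = {ratio.k:.3f} ({ratio.regime})")

image = render_image(field, PSFModel(sigma_psf=0.8), crop=216)
detected = detect_markers(image, sigma_psf=0.8).detected
print(f"detected {len(detected)} markers in the {image.shape} crop")

print("distance features:", np.round(distance_features(detected).values, 3))
curve = besag_l(ripley_k(detected))
print("Ripley features:  ", np.round(k_curve_features(curve).values, 3))

report = run_sweep(
    sigma_psf=[1.02 / 0.5, 1.02 / 2.0],
    methods=("autocorrelation", "ripley"),
    tasks=("organization",),
    n_images_per_class=40,
    seed=0,
)
print(report[["method", "k", "accuracy_mean", "accuracy_std"]].round(3))
```

prints

```
C1 field: 3000 markers, k = 1.275 (super-resolved)
detected 1834 markers in the (216, 216) crop
distance features: [ 8.5008e+01  1.3000e-02 -1.4300e-01  1.0420e+00  2.6270e+00]
Ripley features:   [ 4.0900e-01  4.8500e-01 -9.0000e-03  5.3207e+01  9.9200e-01]
         method   k  accuracy_mean  accuracy_std
autocorrelation 0.5          1.000         0.000
         ripley 0.5          0.575         0.139
autocorrelation 2.0          0.988         0.038
         ripley 2.0          0.975         0.050
```

At k = 1.3 roughly 60% of the 3,000 markers are recovered (close spots
merge); the distance features read off the Gaussian cloud's scale
(σ_R ≈ 85 px) and the K̂ curve is mildly positive (max K̂ ≈ 0.4). In
the mini-sweep the textural descriptor keeps near-perfect accuracy on
the organization task in both regimes, while the pointillist Ripley
descriptor collapses toward chance when the PSF is large (k = 0.5) —
the central comparison the package exists to make.

A command-line interface mirrors the pipeline
(`pointtex simulate | detect | features | sweep | plot | ingest`); run
`pointtex --help`. User-supplied real single-cell TIFF/PNG images can
enter the same feature/classification path via `pointtex ingest`.

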