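# Methods

This note documents the models, parameter choices and numerical
conventions behind `pointtex`, and what the synthetic experiments do
and do not establish.

## Simulation model

A cell is a planar point process of fluorescent markers on a 256×256
pixel frame, observed through a linear shift-invariant optical system.

**Marker fields.** Coordinates are continuous, 1-based pixel units
(x ∈ [1, 256] along columns, y along rows).

* *C1 (reference)* — markers i.i.d. from an isotropic Gaussian,
  x ~ N(126, 100²), y ~ N(126, 100²), n = 3,000. The second parameter
  is interpreted as a standard deviation; draws falling outside the
  frame are rejection-resampled, which preserves the marker total
  exactly (clipping would pile mass on the border and distort the
  nearest-neighbor statistics). The nominal cell area is
  spread_x × spread_y = 100 × 100 px², giving the marker density
  3,000/10,000 = 0.30 px⁻².
* *C2 (density shift)* — identical except spread_y = 90 px:
  density 3,000/9,000 ≈ 0.33 px⁻², a 0.03 px⁻² (10%) shift. Note the
  shift is implemented through the spatial law, so C1 and C2 differ
  (slightly) in second-order structure as well as density.
* *C3 (clustered)* — a Neyman–Scott-type process: 300 seeds uniform on
  the frame; around each seed, 10 markers at radius
  r ~ Exponential(mean μ_D = 35 px) and angle θ ~ Uniform[0, 2π).
  The angular law is a modeling choice — isotropy is the natural null
  when only the radial law is specified. Out-of-frame markers are
  resampled with their seed held fixed. Total: 3,000 markers.
* A *density-only* variant makes C2 share C1's spatial law and differ
  only in marker count (3,300 vs 3,000), isolating pure density from
  organization; combined with σ_psf = 0 it also bypasses diffraction.
* `sample_csr_field` provides the homogeneous (binomial) null used to
  calibrate the spatial statistics.

**Optics.** The PSF is an isotropic Gaussian of width σ_psf (px),
discretized on an odd square support truncated at 4σ and renormalized
to unit sum, so one marker contributes exactly one unit of intensity.
Markers are rasterized as unit impulses at their nearest pixel (no
sub-pixel splatting) and convolved with the kernel (FFT, zero-padded).
σ_psf = 0 degenerates to the identity (the raw count grid).

*Intensity conservation.* A zero-padded same-size output loses the
mass of kernels overhanging the frame edge. `CellImage` therefore
carries `total_intensity`, the mass of the **full** linear response,
which equals the rasterized marker count to machine precision for any
field and σ; the conservation invariant is asserted on that quantity.
The visible image is the same-size view, centrally cropped to 216×216
px — the crop exceeds the largest kernel half-width (4 × 2.04 ≈ 8 px),
so boundary effects never reach the analyzed pixels. The crop side is
a multiple of the 72-px texture window (3×3 windows per image).

**Resolution ratio.** PSF widths are adimensioned by
k = d_min/σ_psf with d_min = 1.02 px, the characteristic minimal
inter-marker distance of the default densities; k > 1 is
super-resolved, k < 1 sub-resolved. The default sweep grid is linear
in k over [0.5, 2] (11 values, σ_psf from 2.04 down to 0.51). A
literal "smallest pairwise distance" over 3,000 dense points would be
far below 1.02 px, so `estimate_dmin` exposes two estimators for user
data — the minimum over classes of the per-field mean nearest-neighbor
distance (default) and the literal minimum pairwise distance — while
the pipeline's k axis uses the printed constant.

**Reproducibility.** One root seed; per-image RNG streams are derived
by counter (`SeedSequence([seed, counter])`), so any image is
regenerable independently of generation order, and identical
(config, seed) pairs give byte-identical datasets.

## Marker localization

The localizer is a deliberately parameter-light surrogate for a
full single-molecule localization algorithm: the image is filtered
with a scale-normalized negated Laplacian-of-Gaussian at scale σ_psf
(the only optical prior), local maxima above 10% of the per-image
maximum response and separated by at least max(1, round(σ)) px are
kept, and each peak is refined by the intensity-weighted centroid of
the clipped-positive response in a (2⌈σ⌉+1)² neighborhood. It is
deterministic and, on isolated noiseless spots, recovers positions to
well under half a pixel. Its absolute recall is *not* comparable to
state-of-the-art localizers — only the shape of its recall-vs-k curve
(high in the super-resolved regime, collapsing in the sub-resolved
one) is used, and downstream conclusions are about feature spaces, not
the detector.

Detection scoring matches detections to ground truth one-to-one,
greedily in increasing distance (ties broken by detection index),
within a tolerance defaulting to max(1, σ_psf) px; the detection rate
is recall. The score also reports the detection count so precision can
be derived.

## Pointillist descriptors

**Distance distributions.** Three distance sets are computed exactly:
all n(n−1)/2 pairwise distances, distances to the mean marker
position, and per-marker nearest-neighbor distances. The
classification features are the ML parameters of fixed families —
Rayleigh scale σ_R (pairwise), exponential rate λ_E (centroid), GEV
(ξ_G, σ_G, μ_G) (nearest neighbor); the GEV shape is reported in the
standard ξ = −c sign convention of scipy's parameterization. Pairwise
samples above 10⁵ are subsampled (seeded) before fitting — with ~4.5
million pairs at n = 3,000 the fit is insensitive to this. Exact zero
distances (coincident detections) are excluded from the
positive-support fits; they carry no distributional information and
lie outside the families' support.

The family-selection audit (`fit_and_select`) fits a pool of 16 common
distributions (normal, lognormal, exponential, gamma, Weibull,
Rayleigh, GEV, logistic, log-logistic, half-normal, inverse-Gaussian,
Nakagami, Rician, Birnbaum–Saunders, t, Gumbel) and ranks them by
BIC = −2 ln L + p ln(nb). On clean Rayleigh draws of size 2,000 the
generating family is selected ≥ 95/100 times. On actual simulated C1
fields, generalizing families that contain or approach Rayleigh
(Rician, Nakagami, Weibull) win by fractions of a percent of BIC —
frame truncation makes the pairwise distances only approximately
Rayleigh — which is why the classification features fix the families
rather than re-select per image.

**Ripley K / Besag L.** K is computed per Eq.
K(r) = |Ω|/(n(n−1)) Σ_{x≠y} 1{|x−y| ≤ r} f(x,y) over ordered pairs
with Ripley's isotropic correction f = ½(P(x,y) + P(y,x)), P being
the reciprocal of the fraction of the circle centered at x through y
that lies inside the window. For rectangular windows the fraction is
exact: each edge at distance d < r removes an arc 2·arccos(d/r), and
arcs crossing a corner overlap by max(0, aᵢ + aⱼ − π/2), which is
added back. A numerical angular-quadrature fallback (4,096 sectors)
covers non-rectangular windows. Weights satisfy f ≥ 1 and f = 1 for
fully interior circles; disabling the correction strictly lowers K
wherever a circle exits the window. The vectorized implementation
matches a naive scalar double loop to 10⁻⁹ relative tolerance.

The default observation window for a field on an M×N frame is the
continuous coordinate support [1, M] × [1, N] (area (M−1)(N−1)) — the
window on which uniform fields are actually uniform; with that
convention the CSR calibration is unbiased: over 100 fields of 200
points on a 100×100 window, mean K stays within 3 standard errors of
πr² for r ≤ 20 and the mean of K̂ = √(K/π) − r straddles zero. (The
square-root form is Besag's variance-stabilized L-function; it is the
only normalization of K that is zero-centered under CSR, which is the
property the comparison needs.)

The K̂ curve on the default grid (100 radii from 0 to a quarter of the
window side) is summarized by five scalars: max K̂; the maximum
gradient on [0, argmax] and minimum gradient on [argmax, end]
(central finite differences, one-sided at the ends, argmax ties broken
toward small r); the argmax radius; and the Spearman correlation of K̂
with r (defined as 0, with a warning, for constant curves).

## Textural descriptors

**Autocorrelation.** G = F⁻¹[|F[i]|²] (circular, no mean
subtraction), shifted so zero lag is central; verified against the
direct double sum to 10⁻⁹. The radial profile (1-px annular means) is
summarized by p(0); the FWHM from linear interpolation of the first
half-maximum crossing; the extreme finite-difference gradients; and
the variance of the profile beyond twice the central peak's HWHM (the
"central-peak removal" rule — the DC pedestal is handled here rather
than by pre-processing). In strongly sub-resolved images the profile
can stay above half maximum everywhere (the DC plateau exceeds half of
p(0)); the FWHM then saturates at the profile length, with a warning —
a legitimate, informative feature value, not an error.

**GLCM/Haralick.** Images are min–max quantized to 32 gray levels
(a balance between resolution and matrix sparsity at 72² px) and tiled
into non-overlapping, top-left-anchored 72×72 windows, partial tiles
discarded. Per window, symmetric normalized co-occurrence matrices at
offset d = 1 px (unstated upstream; the texture scale is set by the
window) and orientations {0°, 45°, 90°, 135°} are accumulated with
`skimage.feature.graycomatrix`; the 14 classical Haralick
coefficients are computed per orientation and averaged over angles
(no preferred orientation is expected), then averaged over windows.
The default 5-feature output is the named subset (contrast, variance,
sum variance, difference variance, sum average); the full 14 + PCA is
available. The maximal correlation coefficient (f14) is guarded to 0
for matrices with fewer than two occupied levels.

**LBP.** Codes per the 8-neighbor sign comparison with ties setting
the bit (b(0) = 1); neighbor order is frozen as top-left then
clockwise with bit n weighing 2ⁿ — any fixed order is admissible since
the histogram is the feature, so the choice is documented rather than
tuned. Codes are computed on each 72×72 region's interior, histogrammed
into 256 normalized bins, and averaged across regions (pooled
histograms rather than concatenation; flagged as a choice). Codes are
invariant under strictly monotone intensity transforms. The PCA to 5
components is performed inside the classification pipeline so its
centering/projection only ever sees training folds.

## Classification protocol

All five feature spaces enter the identical pipeline: per-fold z-score
standardization → (PCA to 5 for spaces wider than 5) → linear-kernel
SVM with C = 1 and no class weighting (balanced classes). Accuracies
are stratified 10-fold cross-validation means ± standard deviations
with seeded shuffling; a held-out train/test evaluation
(`holdout_accuracy`) is available alongside pooled CV, which is the
default. Alternate classifiers (decision tree, logistic regression,
kNN) sit behind a config switch and are not part of the main
comparison. Pointillist features are computed from *detected* markers
by default — the realistic pipeline — with a ground-truth ablation
switch.

## Problem sizes and what the experiments show

The package's own comparison experiments run at 200 images per class
with full 3,000-marker fields at three PSF widths spanning the regime
switch (k = 0.5, 1.3, 2) — sizes chosen so the complete suite runs on
a laptop-class single CPU in minutes while leaving the qualitative
ordering of the methods far outside fold-to-fold noise. At these
sizes, with fixed seeds, the pipeline reproduces the study's
qualitative structure:

* on the density task in the sub-resolved regime the autocorrelation
  space clearly beats the distance-distribution space;
* on the organization task at k ≥ 1.3 every method is far above
  chance;
* the pointillist spaces collapse toward chance as k drops to 0.5
  while the textural spaces do not;
* label permutation drives every method to 0.5 within 3 standard
  deviations.

What passing these experiments does **not** show: performance on real
microscope data. The generator omits camera noise (Poisson shot
noise, read noise, thermal noise), fluorophore photophysics (blinking,
bleaching, variable brightness), spatially varying or non-Gaussian
PSFs, and 3-D structure. LBP in particular is known to be noise
sensitive, so its simulated ranking is optimistic. The real-image
ingestion path (per-image min–max normalization to [0, 1], identical
feature/classification stages) is supported and tested for format
handling, but no real-data accuracy claims are made.

## Numerical and degenerate-input conventions

* FFT convolution round-off can leave intensities around −10⁻¹⁶;
  images are clipped at 0.
* Empty marker fields are constructible only explicitly; samplers
  reject non-positive counts and spreads.
* All-zero images yield an empty detection result (not an error).
* Ripley radii must be strictly increasing within [0, window
  diagonal]; K is error-checked non-negative before the Besag
  transform.
* Degenerate fit samples: families that cannot be fitted are skipped
  with a warning; an error is raised only when none fit, or when a
  fixed-family fit returns non-finite or non-positive-scale
  parameters (the error names the family).
* PCA reduction refuses a fit subset smaller than the target
  dimension and warns when its rank is deficient.
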