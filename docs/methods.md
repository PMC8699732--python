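# Methods

`geoseg` implements a trainable segmentation and whole-image
classification pipeline for 2-D grayscale microscopy: multi-scale
differential-geometric pixel features and orthogonal-moment regional
features feed feature-selected random-forest or maximum-margin
classifiers, and the results are scored with partition metrics
(Vrand/Vinfo) or standard classification metrics. This note records the
models, the numerical choices, and the limits of what the synthetic
tests demonstrate.

## Scale-space pixel features

The image is treated as a smooth surface by convolving with a
radially-symmetric Gaussian kernel of scale s = σ², G(r) = exp(−r²/2s)/2πs.
Derivatives are taken in the weak (distributional) sense: the
order-(dx, dy) response is obtained by convolving with an analytically
sampled Gaussian-derivative kernel, so differentiation and smoothing
happen in one pass and high-frequency noise is not amplified as it is
with finite differences. Derivatives up to total order 6 are supported.

The filter bank computes, per scale: smoothed intensity; gradient
amplitude and orientation (both sine and cosine of the phase);
Laplacian of Gaussian (LoG); its anisotropic gauge decomposition (ALoG)
into the second directional derivative along the gradient (Δ⊥) and
along the isophote (Δ∥), with Δ⊥ + Δ∥ = ΔG identically; Hessian
eigenvalues and determinant; structure-tensor eigenvalues, coherence
c = ((λ₁−λ₂)/(λ₁+λ₂))² and orientation; isophote (line) curvature;
mean and Gaussian surface curvature of the Monge patch z = I(x, y)
(intensity taken as elevation with no rescaling — pre-normalize to
[0, 1] if units matter); iterated Laplacians ΔGⁿ (n ≤ 4, n = 2 is the
bi-Laplacian); and the full jet of partials up to a requested order.

Numerical choices:

* **Window.** Kernels are sampled on odd windows of radius
  ceil(radius_factor·σ), radius_factor 3 by default ("half-width" = σ in
  pixels; default scales σ ∈ {2, 4, 8}). At 3σ the truncated mass is
  ≈0.3%, which bounds the semigroup-composition error near 3·10⁻³
  relative; tests of the semigroup identity therefore use 4σ windows,
  where the error drops below 10⁻⁴.
* **Moment correction.** The 0-order kernel is renormalized to sum
  exactly 1. Derivative kernels receive a constrained least-squares
  correction forcing their discrete moments to the continuous values
  (Σxʲk = 0 for j < d and (−1)ᵈ·d! at j = d), so polynomials below the
  derivative order give an exactly zero response and a unit ramp gives a
  unit first-derivative response. The distributional minus sign is
  absorbed: `gradient_features` reports ∂I_σ/∂x of the smoothed image.
* **Boundaries.** Reflect padding everywhere; analytic identities are
  asserted only at interior pixels at least one kernel radius from the
  border. x is the column coordinate, y the row coordinate, origin
  top-left.
* **Degeneracies.** Where the gradient amplitude (or the
  structure-tensor trace) is below 10⁻¹² of the plane maximum,
  orientation components, line curvature and coherence are set to 0,
  and the ALoG split collapses to Δ⊥ = ΔG, Δ∥ = 0.
* **Eigenvalues** are ordered descending and signed (λ₁ ≥ λ₂), which
  preserves λ₁+λ₂ = ΔG and λ₁λ₂ = det H pixelwise.

## Regional features

Regional (surjective) features map a ROI to a vector:

* **Legendre moments** M_mn, m, n ∈ 0..6 (49 values): the bounding box
  is mapped to [−1,1]², and M_mn = (2m+1)(2n+1)/4·ΣΣ f·L_m(x)L_n(y)ΔxΔy
  with midpoint quadrature at pixel centers and the two-term recurrence
  (n+1)L_{n+1} = (2n+1)xL_n − nL_{n−1}, so all orders come from one
  pass. Midpoint quadrature leaves O(1/N²) residuals in moments that
  vanish analytically; no sub-pixel scheme is used.
* **Zernike moment magnitudes** |Z_nm| for n ≤ 6, n−m even (16 values):
  the region is normalized to unit intensity range and projected onto
  the Zernike basis of the unit disk. The disk is centered on the
  bounding-box center with radius max(h, w)/2, so a disk-shaped region
  fills it exactly and box corners (r > 1) are ignored; this makes the
  constant-disk case project onto Z₀₀ alone, and magnitudes are
  invariant under exact grid rotations. The radial polynomials are
  computed by the three-term recursion R_n^m = r(R_{n−1}^{|m−1|} +
  R_{n−1}^{m+1}) − R_{n−2}^m (out-of-range terms zero), which is
  verified against the direct factorial sum for all n ≤ 10 — the
  recursion's bracketing is the one that reproduces the definition.
* **Haralick textures**: the region is quantized to 32 gray levels over
  its own min–max range; a symmetric normalized co-occurrence matrix is
  accumulated per distance {1, 2, 3} and offset {0°, 45°, 90°, 135°}
  over in-mask pixel pairs (opposite directions are redundant under
  symmetry), and the 13 classic statistics are emitted (156 values).
  The correlation of a constant region is defined as 0.
* **Region statistics**: histogram descriptors (mean, std, mode, min,
  max, center of mass, integrated density, median, skewness, kurtosis,
  area fraction) and shape descriptors (area, bbox, centroid,
  perimeter, fitted-ellipse axes/angle, Feret diameter, form factor
  4πA/P², roundness, aspect ratio, solidity).

`compute_regional_vector` concatenates these on the raw image and,
optionally, on every plane of a scale-space stack (names prefixed by
plane), with deterministic ordering.

## Feature selection and classifiers

CFS scores a subset F by merit(F) = k·r̄_cf / √(k + k(k−1)·r̄_ff) with
symmetric-uncertainty correlations over equal-frequency 10-bin
discretized features, searched best-first from the empty set and
stopped after 5 consecutive non-improving expansions; ties break by
feature name. Note the known CFS limitation: purely interactive
(XOR-like) feature pairs have near-zero individual correlations and are
found only through their small sample correlations. PCA reduction
standardizes columns, drops zero-variance ones, and keeps components
covering the requested variance fraction (default 0.95), with
largest-loading-positive sign fixing.

The random forest uses 100 bootstrap trees with √k candidate features
per split and majority voting. The maximum-margin classifier defaults
to C = 1 with a degree-1 polynomial (linear) kernel; multiclass uses
one-vs-one pairwise coupling, and class probabilities are pairwise vote
fractions — deterministic, but piecewise-constant (a binary problem
yields hard 0/1 scores). Models persist to a versioned container
(magic, JSON header with spec + feature signature + classes, pickled
estimator); prediction on a mismatched feature signature is rejected.

## Segmentation workflow and metrics

Annotated pixels (polygon ROIs rasterized by the pixel-center even-odd
rule, or masks) are sampled into a feature table — all pixels, or a
seeded uniform cap per class; overlapping ROIs of different classes are
rejected as ambiguous. The trained model scores every pixel to a
probability map, thresholded (binary, ≥ threshold inclusive) or
argmax-ed (ties to the lower class id) into a label image.

Vrand = 2Σp²_ij/(Σs² + Σt²) and Vinfo = 2I(S;T)/(H(S)+H(T)) are
computed from the joint overlap distribution of 4-connected components
of the two labelings (background is a segment like any other; natural
logarithms; 0·log 0 ≡ 0). Reductions use compensated summation so
self-comparison scores exactly 1.0. Optional border thinning
skeletonizes the ground-truth boundary class to 1 px and excludes the
remaining boundary pixels; an optional foreground restriction excludes
the boundary class entirely. Classification reports give per-class
one-vs-rest TP/FP rate, precision, recall, F1, trapezoidal ROC and PR
areas (tied recalls keep their best precision), support-weighted means,
and stratified seeded k-fold cross-validation.

## Synthetic data: what it does and does not show

* **Beans** (segmentation): 5 images, 256×256, each with 3–8 kidney
  silhouettes — two half-ellipses sharing their major axis, minor
  semi-axis 8–16 px, axis ratio 1.5–2.5, half-ellipse offset 15–30% of
  the minor axis — placed by rejection sampling with ≤ 2% overlap;
  foreground 200, background 50, optional additive Gaussian noise
  clipped to the level range (10% of the dynamic range, σ = 15, in the
  end-to-end tests).
* **Shapes** (classification): one filled shape per 256×256 instance;
  circles of radius 15–45 px, or jittered equilateral triangles
  (side 40–100 px) under random rotation, anisotropic scale 0.6–1.4 and
  shear ±0.3; 100 training and 50 test instances per class in the
  headline experiment.

Both generators route all randomness through one seeded
`numpy.random.Generator`, so a seed fixes the data set bit-for-bit.
These sets exercise geometry, not microscopy physics: there is no
texture, PSF, uneven illumination or annotation error. Passing the
end-to-end checks (perfect circle/triangle separation; bean Vrand and
pixel F1 ≥ 0.9) shows the pipeline's plumbing and invariants are
correct, not that comparable scores will be reached on real EM or
fluorescence data.

## Problem sizes used by the checks

The end-to-end segmentation check trains the 100-tree forest on a
seeded cap of 2000 pixels per class from 4 fully annotated images
(filters Gauss2D, Gradient, LoG, Hessian at σ ∈ {2, 4, 8}) and scores
the held-out 5th image; the classification check uses the full
100 + 50 instances per class at order-6 moments. These are the
package's default experiment sizes and are deliberately modest; all
entry points accept larger values.

## Known limitations

* 2-D grayscale only; color images are collapsed with ITU-R 601 weights
  on load; no volumetric filtering.
* ARFF support covers the numeric-attributes + nominal-class subset
  this package writes, not the full format.
* SVM probability outputs are vote fractions, not calibrated
  probabilities; use the random forest when smooth probability maps
  matter.
* CFS inherits the interaction blindness of correlation-based merits.
* The iterated-Laplacian and curvature filters assume adequate sampling
  (σ ≥ 1); sub-pixel σ invites aliasing in high-order kernels.
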