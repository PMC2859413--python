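# Methods

## The model

A dynamic susceptibility-contrast (DSC) perfusion acquisition of one slice
is a T x P matrix `y`: T time frames, P pixels.  Because of partial-volume
mixing, each pixel's time course is modelled as a noisy linear combination
of N pure-tissue temporal patterns,

    y = H x + u,        u ~ N(0, Λ),  Λ diagonal,

where the columns of `H` (T x N) are the tissue signal-time curves, the
rows of `x` (N x P) are the tissue factor images, and `u` is sensor noise.
The sources are assumed mutually independent, each with a 1-D
mixture-of-Gaussians (MoG) marginal

    p(x_j) = Σ_a ω_{j,a} N(x_j; μ_{j,a}, ν_{j,a}).

This is the independent-factor-analysis (IFA) family: unlike PCA/classical
factor analysis the non-Gaussian source densities remove the rotational
indeterminacy, and unlike noiseless ICA the model is generative with an
explicit noise covariance, so sources are recovered by posterior inference
rather than by inverting an unmixing matrix.

## Exact EM

The P pixels are treated as i.i.d. realisations; all expectations in the
updates are empirical means over pixels.  The fit criterion is the
negative mean log-likelihood per pixel (the model-dependent part of the
Kullback–Leibler divergence between the empirical and model densities).

Enumerating every joint source state `q = (q_1..q_N)` (`Π n_j` states,
capped at 4096) makes the model conditionally linear-Gaussian, so the
E-step is closed-form per state: responsibilities from the marginal
`N(Hμ_q, H V_q Hᵀ + Λ)` (evaluated by Cholesky in the log domain), source
posteriors by Gaussian conditioning with covariance
`(HᵀΛ⁻¹H + V_q⁻¹)⁻¹`.  The M-step is the standard closed-form update of
`H`, the diagonal of `Λ`, and the per-source MoG moments.  After every
M-step the scale indeterminacy is removed by renormalising each source's
marginal MoG variance to one and absorbing the scale into the mixing
column; this is a pure reparametrisation (the likelihood is invariant,
checked to 1e-8 in the tests).

Numerical guards: noise and MoG variances are floored at 1e-9; an
ill-conditioned source second-moment matrix is ridge-regularised by
1e-9·trace; responsibilities are normalised with log-sum-exp.

The factor images are the posterior means `E[x|y]` — equivalently the
state-weighted least-mean-square estimator `Σ_q p(q|y)(A_q y + b_q)`; the
tests verify both routes agree to 1e-10.

### Initialization

EM on this likelihood is multimodal.  The default start exploits the
strong clustering of bolus data: pixels are split into background and
foreground by Otsu's threshold on temporal energy `Σ_t y_t²` (stragglers
below 10% of the median foreground energy are discarded — a handful of
borderline pixels can otherwise capture a centroid of their own), the
foreground time courses are clustered by k-means into N groups, and the
centroid curves become the initial mixing columns.  Initial MoG parameters
come from a midpoint split of the least-squares source estimates, and the
initial noise diagonal from the residual variance.  A PCA start (first N
principal directions scaled by singular values) is available as
`init="pca"`; on the simulation phantom it reproducibly converges to
rotated local optima (matched correlations as low as 0.15 versus > 0.9999
from the clustering start at the same likelihood tolerance), which is why
it is not the default.  Both starts receive seeded jitter (1% of the
column norm), and fitting uses `n_restarts=3` independent restarts keeping
the lowest final loss, ties broken by the lowest restart index.

Convergence: relative loss change below 1e-6 or 500 iterations (then the
model is returned with `converged=False` rather than raising).  On the
default phantom EM typically converges in 250–350 iterations, a few tens
of seconds on one CPU.

### Sign convention

A factor and its mixing column can be jointly negated without changing
the likelihood.  After fitting, each column is flipped so its largest
excursion from the first-frame value points downward — during bolus
passage susceptibility *lowers* the signal — which makes the factor
images' foregrounds positive.  Component matching in the phantom
experiments is nevertheless sign-agnostic (absolute Pearson correlation,
Hungarian assignment).

## Tissue identification and segmentation

Contrast arrives in a fixed physiological order: artery, gray matter,
white matter, venous structures, choroid plexus.  Each mixing column is
normalised to a unit first-frame baseline and components are ranked by
the frame of their minimum (ties: deeper dip first); names are assigned
in rank order.  The normalisation is by the baseline value rather than by
the curve's variance: variance normalisation rescales the dip depths and
can rank a shallow-but-noisy curve above the artery, whereas depth below
a unit baseline is the physical quantity (it grows with blood volume and
flow).  Each factor image is binarised at its Otsu threshold (256 bins);
pixels above threshold in several components are assigned to the one with
the highest factor value, so the composite map partitions the labelled
pixels.  Averaged signal-time curves are means of the *observed* series
within each final mask.

## Hemodynamic maps

Signal is converted to concentration by `C = -(k/TE) ln(S/S0)` with k = 1
(only relative quantities are reported) and S0 the mean of the first
`baseline_frames` frames (default 5; the pre-bolus stretch of a typical
50-frame acquisition).  Pixels with non-positive signal are flagged
invalid and excluded, never propagated as NaN.

The arterial input function (AIF) is the concentration of the
mask-averaged arterial signal.  The first-pass window defaults to an
AIF-driven rule: start where the AIF reaches 10% of its peak; end on the
last frame before the post-peak curve, having fallen below 50% of peak,
re-rises above that level (recirculation); if it never re-rises, the
window runs to the last frame.  A fixed window can be configured.

- **rCBV** is the ratio of the first-pass areas of the tissue and
  arterial concentration curves.
- **rCBF** comes from deconvolving `C_t = rCBF · (C_a ⊗ R)` with the
  lower-triangular Toeplitz operator `A[i,j] = dt·C_a[i−j]`; singular
  values below `svd_threshold_fraction` of the largest (default 0.2, the
  convention of the SVD bolus-tracking literature; noise-free tests use
  1e-6) are truncated in the pseudo-inverse, and rCBF is the peak of the
  recovered `rCBF·R(t)` curve.
- **MTT** = rCBV / rCBF, in seconds.

Integration rule: integrals default to the left-endpoint rectangle rule
(`Σ c·dt`) rather than the trapezoid, because the discrete convolution
operator above *is* the rectangle rule — using the same quadrature on
both sides makes the three maps mutually consistent and preserves the
central-volume identity exactly (an impulse-AIF boxcar-residue pixel
yields MTT equal to the boxcar width; under the trapezoid it would give
2w−1).  For smooth in-vivo curves sampled at 1 s the two rules differ
negligibly; `integration_rule="trapezoid"` is available.  Negative
concentrations from noise are kept for integration (unbiased areas);
clipping is a config option.

## The phantom

The simulation study generates N spatially disjoint binary source regions
with exact pixel counts (defaults 603, 1683, 1514, 924 on a 128 x 128
grid — artery, GM, WM, and a mixed venous/CSF compartment), grown as
seeded 4-connected random blobs.  Real anatomy shapes are not imitated:
under the mixing model the source geometry is immaterial, only the
supports' sizes and disjointness matter.  The default 5 x 4 mixing matrix
holds five-point bolus-passage curves per tissue with a unit baseline.

Noise is i.i.d. Gaussian per entry with variance 10 (default).  SNR
follows the MR-imaging convention: mean noise-free signal intensity over
foreground pixels divided by the noise standard deviation.  When a target
SNR is given (default 240), the foreground amplitude is solved so the
realised SNR matches it exactly.  An alternative definition considered —
mean squared entry of the clean data over the noise variance — was
rejected because, at its "SNR 240", even EM started at the ground truth
cannot push the factor-image correlations past ~0.99, i.e. it conflates
the two noise regimes the simulation is meant to separate.

What the phantom does not emulate: Rician/spatially-correlated MR noise,
motion, recirculation in the mixing curves, partial-volume *gradients*
(sources are strictly disjoint binary supports), and multi-slice
geometry.  Passing the recovery tests therefore shows the estimator is
correct under its own model assumptions, not that separation quality on
real scans will reach the same correlations.

Recovery is scored after Hungarian matching on absolute Pearson
correlations (images over pixels, mixing columns over frames) and
summarised by the cross-talk matrix `J = (ĤᵀĤ)⁻¹ĤᵀH` with both matrices
column-normalised to unit Euclidean norm after permutation/sign alignment
(the estimated and true columns carry arbitrary relative scales; the
normalisation makes `J ≈ I` the scale-free statement of correctness).

## Problem sizes used in tests

The test-suite phantom runs use the full 128 x 128 grid (P = 16384,
T = 5, N = 4, 16 joint states) at SNRs 240 and 40 with three seeds each.
EM-correctness properties run on small instances (T ≤ 4, N = 2) against a
dense-grid quadrature oracle; the M-step fixed-point check uses 10^5
pixels.  Hemodynamics oracles use 30–200-frame noise-free curves.

## Known limitations

- Exact EM enumerates `Π n_j` joint states; the 4096-state cap keeps the
  method practical for N ≤ 11 at n_j = 2 (the regime of interest is
  N ≤ 6).  Large-N problems need the factorised variational posterior,
  which is out of scope.
- Model selection for N is not automated; N = 5 is the default for in
  vivo slices per the arrival-order taxonomy, and the choice is exposed
  in the config.
- The AIF is taken from the arterial segmentation of the same slice; no
  delay/dispersion correction or block-circulant (delay-insensitive)
  deconvolution is implemented, and absolute quantification (mL/100 g/min)
  is out of scope.
- Tissue labels beyond the artery rely purely on arrival order; on
  pathological hemodynamics (e.g. shunts) the order can be violated and
  labels must be reviewed.
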