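# Methods

This note documents the models, estimators, parameter choices and known
limitations of the phasequant pipeline, and states what the synthetic-data
generators do and do not emulate.

## Droplet segmentation and settled volume

Fields of settled condensates are min-max normalized to [0, 1] before
thresholding, because the Phansalkar constant r = 0.5 presumes a normalized
dynamic range. When a concentration series contains fields with no droplets,
normalization must share one scale across the series (`intensity_range`);
otherwise an empty field's noise is stretched to full range and the local
threshold fires on it. The threshold is

T = μ · (1 + p·exp(−q·μ) + k·(σ/r − 1)),  k = 0.25, r = 0.5, p = 2, q = 10,

with μ, σ the mean and standard deviation over a window of radius 30 px
(circular by default; a square window is available since the reference
implementations differ and neither documents the shape). Window statistics
are computed by FFT convolution with edge-clipped counts, which a literal
O(N·r²) double-loop oracle verifies pixel-for-pixel in the tests. Connected
components are 8-connected; components under 10 px are discarded; droplets
touching the field border are retained, since discarding them would bias the
settled volume per area low.

Per droplet, the equivalent ellipse comes from intensity-weighted second
central moments (a = 2√λ₁, b = 2√λ₂, plus a 1/12 px² quantization floor per
axis so single-pixel rows remain well-posed). The volume estimate takes the
out-of-plane semi-axis as the geometric mean of the in-plane ones:
c = √(a·b), V = (4/3)π·a·b·c. The Gaussian edge blur used in rendering
(σ = 1 px) inflates segmented radii by roughly one pixel, so absolute
volumes from rendered fixtures run ~20–30 % high while counts, centroids
(< 0.5 px) and the *location of the x-intercept* are unaffected — which is
why c_sat recovery is tested on the volume–concentration relationship, not
on absolute volume.

## Saturation concentration

Conditions whose settled volume exceeds `min_detectable` enter an ordinary
least-squares fit of volume on concentration; c_sat = −intercept/slope with
a delta-method standard error from the coefficient covariance. A
non-positive slope raises an explicit "no trend" error rather than returning
a meaningless intercept. When fewer than three conditions phase-separate,
`min_visible_concentration` provides the fallback: the lowest tested
concentration with visible condensates. `min_detectable` defaults to 0 and
should be set to the volume of one minimum-size droplet when empty fields
can produce spurious detections.

Reentrance classification works on replicate means along the DNA axis at
fixed protein: "reentrant" requires an interior maximum exceeding both
endpoints by more than the pooled replicate SD; monotone labels require
Spearman |ρ| ≥ 0.8; everything else is flat. The rule is scale-free, hence
invariant to uniform volume rescaling.

## Fusion kinetics

A fusion event is the interval from the last frame with two separate
segmented objects to the first frame where the fused object's aspect ratio
is ≤ 1.1 for two consecutive frames. The 1.1/2-frame operationalization of
"appears spherical" is a package choice (exposed as `ar_complete`,
`hold_frames`); a single-frame criterion would let one noisy frame end an
event. Events that never reach the criterion are returned uncompleted and
enter the empirical fusion CDF as censored observations (denominator only).
The synthetic fusion movie relaxes its aspect ratio exponentially from 2
toward 1 with the time constant chosen so the nominal curve crosses the
criterion half a frame before the intended completion frame, giving the
scorer symmetric margins against rendering error; ellipses are rendered with
4× supersampling so moment-based aspect ratios are accurate to ~10⁻³.

## Trajectories, MSD, and first passage

Detection uses a scale-normalized Laplacian-of-Gaussian at
σ = diameter/(2√2)/pixel size (default diameter 0.5 μm), a mean + 2 SD
threshold on the filtered image (the filtered-image convention is a choice;
the raw-image alternative changes only the threshold's meaning), and 3×3
quadratic subpixel refinement. Drift is removed by phase-correlation
registration to the first frame. Linking minimizes total squared
displacement per frame pair by the Hungarian algorithm with a hard maximum
link distance (default 0.5 μm) and no gap closing: a missed detection
terminates the track. Tracks below half the movie length are discarded.
An exhaustive-search matcher is the oracle for frames with ≤ 6 particles.

MSD is the two-dimensional time-averaged squared displacement (x and y
summed), ensemble-averaged with pair-count weights, at lags up to 25 % of
the trajectory length. The power law is fitted as

MSD(τ) = D·τ^α + c,  c ≥ 0,

by nonlinear least squares seeded from the log-log OLS fit. The constant
accounts for static localization error, which adds 4σ_loc² at every lag:
with 20 nm noise and D = 2.8×10⁻³ μm² s^−α the floor is 1.6×10⁻³ μm² —
more than a third of MSD(2 s) — and a plain log-log fit is biased to
α ≈ 0.46 (analytically, not by sampling). The plain fit remains available
(`loc_error="none"`), as does subtraction of a known noise floor
(`loc_error=σ`). With the offset-aware fit, 200 trajectories × 300 frames
recover α = 0.54 within ±0.03 on the seed-mean and D within a few percent.

First-passage extrapolation solves 2·D·t^α = d² (two independently
subdiffusing loci; the relative-motion MSD is twice the single-locus MSD),
so t = (d²/2D)^{1/α}; a single-locus mode (D·t^α = d²) is kept for
sensitivity analysis. Extrapolating a power law fitted over tens of seconds
out to days assumes the law holds over five orders of magnitude in time —
treat the result as an order-of-magnitude statement; the API flags it as
extrapolated in the analysis outputs.

The fBm generator synthesizes exact fractional Gaussian noise by
Davies–Harte circulant embedding (Cholesky fallback when the embedding is
not non-negative, relevant for H near 1 at small n), with per-coordinate
variance D·τ^α/2 so the summed 2D MSD equals D·τ^α. The sample
autocovariance is tested against the fGn law at lags 0–10 within 3 SE at
10⁵ increments. Localization noise is iid Gaussian per frame; its
noise-only MSD contribution is 4σ² (2σ² per coordinate), which the tests
assert against a brute-force average.

## FRAP

Normalization is the standard double ratio
F₁(t) = (F(t)/⟨F⟩_pre)·(⟨W⟩_pre/W(t)) followed by full-scale rescaling
F₂ = (F₁ − F₁(t₀))/(⟨F₁⟩_pre − F₁(t₀)), anchoring the pre-bleach mean at 1
and the first post-bleach point at 0 exactly. A bleach depth near zero
(no-bleach control) makes the rescale degenerate; the curve is then
returned after the double normalization only, flagged. The recovery model
m·(1 − e^{−t/τ}) is a single-exponential; reaction–diffusion FRAP models
are out of scope.

## Nuclear foci and intensity bookkeeping

Nuclei: Otsu threshold (256 bins; verified against an exhaustive
between-class-variance search — thresholds inside the empty gap between
modes tie in the binned criterion, so equivalence is asserted on the
criterion value), hole filling, minimum size 20 μm² (2D) / 50 μm³ (3D),
8/26-connectivity. Foci and telomeres: 3D LoG with mean + 2 SD threshold
and a 4-voxel floor. A focus belongs to the nucleus containing its centroid
(counting semantics), and is colocalized when it shares ≥ 1 voxel with a
telomere object (threshold exposed as `coloc_min_voxels`, since the
reference plugin's criterion is undocumented). The damage classifier is the
fraction of nuclei with strictly more than 10 foci.

Coalescence bookkeeping treats integrated intensity as a volume proxy:
the predicted post-merge intensity is the sum of the two pre-merge means
(frames with exactly two objects), with SEs propagated in quadrature, and
conservation passes when |measured − predicted| ≤ 2 combined SE. On
noiseless fixtures the SE collapses to 0, so the test scale is floored at
1 % of the prediction to absorb discretization error; constructed
violations of ≥ 5 combined SE always fail.

The dilute-phase measurement takes c_tot as the mean nuclear intensity and
c_dil as the mean with detected bright puncta dilated by 1 px masked out,
warning when the mask covers over half the nucleus.

## Dilute-phase scaling models

Two generative/fit models are registered. Homotypic buffering:
c_dil = min(c_tot, c_star − e), with e ≥ 0 an endogenous-protein offset
(untagged protein participates in the equilibrium, so the tagged dilute
signal pins below the true threshold — this is why the buffered curve need
not be flat). Heterotypic stabilization: c_dil = c_tot − A·c_tot/(K + c_tot),
strictly increasing and sublinear for A < K. The heterotypic form is a
deliberately simple saturable-partner parameterization, registered behind
`DILUTE_MODELS` so a mechanistic model can replace it without touching the
selection machinery. Fits use 5 seeded multistarts; selection is by AICc
with |ΔAICc| < 2 → indeterminate, and when both models reproduce the data
to numerical precision (all c_tot below the buffering threshold, where the
models coincide) the comparison is declared indeterminate outright rather
than trusting information criteria on floored residuals. At 5 % noise over
a 30-fold concentration range, 12 points select the true heterotypic model
in ≥ 95/100 seeded replicates, approaching 100 % as noise → 0.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *geometry and statistics* the estimators
consume: non-overlapping blurred discs with Poisson-Gaussian-like noise at a
stated SNR, isotropic Gaussian puncta (σ = 1.3 px), exponential
aspect-ratio relaxation, exact fBm displacement statistics, closed-form
FRAP traces, and intensity ∝ volume photometry. They do not model
hydrodynamic neck growth during fusion, evanescent-field excitation,
camera-specific noise calibration, chromatic aberration, or anisotropic
PSFs. Passing recovery tests therefore demonstrates estimator correctness
under the stated generative assumptions, not robustness to every real-world
imaging artifact; the thresholds most sensitive to those artifacts
(detector sigmas, minimum sizes, colocalization voxels) are exposed as
configuration for that reason.

## Problem sizes and determinism

Default validation sizes — 20 seeds × 200 trajectories × 300 frames for the
MSD study, 50 seeded series for each c_sat recovery, 10 rendered movies for
fusion — keep the full test suite and the acceptance script in the tens of
seconds on one CPU while leaving seed-mean sampling error well inside the
asserted tolerances. Every stochastic step takes an explicit integer seed
through `numpy.random.default_rng`; no global RNG state is used, and
identical (parameters, seed) reproduce arrays bit-exactly.
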