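# Methods

## The statistic

Fully developed OCT speckle has Rayleigh-distributed amplitude. The
package's core statistic fits the three-parameter Rayleigh density

    P(x; a, b, c) = a (x − c) / b² · exp(−(x − c)² / (2 b²)),   x ≥ c
    P(x; a, b, c) = 0,                                          x < c

to the intensity histogram of a pooled region of interest. The printed form
of this density goes negative for x < c; a density cannot, so the curve is
extended by zero below the shift point (the standard shifted-Rayleigh
convention), which also keeps the least-squares objective meaningful.

An ROI is 6 × 6 × 10 voxels (depth × fast × slow), i.e. 45 × 45 × 37.5 µm
at the default pitch, pooled across all 24 repeat frames: 8640 pixels per
histogram. Pooling repeats is what gives the histogram enough occupancy for
a stable 64-bin fit.

### Fitting protocol

The histogram is equal-width over [min, max] with 64 bins by default
(≈ 135 expected counts per bin at n = 8640 — a balance of shape resolution
against multinomial noise; the bin count is a parameter). Heights are
density-normalized, so for a pure Rayleigh sample the fitted a ≈ 1 and any
departure of a from 1 measures shape mismatch — this is what makes a
comparable across ROIs of equal n and usable as a classification feature.

The fit is bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) on (bin centre, density) pairs:

* initialization: c₀ = min − 0.05·range, b₀ = mode-bin centre − c₀,
  a₀ = peak density · b₀ · e^{1/2} (exact for a noiseless Rayleigh);
* bounds: a ≥ 0, b ∈ (10⁻¹², 10·range], c ∈ [min − range, min];
* tolerances 10⁻¹² (xtol/ftol/gtol), ≤ 2000 evaluations.

Everything is deterministic: the same histogram always returns the same
coefficients. Multimodal or otherwise non-Rayleigh histograms are fitted
as-is — a low R² is the signal, not an error. `converged` is false only
when the optimizer fails or ends pinned at a bound; coefficients are still
reported. R² = 1 − SSE/SS_tot is computed on the bin heights about their
mean, so it is exactly the quantity a curve-fitting package would report
for the red curve drawn over a histogram.

Intensities are treated as linear amplitude throughout (no log
compression); negative shifts are allowed, since the fitted c of real
(preprocessed) OCT data can be negative.

## The phantom simulator

The simulator emulates the six materials of a lymph/nerve-mimicking
phantom: air, deep low-SNR noise, dyed water in a 305 µm lumen, a 400 µm
transparent rod, the 762 µm-outer-diameter semi-transparent tube wall, and
an Intralipid-gelatin scattering background. Geometry is analytic
(cylinders along the slow axis; a voxel belongs to a cylinder iff its
centre is strictly inside), so the label map is exact. Default volume:
150 × 200 × 32 voxels at 7.5 × 7.5 × 3.75 µm pitch with 24 repeat frames —
the repeat count, ROI footprint and tube/rod dimensions of the physical
phantom, with lateral extent scaled down to desk size. Repeats are modeled
at every slow position.

Per region, a voxel intensity is

    I = shift + b(z)·|Z| + b_nf·|Z_nf|,    Z, Z_nf ~ CN(0, 1)

with b(z) = base_scale · exp(−depth_attenuation · depth below the region
entry surface). Two mechanisms degrade the single-Rayleigh character:

* **Graded contamination** — with probability 1 − rayleigh_purity a
  voxel's scale is multiplied by a factor ramping linearly from 1 − g to
  1 + g over each ROI-depth-sized band (a sawtooth with 6-voxel period, so
  every analysis window sees the full ramp and pooled statistics do not
  depend on window placement). This models residual depth structure inside
  scattering media and produces mild R² loss.
* **Additive second component** (`noise_floor_scale`) — the sum of two
  comparable-scale Rayleigh amplitudes is no longer Rayleigh; this is the
  strong-degradation mechanism (a free three-parameter Rayleigh absorbs
  moderate scale *mixing* surprisingly well, but not amplitude *addition*).

Repeat frames share speckle through variance-preserving field mixing
Z_r = √(1−d)·Z₀ + √d·W_r with per-region decorrelation d ∈ [0, 1]. Mixing
the complex field rather than the amplitude keeps every frame exactly
Rayleigh for any d — interpolating amplitudes directly would corrupt the
marginal the whole analysis rests on.

All randomness flows through one PCG64 generator seeded explicitly;
regions are filled in fixed enum order, so config + seed reproduces a
volume bit-for-bit.

### Default region models

The per-region parameters (in `data/phantom_default.yaml`) were calibrated
once so that pooled 8640-pixel ROI histograms reproduce the characteristic
goodness-of-fit ladder of the six materials — air/noise ≈ 0.993, dyed
water ≈ 0.988, transparent solid ≈ 0.983, semi-transparent solid ≈ 0.96,
Intralipid ≈ 0.91 (< 0.93) — with comparable between-ROI spreads:

| region | b | c | purity | grade | noise floor | atten (µm⁻¹) | decorr |
|---|---|---|---|---|---|---|---|
| air                | 0.9 | −0.22 | 1    | –   | 0    | 0      | 1.0  |
| noise              | 1.1 | −0.20 | 1    | –   | 0    | 0      | 1.0  |
| dyed water         | 1.4 | −0.22 | 0.60 | 0.6 | 0    | 0      | 1.0  |
| transparent solid  | 1.8 | −0.26 | 0.50 | 0.8 | 0    | 0      | 0.9  |
| semi-transp. solid | 3.0 | −0.21 | 1    | –   | 0.81 | 0      | 0.6  |
| Intralipid         | 8.0 | −7.50 | 0.85 | 0.6 | 6.8  | 0.0008 | 0.75 |

Scales are arbitrary linear units; only ratios matter (the fit is scale-
equivariant). The strongly negative Intralipid shift mirrors the sign
structure seen in fitted c coefficients of scattering media. Decorrelation
values encode physics — detector noise and fluids decorrelate fully
between 25 ms-spaced frames, solids only partially — but have little
effect on pooled histograms except near d = 0 (24 frozen repeats would
reduce the effective sample 24-fold).

## Comparator features

**Depth-resolved attenuation.** The single-scattering tail-sum estimator
µ[i] = I[i] / (2 Δz Σ_{j>i} I[j]) on the repeat-averaged volume (Δz in
mm). It is exact up to discretization for a single-exponential A-line and
invariant to global intensity scaling. The deepest `tail_frac` = 0.1 of
samples is masked (too few tail terms), as are voxels with non-positive
tail sums. The classifier consumes the per-pixel µ at each sampled voxel.
No confocal/roll-off correction is applied.

**GLCM texture.** Within a 6 × 6 (depth × fast) window of the
repeat-averaged B-scan, intensities are quantized to 32 levels over the
window's own range; symmetric, normalized co-occurrence matrices are
accumulated at distance 1 along the four standard directions and averaged.
Energy follows the MATLAB/Haralick angular-second-moment convention
(Σ p²). Constant windows use the zero-variance convention (contrast 0,
correlation 0, energy 1, homogeneity 1). With 36-pixel windows and 32
levels the matrices are extremely sparse — these features are genuinely
weak at this window size, which is the point of the comparison.

## Classification study

Training pixels are window centres whose full 6 × 6 × 10 footprint lies
inside one region (morphological check against the label map) and where
every feature set is defined. A pool of up to 120 centres per region is
drawn once; each of the 10 randomizations re-draws 30 per region from the
pool and re-assigns stratified five-fold splits with a fresh seed. All
three feature sets (Rayleigh R²/a/c, attenuation µ, GLCM quadruple) are
extracted at the *same* pixels and trained identically: z-scoring fitted
on training folds only, RBF SVM with kernel scale √d/4 and box constraint
1 (the "fine Gaussian" preset re-specified explicitly), one-vs-one
prediction with one-vs-rest scores for per-class ROC. Overall accuracy is
the mean of the six per-class TPRs; its sd is across randomizations. The
ROC optimal point maximizes Youden's J = TPR − FPR (ties toward higher
TPR) — a concrete choice for "high sensitivity and high specificity".

In this phantom the main residual confusion is air ↔ noise: both are pure
speckle differing only in scale, and b is deliberately not a feature (it
discriminates poorly on real data). Real air regions additionally carry
complex-conjugate artifacts that the simulator does not model, so
per-class air behaviour on instrument data will differ.

## Flow study

Three lumen conditions — flowing dyed water, static dyed water, static
clear water — differ only in repeat decorrelation (1.0 flowing vs 0.9
static: Brownian motion alone decorrelates fluid speckle almost completely
between 25 ms-spaced frames) and a 2% absorption-driven intensity scale
for dye (food colouring absorbs but barely scatters at 1320 nm). Because
the fit is scale-equivariant and pooled histograms are insensitive to
weak repeat correlation, R² and a are insensitive to condition by
construction — matching the physical finding the study design emulates.
Ten ROIs per condition are fitted and every condition pair is compared on
R² and a with two-sided permutation tests on the mean difference
(5000 resamples), Holm-corrected at familywise α = 0.05. The correction is
essential to the study's logic: six raw tests at α = 0.05 would flag ~26%
of null datasets by chance.

## What the simulator does and does not emulate

It reproduces: Rayleigh amplitude statistics with controllable purity,
repeat decorrelation, depth attenuation, region geometry with exact labels,
and the per-region goodness-of-fit ladder with realistic between-ROI
spread. It does **not** model: coherent PSF convolution or spatially
correlated speckle (voxels are independent draws), complex-conjugate
artifacts, confocal roll-off, Doppler/flow dynamics beyond the
decorrelation knob, or detector saturation. Consequently, passing tests
demonstrate that the *analysis chain* behaves correctly on data with known
statistics — not that the specific accuracy numbers will transfer to
instrument data. One concrete caveat: the phantom's stereotyped geometry
(noise always deepest, air always on top) makes depth-coupled features
such as the attenuation comparator somewhat more informative than they
would be on real tissue.

## Problem sizes and numerical notes

The default studies use a 150 × 200 × 32 × 24 volume (≈ 92 MB float32,
≈ 2.5 s to generate), 2 phantoms × 10 ROIs × 6 regions for the fit
statistics, and 10 randomizations × 180 pixels for the classifier — sizes
chosen so a full reproduction runs in well under a minute on one CPU while
keeping every per-histogram sample at the full 8640 pixels. Fitted
absolute a magnitudes depend on whether histograms are count- or
density-normalized and on binning, none of which are standardized across
tools; only orderings and relative differences of a are meaningful.
Degenerate inputs are explicit errors (zero-range samples, < 4 occupied
bins, flat histograms) rather than NaN propagation.
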