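# Methods

## Statistical model

All repeatability statistics assume the one-way random-effects model for a
feature measured on lesion *i* at visit *j*:

    x_ij = μ + b_i + e_ij,   b_i ~ N(0, σ_b²),   e_ij ~ N(0, σ_w²)

Lesions are treated as independent sampling units. This ignores
patient-level clustering (several lesions can come from one patient), which
mildly overstates the effective sample size of real cohorts; it is the
standard per-lesion analysis and a documented limitation.

**ICC(1,1).** From the one-way ANOVA mean squares, MSB (between lesions,
df = n−1) and MSW (within, df = n(k−1)):
ICC = (MSB − MSW)/(MSB + (k−1)MSW). Negative estimates are reported as
computed — clamping at zero would distort the estimator's sampling
distribution and break the confidence-interval coverage checks. The 95% CI
is exact under the Gaussian model: with F = MSB/MSW,
FL = F/F₀.₉₇₅(n−1, n(k−1)) and FU = F·F₀.₉₇₅(n(k−1), n−1) give bounds
(FL−1)/(FL+k−1) and (FU−1)/(FU+k−1).

**Repeatability coefficient.** RC = 1.96·√2·wsd with wsd² = MSW (for k = 2,
wsd² = Σd_i²/2n with d_i the visit difference). The CI follows from
n(k−1)·wsd²/σ_w² ~ χ²(n(k−1)). RC carries the feature's units; ICC is
dimensionless, which is why cross-sequence comparisons in the pipeline use
ICCs.

**Gaussianity gating and Box–Cox.** Both estimators assume Gaussian
features. Each feature is screened with Shapiro–Wilk on values pooled
across both visits; the gate fails at p < α/m with α = 0.05 and m the
feature-panel size (105 for a full radiomics extraction; the pipeline
defaults to the number of features actually present). Failing features are
Box–Cox transformed with a single λ per feature, fitted on the pooled
values and applied identically to both visits so that visit pairing is
preserved. λ is selected by maximising the probability-plot correlation
coefficient over [−5, 5] with bounded scalar optimisation (xatol 1e−8);
maximum-likelihood selection is available (`method="mle"`) and agrees to
within a few tenths on well-behaved data. Features that remain non-Gaussian
("never") keep the transformed values downstream, since the transform still
moves them toward Gaussianity. Features with non-positive values are
shifted by −min + ε before transformation, ε scaled to max(range, |min|, 1)
× 1e−6; the shift is recorded per feature. The handling of non-positive
values is a package choice, flagged to users in the transformation report.

**Fisher-Z comparison.** ICCs from two datasets are compared as
z = atanh(ICC) differences. The SE uses 1/(n−3/2) per cohort — Fisher's
variance for intraclass correlations with k = 2 — because it tracks the
nominal type-I error more closely in simulation (≈4.5% at n = 50 versus
≈4.0% for the classic interclass 1/(n−3), which remains available via
`se_variant="classic"`). Cohorts are treated as independent even when the
same lesions underlie both datasets; this unpaired test is conservative in
that common setting and is a documented limitation. Significance is gated
at α/m (Bonferroni over features, not over dataset pairs).

## Image computation

**T1 mapping.** The SPGR steady-state signal S(α) = M0 sinα (1−E)/(1−E cosα),
E = exp(−TR/T1), is fitted voxelwise for (M0, T1). Initialisation uses the
closed-form DESPOT1 linearisation (slope of S/sinα on S/tanα equals E),
removing any dependence on arbitrary starting values; voxels where the
linearisation is degenerate fall back to T1 = 1000 ms. The refinement is a
Levenberg–Marquardt iteration run as a vectorised batch over all voxels:
the model has two parameters, so the damped normal equations are 2×2 and
solved in closed form per voxel, making whole-volume fits (64³ in a few
seconds) cheap and exactly deterministic. Convergence: relative cost change
≤ 1e−12 or 60 iterations. Default T1 bounds (1, 10000) ms; out-of-bound or
failed voxels are flagged in `fit_ok` with NaN T1, never clamped. All-zero
signal voxels are flagged without fitting. B1 inhomogeneity correction is
not applied.

**Normalisation and discretisation.** Linear normalisation maps the whole
volume to mean 0, SD 100 (the extraction-tool convention); statistics over
the full volume rather than the ROI is the default and is configurable
(`roi_only=True`), since either convention is defensible. Discretisation
uses fixed-width bins anchored at the ROI minimum,
level = floor((x − min)/w) + 1, default width 5; the number of bins then
adapts to the ROI range, and the pipeline records each lesion's bin count
(`n_bins`) so the median over lesions can be reported.

**Mask resampling.** Nearest-neighbour in world coordinates with the two
voxel grids' corners aligned, guaranteeing binary output and exact integer
up-sampling of axis-aligned cuboids. Down-then-up round trips lose boundary
voxels to blockification: Dice ≥ 0.9 holds for convex masks spanning
roughly ≥ 10 low-resolution voxels per axis, degrading to ≈ 0.89 at spans
of 7–8. Trilinear-plus-threshold resampling would be smoother but can
produce non-binary intermediates; nearest-neighbour is the conservative
choice.

**Features.** The feature set is a documented subset of a full radiomics
catalogue: every texture feature named in the repeatability results it
supports, plus exemplars per class (shape: voxel/mesh volume, surface area,
sphericity, elongation, major axis length, maximum 3D diameter;
first-order: mean, median, extrema, range, variance, skewness, kurtosis,
energy, total energy, RMS, MAD, IQR; GLCM inverse difference moment and
cluster shade; GLRLM grey-level and run-length non-uniformity; GLSZM small
area emphasis, size-zone non-uniformity (plain and normalised), grey-level
non-uniformity, large area low grey-level emphasis; GLDM dependence and
grey-level non-uniformity; NGTDM coarseness). Texture matrices use the 13
unique 3D directions at distance 1 (GLCM symmetrised per direction, GLRLM
runs broken by out-of-ROI voxels) and 26-connectivity (GLSZM zones, GLDM
dependence at α = 0, NGTDM neighbour means over in-ROI neighbours only).
Per-direction features are averaged over directions (matrix merging is the
other convention; averaging is the default here). Coarseness is capped at
1e6 when its denominator Σp_i·s_i vanishes (homogeneous ROI).

Mesh volume and surface area come from a marching-cubes isosurface of the
mask after light Gaussian pre-smoothing (σ = 0.7 voxels). Smoothing
suppresses the staircase inflation of surface area on binary masks (a raw
binary isosurface overestimates a digitised ball's area by ~10%, biasing
sphericity to ~0.90; with smoothing a radius-8 ball yields sphericity
≈ 0.99 and volume within ~2% of analytic); if smoothing collapses a thin
mask below the iso-level, the raw mask is used. Elongation is
√(λ₂/λ₁) of the voxel-coordinate covariance eigenvalues, major axis length
4√λ₁, maximum 3D diameter the largest pairwise distance between surface
voxel centres (convex-hull accelerated). Single-voxel masks return NaN for
mesh-based features, flagged rather than raised.

## Synthetic-data generator

The generator is the validation instrument: every estimator is checked by
parameter recovery against its known truth.

* `simulate_feature_table` draws from the one-way model above, so true
  ICC = σ_b²/(σ_b²+σ_w²) and true RC = 1.96√2·σ_w are known exactly.
  Optional skew passes the Gaussian values through the *inverse* Box–Cox
  map with a known λ, so the forward transform with that λ restores
  Gaussianity exactly; out-of-domain draws raise (naming λ and the data
  range) rather than being clipped, keeping the generative truth exact.
  The synthetic study panel spans true ICCs from ≈0.26 to ≈0.99 with a
  log-normal (λ = 0) and a square-root (λ = 0.5) skewed feature per
  sequence, emulating the observed mix of Gaussian and skewed features;
  the default cohort is 134 lesions, two visits.
* `simulate_vfa_phantom` builds SPGR volumes at flip angles 2°/10°/20°,
  TR 4 ms, from known M0/T1 maps with an ellipsoidal lesion (defaults:
  background T1 500 ms, lesion 800 ms — liver-like at 1.5 T) plus
  additive Gaussian noise.

What the generator does **not** emulate: realistic anatomy or texture
correlation structure, breathing motion, contrast-agent kinetics, Rician
noise at low SNR, patient-level clustering of lesions, or scanner drift
between visits. Passing tests therefore demonstrate the correctness of the
estimators and image operators under their stated model, not the clinical
repeatability of any particular feature.

## Problem sizes and numerical choices

Validation runs use 2000 simulated cohorts of 50 lesions for CI coverage
and type-I-error checks (binomial 3-SE tolerance ≈ 1.5 percentage points),
100,000 subjects for RC containment, 64³ voxels for noiseless T1 recovery,
and ≤ 5³ ROIs for exact brute-force texture-matrix equivalence — sizes at
which the Monte-Carlo error bounds quoted in the tests hold. Seeds are
fixed throughout; a single top-level seed fans out to per-stage seeds via
SHA-256, so any stage can be reproduced in isolation.

Known limitations: unpaired Fisher-Z comparisons (above); per-lesion
independence; the feature subset does not aim at full catalogue parity
with any extraction tool; coarseness correlates *negatively* with ROI size
on noise textures (its denominator grows with voxel count) even though the
association with volume is strong in absolute rank correlation — size
confounding should be assessed with |ρ|, as the pipeline's
volume-confounding report does.
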