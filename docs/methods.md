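# Methods

`ctradiomics` implements a quantitative CT phenotype pipeline for tumor
prognosis studies: tumor segmentation, high-throughput texture/shape
descriptor extraction, per-feature predictive ranking, and a survival
analysis stage. Because real patient cohorts cannot ship with the package,
every stage is validated against a synthetic cohort generator that plants
known, recoverable statistical structure. This note records the models,
conventions, numerical choices and their rationale.

## Synthetic cohort generator

Each patient is an ellipsoidal tumor (elevated mean intensity, 40 HU) on a
darker background (−50 HU) inside a 3D grid with physical voxel spacing.
Intratumoral heterogeneity is a stationary Gaussian random field built by
filtering white noise with a Gaussian kernel whose width is the
*correlation length* (mm) — the single texture knob. The field is
restandardized to SD 25 HU; i.i.d. acquisition noise of SD 10 HU is added
everywhere. Larger correlation lengths give smoother (less heterogeneous)
texture and, downstream, higher co-occurrence correlation; this
monotonicity is covered by a test. The `corr_length -> inf` limit yields a
flat interior whose variance is exactly the additive-noise variance.

Class labels (histology or stage surrogates) are drawn from `class_probs`
and determine the patient's correlation length, so labels are statistically
linked to texture and nothing else. Survival times are exponential with
hazard `h0 * exp(beta * status)` where `status` is 1 for the class with the
longest correlation length; censoring is an independent exponential whose
rate is solved by bisection (Brent) so that the expected censored fraction
equals `censor_rate` — `P(censored | hazard h) = c/(c+h)` averaged over the
cohort is monotone in `c`, so the root is bracketed. Clinical covariates
(age ~ N(60, 11²) years, sex 65/35, smoking Bernoulli(½)) are independent
of the image by default so that multivariate Cox adjustment can be
exercised without confounding.

All randomness flows through NumPy's PCG64 generator; a fixed design seed
reproduces volumes, masks and the clinical table bit-for-bit.

What the generator does **not** emulate: CT physics (beam hardening,
reconstruction kernels, contrast kinetics), lung anatomy, lesion-adjacent
structures (vessels, pleura), or the marginal distributions of any real
cohort. Passing tests therefore demonstrate that the *statistical
machinery* recovers planted structure under its own assumptions — not that
the pipeline generalizes to clinical images.

## Segmentation

Seeded region growing with multi-scale constraints, a principled re-design
of that method family (the published variant it emulates is not specified
in enough detail to reproduce). The volume is smoothed at each scale in
`scales` (Gaussian widths in mm; scale 0 = original). A candidate voxel is
accepted iff at *every* scale its smoothed intensity is within
`intensity_tolerance` of the running mean of the accepted region in that
same smoothed volume. Fine scales block single-voxel noise leaks; coarse
scales block thin bridges into the background. Exploration is best-first
(smallest deviation at the coarsest scale), growth is 26-connected, stops
at `max_radius` (mm from the seed), and ends with a morphological closing
(ball of `closing_radius` voxels) that never removes accepted voxels.
Defaults (tolerance 30 HU, scales 0.5/1.5 mm, closing 1) give Dice ≥ 0.95
on noisy high-contrast phantoms and degrade monotonically with noise. If no
neighbor is acceptable the seed alone is returned with a warning (the
radiologist-fallback `--manual-mask` bypass exists in the CLI).

## Derived images

Wavelet sub-bands are a one-level 2D discrete wavelet transform applied
slice-wise to the ROI bounding-box patch, giving the four canonical bands
LL/LH/HL/HH (a 3D transform would give eight bands and is out of scope).
The default wavelet is the orthonormal Haar (none is mandated by the
descriptor taxonomy; configurable), boundary handling is symmetric padding.
For even slice sizes the transform conserves energy to 1e−6 relative and
reconstructs perfectly to 1e−8.

Gabor maps come from complex kernels (Gaussian envelope × complex carrier)
with one-octave bandwidth, default 1 scale (0.15 cycles/voxel) × 30
orientations evenly spaced over [0, π). The kernel DC is subtracted exactly,
so magnitude responses are invariant to constant intensity offsets — the
reason the kernels are built in-package rather than taken from
scikit-image, whose kernels are only approximately zero-mean. Frequencies
above Nyquist (wavelength < 2 voxels) are rejected as aliasing. Magnitude
maps feed "MTR" statistics, phase maps "PTR" statistics (mean, variance,
histogram entropy).

## Quantization and matrix textures

Matrix features operate on `Ng` equal-width gray levels over the in-mask
[min, max] (default Ng = 32; no canonical value exists, so it is
configurable and recorded). Equal-width min–max binning makes the level map
invariant to positive affine intensity rescalings.

Co-occurrence matrices use in-plane voxel offsets `(d_row, d_col)`; pairs
with both endpoints in-mask are counted per slice, symmetrized by adding
the transpose, pooled by summing counts over slices, then normalized. The
offset notation `CO [a, b]` in feature names is read as `(d_row=a,
d_col=b)`; this is a documented convention, configurable per extraction.
Features: correlation Σ(i−μx)(j−μy)p/(σxσy), contrast Σ(i−j)²p, variance
Σ(i−μ)²p with μ the grand mean level, energy Σp², entropy −Σp·log₂p.
Correlation on a flat texture (zero marginal SD) is reported as missing
(NaN), never a crash.

Run-length matrices count maximal same-level runs along three in-plane
directions (RL1 = 0°, RL2 = 45° anti-diagonal, RL3 = 90°), truncated at the
mask boundary, pooled over slices like the GLCM. Since every in-mask voxel
belongs to exactly one maximal run per direction, Σ j·r(i,j) equals the
in-mask voxel count — a tested invariant. Features are the Galloway-style
emphases SRE, LRE, LRLGE, LRHGE and run-energy Σ(r/N_r)².

Every matrix builder and feature is checked to 1e−12 against naive
brute-force enumerations on random small images.

## Full-catalog extraction

`extract_all` computes, per patient: histogram statistics (mean, variance,
skewness, Pearson kurtosis, histogram energy/entropy), GLCM and RLM
features on the original ROI and on each wavelet band; Gabor MTR/PTR
statistics on the LL band; and 3D shape descriptors. The default catalog
enumerates 5 images × (6 histogram + 6 offsets × 5 GLCM + 3 directions × 5
RLM) + 30 orientations × 5 Gabor statistics + 4 shape = **409 named
features**; `catalog()` returns the stable name list and the CLI can dump
it. Original-image statistics use in-mask voxels only; band features use
the full half-size band patch after out-of-mask voxels are replaced by the
in-mask mean (avoiding an artificial tumor/background edge that would
dominate the detail bands — a documented trade-off: band features see a
little background context). Matrix pooling makes all texture features
invariant to slice-order permutations. Any sub-feature failure is logged
and recorded as NaN; rows always carry the complete catalog.

## Shape and first-order statistics

Surface area comes from a marching-cubes triangulation at spacing-aware
coordinates. Triangulating the raw binary grid overestimates a ball's area
by ~8% (stair-step artifact), so the mask is pre-smoothed with a one-voxel
Gaussian before extracting the 0.5-level surface; the enclosed volume is
then computed from the same mesh via the divergence theorem, which makes
sphericity = π^(1/3)(6V)^(2/3)/A respect the isoperimetric bound (≤ 1) by
construction and puts a radius-20 digital ball at 0.997. Compactness is
V/(√π·A^{3/2}). Kurtosis uses the Pearson (non-excess) convention —
Gaussian = 3; skewness is moment-based g1. Histogram energy/entropy use a
fixed 64-bin equal-width histogram. Zero-variance samples report
skewness/kurtosis as missing.

## Feature ranking

Each feature is scored alone: stratified 5-fold CV; per fold the training
split is median-imputed and standardized (no leakage), a linear SVM (C = 1)
is fitted on the single feature, and held-out accuracy recorded; the score
is the fold mean. The kernel and C are not canonical — linear with C = 1 is
the simplest max-margin choice and is configurable in code. Accuracy is
fold-averaged (vs fold-pooled; either is defensible, one had to be chosen).
Ties are broken lexicographically by name, so rankings are bitwise
reproducible given (table, labels, cv_seed). Constant features score 0.5 by
convention and are flagged. An optional independence filter prunes features
with pairwise |r| > 0.95.

The stability curve refits the same classifier on the top-k features over a
k grid, pools held-out decision scores across folds into one ROC, and takes
the trapezoidal AUC. Note a protocol subtlety: at k < p the curve inherits
selection bias when the labels being evaluated also drove the ranking
(winner's curse, ~+0.1 AUC under the null at p = 20–51); null-calibration
checks therefore evaluate k = p, where no label-driven selection occurs.

## Survival stage

Signatures are min–max normalized to [0, 1] **within each cohort** (pooled
normalization would leak scanner/protocol differences), then dichotomized
at the cohort median — value > median is high (status 1), the median
element itself goes low (a documented tie policy). Cox proportional-hazards
models (lifelines) use the Efron approximation for ties, since month-scale
survival times tie often; Wald 95% CIs and two-sided p-values are reported,
significance at p < 0.05. Kaplan-Meier curves use the product-limit
estimator; the median is the earliest time with S(t) ≤ 0.5, "not reached"
(inf) if the curve never drops that far.

The weighted log-rank test is the Harrington–Fleming G-rho family with
weights S(t−)^ρ from the left-continuous pooled Kaplan-Meier estimate,
default ρ = 1 (emphasizing early differences); ρ = 0 reduces exactly to
the standard log-rank test, verified against an independent implementation
to 1e−10. Agreement between parallel measurements uses ICC(2,1) — two-way
random effects, absolute agreement, single measure (the specific ICC form
is a documented choice) — computed from the crossed ANOVA decomposition and
cross-checked against an independent implementation. The Kruskal-Wallis H
test (tie-corrected, chi-square p) compares signature distributions between
datasets. Censored records are fully supported; an events-only filter
reproduces the inclusion rule of complete-follow-up cohorts.

## Problem sizes and calibration checks

The test suite validates, among others: brute-force texture equivalence on
100 random ≤ 8×8 images; planted-feature ranking recovery (1 informative +
50 noise features, n = 80, 100 CV seeds); Cox recovery of a planted hazard
ratio of 2 at n = 500 over 200 replicates with Wald CI coverage; type-I
error of the G-rho test and Kruskal-Wallis over 1000 null replicates
(nominal band 3.5–6.5% at α = 5%); and five full simulate → extract → rank
→ survive runs on 150-patient cohorts with a texture-linked hazard ratio
of 2. End-to-end runs use a reduced extraction catalog (Ng = 16, two
offsets, two run directions, no Gabor) — the planted signal lives in the
co-occurrence/histogram families, and the reduced catalog keeps the
whole-cohort extraction fast without changing what is being tested.

A calibration caveat worth knowing: with ~400–500 events, the sampling SD
of the fitted log hazard ratio is ≈ 0.09–0.10, so the probability that a
single fit lands inside the fixed window [1.7, 2.3] around a true HR of 2
is ≈ 0.87–0.91 (the window is asymmetric on the log scale). A check
demanding ≥ 90% of fits inside that window at n = 500 sits at or slightly
above the true rate and can fail honestly; the corresponding test is kept
faithful rather than widened, and the CI-coverage check (93–97% observed)
is asserted separately.

## Known limitations

- Texture features are 2D in-plane (per-slice, pooled); fully 3D offsets
  and 13-direction run-length analysis are not implemented.
- The segmenter assumes a roughly homogeneous lesion brighter than its
  surroundings; juxtapleural or cavitating lesions are out of scope.
- The Gabor bank uses one scale by default; multi-scale banks are possible
  via configuration but untested beyond smoke level.
- Proportional-hazards diagnostics are limited to what lifelines exposes;
  no Schoenfeld-based model criticism is automated.
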