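# Methods

`radtex` implements a small-cohort radiomics analysis for discriminating
brain-tumor tissue from peritumoral edema on 2D MR regions of interest
(ROIs): mask-aware texture feature extraction, per-ROI intensity
normalization, two-reader LASSO-consensus feature selection and
ROC/threshold/kappa evaluation, validated end to end against a synthetic
cohort with known planted contrasts. This note records the model choices,
conventions, and their rationale.

## Study structure and unit of analysis

The analysis assumes the two-tissue, two-reader, multi-sequence design of a
small prospective imaging study: per patient and pulse sequence
(FLAIR, ADC, T1W, T1W+C, T2W), two contoured ROIs (tumor and edema), each
segmented independently by two readers on the same acquired image, with the
contour replicated across co-registered sequences. Each ROI (optionally one
per slice) contributes one row to the feature table; the scenario grid over
which selection and evaluation run is disease × normalization mode ×
sequence. Univariate AUCs and threshold rules are computed on both readers'
rows pooled (the design leaves the unit of analysis open; pooling doubles
the effective n at desk scale), while LASSO selection is strictly
per reader, as the consensus procedure requires.

## Intensity normalization and quantization

Two preprocessing scenarios are analyzed side by side:

* **none** — features on raw MR intensities;
* **p1_99** — each ROI is clipped to the band between the 1st and 99th
  percentile of its own masked intensity histogram and mapped linearly onto
  [0, 1]. The output scale is a package convention (the normalization is
  defined up to an affine map); thresholds reported for normalized
  scenarios are therefore scale-relative. Because the map is per-ROI, it
  removes between-ROI location and scale: a tissue contrast that is purely
  a brightness shift is *eliminated* by normalization, and normalized
  scenarios are expected to lose first-order signal. A constant ROI has no
  band to map and is returned all-zero with a degenerate flag rather than
  an error.

All percentiles in the package (the normalizer bounds, the histogram
percentile features, every test oracle) use one convention — linear
interpolation between closest ranks ("type 7") — implemented in exactly one
place, because percentile thresholds are convention-sensitive.

For the co-occurrence and run-length matrices, masked intensities are
discretized into `n_levels` equal-width bins over the masked min–max range
(level = 1 + floor(n·(v−min)/(max−min)), max → level n, 0 outside the
mask). The default `n_levels = 64` (configurable 8–256) is a conventional
radiomics operating point: fine enough to resolve texture, coarse enough
that a few-hundred-pixel ROI populates the matrix. Equal-width binning over
the observed range makes the level raster — and hence every matrix
feature — exactly invariant to positive affine intensity maps.

## Feature families

**First-order (HIST_, 20 features).** Population moments (mean, variance,
SD, skewness, non-excess kurtosis — a normal sample gives ≈ 3), histogram
energy/uniformity (both Σp², emitted under both conventional names) and
entropy in bits over a 256-bin histogram of the masked range, percentiles
1/10/50/90/99, Tamura-style coarseness, directionality and contrast, and
four moments of the absolute finite-difference gradient magnitude
(central differences where both axis neighbours are in-mask, one-sided at
the mask boundary, pixels with no in-mask neighbour excluded). The Tamura
triple follows the classic definitions with two documented conventions:
contrast = σ / kurtosis^0.25, and directionality summarized as the
magnitude-weighted circular resultant of doubled gradient orientations
(0 = isotropic, 1 = one dominant direction); the exact equations behind
these three names vary across the literature, so they are flagged as
convention-dependent rather than canonical.

**Second-order (GLCM_, 22 × 5 distances × 4 angles = 440).** The
co-occurrence matrix P(i, j | d, θ) is accumulated over every ordered pixel
pair whose *both* endpoints are inside the mask (the ROIs are irregular
contours, so a rectangle-based implementation would leak background), then
symmetrized by adding the transpose and normalized. Offsets, with image
rows increasing downward: 0° → (0, +d), 45° → (−d, +d), 90° → (−d, 0),
135° → (−d, −d); symmetrization makes θ and θ+180° equivalent, so four
angles cover all eight neighbours. Diagonal displacement takes d steps
along each axis (Chebyshev convention). The 22 statistics are the
classical set — autocorrelation, contrast, correlation, cluster
prominence/shade/tendency, dissimilarity, energy (ASM), entropy,
homogeneity (IDM), inverse variance, maximum probability, sum of squares,
sum average/variance/entropy, difference variance/entropy, the two
information measures of correlation, and the normalized inverse-difference
pair — with base-2 logs, 0·log 0 := 0, IMC2 = sqrt(1 − exp(−2(HXY2 − HXY)))
clamped at 0. "Cluster tendency" and "sum of squares" overlap in some
canonical lists; both are emitted under distinct names with the formulas
above. Vanishing denominators (e.g. correlation on a constant ROI) flag the
feature undefined (stored as 0 with an explicit flag, never a silent NaN).

**Higher-order (GLRLM_, 13 × 4 angles = 52).** Runs are maximal collinear
in-mask segments of constant gray level; a mask gap terminates a run, which
gives the conservation law Σ ℓ·r(i, ℓ) = masked pixel count per angle —
asserted as a property test and recomputed in the acceptance script.
Diagonal traversal enumerates every 45°/135° line through the bounding box
clipped to the mask. The 13 statistics are the standard run emphases,
non-uniformities, run percentage (runs / pixels) and the gray-level and
run-length variances over the run distribution p(i, ℓ) = r(i, ℓ)/n_runs.

Feature names encode family, statistic and displacement
(`GLCM_Correlation_d1_a090`, `GLRLM_GLN_a000`, `HIST_Percentile90`), so a
selection can be audited against the extraction configuration.

## Selection: per-reader LASSO and consensus

Within each scenario, tumor-vs-edema is modelled per reader by L1-penalized
logistic regression (binomial family, logit link) on z-standardized
features; columns with any undefined value or zero variance are dropped
first, and both readers are fit over the shared surviving namespace. The
penalty path follows the reference coordinate-descent conventions: a
geometric grid of 60 values from λ_max (the smallest penalty that zeroes
every coefficient) down to λ_max/100, truncated where the full-data
deviance ratio reaches 0.999 — without that truncation, on a separable
table the cross-validated deviance decreases monotonically and "λ with
minimal prediction error" degenerates to the bottom of the path. λ is then
chosen to minimize the 10-fold stratified cross-validated binomial
deviance (fold assignment fixed by the seed, default 20181008, so reports
are bit-reproducible); ties keep the larger (more parsimonious) λ. Nested
cross-validation is deliberately not used at this sample size.

The consensus set is the intersection of the two readers' nonzero-support
sets: empty-while-either-selected is reported as `no_agreement` (rendered
"NA"), both-empty as `none_selected`. No cap is placed on set size. Note a
structural property of the design: because both readers contour the *same*
image, a feature that looks discriminative by chance for one reader tends
to look so for the other, so consensus removes reader-specific instability
but not shared-noise selections — small numbers of co-selected bystander
features beside the true signal are expected, and the evaluation stage
(most-useful parameter, perfect-threshold rules) is what identifies the
substantively discriminating features.

## Evaluation

AUC is the Mann–Whitney statistic (ties counted half), oriented so
AUC ≥ 0.5 with the direction recorded, with a 95% CI from the DeLong
structural-component variance (the CI method is a package choice; the
variance is zero under perfect separation and the CI collapses onto the
estimate). Per scenario the report gives each consensus feature's
univariate AUC, the most-useful (highest-AUC, ties reported jointly)
parameter, a multivariable AUC from an unpenalized logistic refit on the
consensus set (relaxed-LASSO-style reporting), and single-feature threshold
rules: when the class ranges are disjoint the cut is the midpoint between
the boundary observations and the rule is marked perfect; otherwise the
best-accuracy midpoint is reported (ties toward the smaller cut).
Inter-reader agreement is Cohen's κ between the two readers' rule-based
classifications of their own ROIs, with the degenerate convention κ = 1
when both raters use a single identical category (p_e = 1 with perfect
observed agreement).

ADC maps are computed voxelwise from a b = 0 / b = 1000 s/mm² pair as
ADC = ln(S0/Sb)/b, with both signals floored at 10⁻⁶ of the median b=0
signal to keep the logarithm finite; the result is invariant to common
positive rescaling of the pair.

## Synthetic cohort: what it emulates and what it does not

The generator reproduces the *statistical* structure the analysis assumes,
at the emulated study's size: 17 GBM + 8 meningioma patients, 2 slices per
patient, five sequences as independent contrast re-parameterizations of the
same slice geometry (per-sequence base mean/SD at plausible MR scales, e.g.
ADC ≈ 1.1·10⁻³ mm²/s), elliptical masks with jittered boundaries
(semi-axes 9–14 px on a 64×64 raster), a per-patient brightness offset
(SD 0.2 of the sequence SD) shared by both tissues, and a second reader
whose masks are random one-pixel erosions/dilations of the first reader's
(Dice ≥ 0.8 enforced).

Texture fields are white Gaussian noise smoothed by an isotropic Gaussian
kernel of scale `corr_len`; the in-mask values of each contoured ROI are
then rank-mapped onto an exact Gaussian quantile grid at the target
mean/SD. The rank map is monotone, so the spatial correlation structure —
and hence the co-occurrence signal — survives, while the within-ROI
marginal histogram is *identical* across correlation lengths. This exact
marginal matching is what makes the GBM arm a clean second-order testbed:
moment-only matching leaves a residual percentile signal (extreme sample
quantiles of a correlated field are systematically inward-biased, worth
AUC ≈ 0.7 at this n), which would confound the "texture-only" ground truth.

Planted contrasts:

* **meningioma arm** — tumor mean offset by 1.5 sequence-SD at equal
  correlation length (1.0 px) for both tissues: first-order features
  discriminate, texture is matched;
* **GBM arm** — tumor correlation length 2.5 px vs white-noise edema at
  exactly matched marginals: co-occurrence features discriminate,
  histogram percentiles carry no signal by construction.

The ground-truth ledger emitted with each cohort records these families,
and the acceptance checks verify the full pipeline recovers them.

What the generator does **not** emulate: MR physics (bias fields, partial
volume, Rician noise, acquisition resolution differences), anatomically
realistic contour shapes, between-sequence intensity correlation within a
patient, or disease heterogeneity. Passing the planted-signal checks
therefore shows the *pipeline* is sound — extraction measures what it
claims, selection finds what is there, evaluation reports it faithfully —
not that any particular feature discriminates real tumor from real edema.

## Numerical conventions and degenerate inputs

* Masks need ≥ 16 pixels (configurable); smaller regions raise a
  degenerate-input error at construction.
* Matrices with no valid pair/run (mask too small for the displacement) are
  empty-flagged; their features are flagged undefined, and any feature
  column containing an undefined value is dropped before selection
  (conservative, documented rule).
* Undefined features are always explicit flags (rendered NaN only in CSV),
  never silent NaNs.
* Deviance uses probability clipping at 10⁻¹²; the liblinear subproblem is
  solved to tol 10⁻⁷ with a fixed internal seed.
* All simulation randomness flows from a single `numpy` Generator seed;
  fixed seed ⇒ byte-identical feature tables and reports.

## Problem sizes

Default problem sizes were chosen so that a full simulate → extract →
select → evaluate run (1000 ROIs × 2 normalization modes × 512 features,
40 cross-validated LASSO fits) completes in a few minutes on one CPU, which
is also the scale at which the validation suite runs it. Oracle checks use
hundreds of small random rasters (≤ 12×12, ≤ 8 levels) where brute-force
enumeration is exact and fast.

## Known limitations

* The Tamura triple and the "~300 vs 512 features" bookkeeping follow
  package conventions where the field's naming is ambiguous; both are
  documented above rather than asserted as canonical.
* DeLong CIs are asymptotic and degenerate under perfect separation —
  expected and flagged at desk-scale n.
* The DICOM/NIfTI adapters handle single-frame 2D slices only; masks must
  arrive pre-rasterized (no contour rasterization, no partial pixels).
* Mask transfer assumes co-registered grids (identical or trivially
  resampleable); there is no registration.
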