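# Methods

`periradiomics` implements a complete intratumoral + peritumoral CT
radiomics analysis for discriminating minimally invasive (MIA) from
invasive (IAC) lung adenocarcinoma presenting as subcentimeter nodules,
together with a synthetic cohort generator that stands in for the
(non-deposited) clinical imaging data.  This note records the model,
the defaults, the numerical choices, and what the synthetic results do
and do not demonstrate.

## Regions of interest

Three nested ROIs are derived from a nodule segmentation:

* **GTV** — the segmented gross tumor volume (an input; automatic
  segmentation is out of scope);
* **GPTV** — the GTV dilated outward by a physical margin, default
  5 mm, motivated by histologic microscopic-extension distances in
  adenocarcinoma;
* **GPR** — the peritumoral shell, `GPTV \ GTV`.

Dilation is exact Euclidean: a voxel joins the dilated set iff its
center lies within the margin of some foreground voxel center, computed
with a spacing-aware distance transform (never iterated structuring
elements, which accumulate chamfer error).  Dilation happens after
resampling to 1 mm isotropic voxels so "5 mm" is exact on the working
grid.  If the margin would leave the field of view the volume is padded
with air (−1024 HU) and a warning is raised; the margin is never
silently truncated.  Dilation is not geodesically restricted to lung
parenchyma — the study grid contains only lung — but callers can mask
non-lung voxels out of the result.

## Preprocessing

* Lung-window intensity normalization `(HU − (−600)) / 1500`, exposed
  as an explicit step.
* Resampling to 1×1×1 mm³ with cubic B-spline interpolation for
  intensities and nearest-neighbor for masks.
* Gray-level discretization with a fixed 25 HU bin width anchored at
  the ROI minimum: `level = floor((x − min)/25) + 1`.

Discretization operates on **original HU values**, not on the
window-normalized values: a 25-unit bin applied to a [−0.5, 0.5]-ranged
normalized image would collapse every ROI to one gray level.  Whether
the upstream clinical toolchain binned before or after its
normalization is not recoverable; this package's order (resample →
ROI geometry → per-ROI HU discretization → texture matrices) is the one
that keeps the stated bin width meaningful, and both the normalization
and the bin width are configurable.

## Radiomic features

Per ROI: shape features from the mask (voxel volume, marching-cubes
surface area, sphericity, maximum 3D diameter, elongation, flatness,
surface/volume ratio) and, from the discretized intensities, 16
first-order features plus the five standard texture families — GLCM,
GLRLM, GLSZM, GLDM, NGTDM — implemented from scratch and verified
against brute-force enumeration oracles on random arrays.  Conventions
where the field offers choices:

* 13 unique 3D directions at Chebyshev distance 1; GLCM matrices are
  symmetrized and normalized per direction and features are averaged
  over directions (GLRLM likewise).
* GLSZM zones are 26-connected; GLDM uses dependence tolerance
  alpha = 0 with dependence *size* = dependent neighbors + 1; NGTDM
  uses the available 26-neighbors at edges.
* Degenerate ROIs (single voxel / single level, no valid pairs) return
  0 for texture features, with GLCM correlation = 1.
* Surface meshing smooths the binary mask with a 0.7-voxel Gaussian
  before marching cubes; the raw 0/1 staircase mesh overestimates a
  sphere's area by ~8% (sphericity 0.93 instead of ~1).  Thin masks
  whose smoothed field loses the 0.5 level fall back to the binary
  mesh.

An optional filter bank (8 stationary-wavelet sub-bands, `coif1`, and
Laplacian-of-Gaussian images at configurable physical sigmas) feeds
every derived image through the first-order + texture families.  The
feature count is a configuration outcome: 8 shape + (1 + n_derived) ×
110 per ROI (1,218 with the full default filter bank; 118 with filters
off, the default used by the pipeline for tractability).  Catalogue
sizes in the thousands quoted for commercial platforms are reachable by
enlarging the sigma list and wavelet levels, and are deliberately not a
contract.

## Feature selection and Radscore

1. **Stability (ICC)** — features with inter-rater ICC(2,1) < 0.75 are
   discarded.  ICC(2,1) is the two-way random-effects, absolute-
   agreement, single-rater form from the ANOVA mean squares; a
   zero-variance matrix is defined as ICC 1.  The second "rater" in the
   synthetic pipeline is emulated by 1-voxel random boundary patches on
   the segmentation.  The 0.75 threshold is the conventional "good
   reliability" cut.
2. **Redundancy (mRMR, MID)** — greedy ranking with score =
   relevance − redundancy.  Relevance is the class-association
   F-statistic mapped to the point-biserial correlation scale
   `sqrt(F/(F+n−2))` so that it is commensurate with the redundancy
   term (mean |Pearson r| against already-selected features); a raw
   F-statistic would dwarf redundancy and never discard a duplicated
   column.  Ties break by feature name.  Default keep: 30, bracketing
   typical post-LASSO signature sizes (13–28).
3. **Sparsity (LASSO)** — L1-penalized logistic regression on
   column-standardized features over a 40-point log-spaced penalty
   path (`lambda_max` down 3 decades), penalty chosen by 10-fold
   stratified cross-validated binomial deviance, minimum rule by
   default (`1se` available).  Solutions come from liblinear followed
   by an L-BFGS polish on the active set with signs fixed, giving
   KKT residuals below 1e-6.  Coefficients are reported on the original
   feature scale.  Rows are canonicalized by case id, so the fit is
   exactly invariant to input row order, and fold assignment depends on
   (seed, case id), never position.

The **Radscore** is the fitted model's predicted probability
(inverse-logit of the linear predictor), a [0, 1] quantity consistent
with probability-style cutoffs; the linear predictor is exposed as an
alternative output.

## Predictive models and evaluation

Four deliberately isolated logistic models: CT features (maximum
diameter + vessel convergence sign only) and one per Radscore (that
Radscore as sole predictor).  Fitting is maximum likelihood via IRLS
(statsmodels GLM), convergence tol 1e-8, 100 iterations; complete or
quasi-separation triggers a flagged ridge-penalized fallback.  Both
apparent (resubstitution) and stratified 10-fold out-of-fold
probabilities are reported, labeled distinctly.

Evaluation: empirical ROC with AUC = Mann-Whitney U/(n₁n₀) (ties ½);
Youden-index cutoff (ties → lowest threshold); DeLong
structural-components variance, Wald CIs, and paired tests; stratified
percentile-bootstrap AUC CIs (default 2000 replicates); Hosmer-Lemeshow
over deciles of risk (equal-count bins, ties grouped, df = bins − 2);
decision curves with net benefit `TP/n − (FP/n)·p_t/(1−p_t)` against
treat-all/treat-none, grid 0.01–0.99, and the "useful range" reported
as the interval where the model beats both references.

**Leakage note.**  `run_study` reproduces the single-cohort design:
Radscores are built on the full cohort, then the one-predictor models
are cross-validated.  That estimate is optimistically biased —
dramatically so near the null — because every case helped choose the
signature.  `nested_radscore_auc` re-runs the entire selection chain
inside each training fold and is the honest out-of-fold estimate; the
null-control tests use it.

## Clinical statistics layer

Closed-form 2×2 Pearson and Yates-corrected chi-square, Fisher's exact
test, Wald odds ratios (z = 1.96 exactly; Haldane 0.5 correction
flagged on zero cells), Mann-Whitney U (exact for pooled n ≤ 12 without
ties), a Shapiro-Wilk–gated t-test/MWU dispatcher, and univariable /
multivariable logistic regression.  Baseline tables dispatch 2×2 tests
by expected counts: Pearson when all ≥ 5, Yates when any < 5, Fisher
when any < 1 — the rule that exactly reproduces every reconstructable
statistic in the study's baseline table from its printed percentages
(n = 53/89).  The 5×2 nodule-location row is served by a generic r×c
Pearson test and a Monte-Carlo Freeman-Halton option; no parity with
the published location statistic is claimed, since plain Pearson on the
printed counts does not reproduce it and the method used there is not
identifiable.

## Synthetic cohort generator

The generator is the package's study stand-in, not a fixture.  Each
case is a small CT volume (default 1 mm isotropic) containing one
nodule:

* **Geometry** — superellipsoid (exponent 1.8) with smooth shrink-only
  boundary perturbation.  The exponent stays below 2 so no direction
  bulges past the nominal radius and the caliper diameter respects the
  10 mm subcentimeter ceiling; the perturbation is shrink-only for the
  same reason.  Diameters are `10 − Y` with `Y` lognormal, the location
  solved numerically so the *truncated* (4–10 mm) medians equal the
  cohort's 8.0 mm (MIA) / 9.0 mm (IAC) with IQR-matched scale.
* **Intensities** — air-dominated parenchyma N(−850, 50²) clipped to
  [−1024, −500]; subsolid cores N(−450, 60²) (≈87% of cases, per the
  cohort margins) and solid cores N(−30, 40²); per-case lognormal
  jitter of the background and core noise scales (log-sd 0.20 / 0.25)
  representing scanner/patient variability; a 0.8-voxel Gaussian
  reconstruction PSF.
* **Class effects** — a smooth intratumoral heterogeneity field and a
  diffuse peritumoral densification field are present in *both*
  classes at base amplitudes (25 / 15 HU); invasiveness raises them in
  quadrature by `texture_effect` (default 60 HU) and
  0.8·`peritumoral_effect` (default 12 HU) for IAC only.  1–3
  vessel-like strands (radius 0.5 mm, HU ≈ −100 ± 25) cross the
  peritumoral shell in every case; IAC cases gain Poisson-distributed
  extra strands (rate `peritumoral_effect`/15, brighter by
  1.5·`peritumoral_effect`).  Keeping the base processes in both
  classes is essential: class-exclusive structure of any kind is a
  qualitative signature that a feature bank detects perfectly
  regardless of amplitude.
* **Covariates** — binary flags (VCS, vacuole, lobulation, …) drawn
  with the class-conditional prevalences of the cohort margins; an
  `exact_counts` mode reproduces the implied integer contingency
  tables.  Morphological flags are sampled, not rendered.
* **Determinism** — per-case seeds derive from the master seed via
  `SeedSequence([seed, case_index])`; identical spec + seed gives
  bit-identical cohorts.

The two effect amplitudes and the PSF width were fixed once so that the
default study conditions land the four models at the performance levels
characteristic of this clinical problem — CT-features AUC ≈ 0.72,
GTV ≈ 0.93 ≥ GPTV ≈ 0.89 ≥ GPR ≈ 0.80, the intratumoral effect
dominating the peritumoral one — and were not revisited afterwards.
`scripts/acceptance.py` recomputes these numbers on fresh cohorts.

**What the generator does not emulate:** scanner/kernel-specific noise
spectra, respiratory/motion artifacts, attached vessels and pleura,
non-lung anatomy within the margin, rendered lobulation/spiculation,
and any correlation between the morphological covariate flags and the
rendered image.  Passing tests therefore demonstrate that the pipeline
machinery is correct and that it recovers planted effects of realistic
size under realistic nuisance variability — not that the specific
published effect sizes generalize to real CT data.

## Problem sizes in the test suite

Simulation-backed tests use the cohort sizes the analysis targets
(142 cases) where the tested quantity depends on n (null coverage,
model-ordering sign tests), and smaller cohorts (20–60 cases) for
wiring and determinism checks.  Type-I-error checks use 500–1000
replicates; LASSO recovery uses 20 seeds at n = 142, p = 100.

## Known limitations

* Texture conventions follow the common radiomics definitions but are
  not certified IBSI-compliant output-for-output; the brute-force
  oracles pin down this package's own definitions instead.
* `run_study`'s headline AUCs inherit the single-cohort selection
  leakage of the design it mirrors (see the leakage note); use
  `nested_radscore_auc` for honest generalization estimates.
* The DICOM reader trusts GDCM's series sorting; multi-series
  directories are not disambiguated.
* No scanner harmonization (e.g. ComBat) is provided.
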