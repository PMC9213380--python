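# Methods

## The stability model

The pipeline treats a radiomics feature as a measurement instrument and
asks three questions per (dose, reconstruction) acquisition condition:

1. **Consistency** — does the feature characterize the *same* tissue
   class identically at different positions within one image? Rated by
   the intraclass correlation ICC(3,1) (two-way mixed, single score,
   consistency form) on a rating matrix with subjects = the three tissue
   classes and raters = the eight ROI positions within each class; the
   median over the repeated acquisitions is thresholded at ≥ 0.75.
   The subjects/raters orientation follows from treating the ROI
   position as the "rater" that re-measures each class; the consistency
   (not absolute-agreement) form deliberately ignores additive
   position offsets.
2. **Discriminative power** — does the feature separate the three
   classes? The Kruskal–Wallis omnibus rank test over 3 groups of 8 is
   run per repeat; the Bonferroni-adjusted p must fall below 0.05 in at
   least 95 % of repeats (19 of 20 in the full design). The
   multiplicity family is explicit configuration
   (`EvaluationThresholds.bonferroni_family`): the default adjusts for
   the number of features tested per cell (93), the most conservative
   reading; `"none"` disables adjustment.
3. **Repeatability** — does the feature reproduce across repeated
   acquisitions of the same object? Barnhart's overall concordance
   correlation coefficient (OCCC) with subjects = the 8 ROIs and
   raters = the repeats, computed per tissue class and averaged without
   weights, thresholded at ≥ 0.75.

A feature is **robust** in a cell iff all three criteria hold. Yield
summaries report, per cell, the fraction of the 93 features passing
each criterion, plus per-reconstruction medians/ranges over doses and
the Pearson correlation between dose and yield.

### Statistical conventions

* ICC(3,1) = (BMS − EMS)/(BMS + (k−1)·EMS) from the two-way ANOVA mean
  squares. CCC and OCCC use biased 1/n moment estimators (Barnhart's
  population form); mixing 1/n and 1/(n−1) estimators changes the
  values, so this choice is fixed and tested.
* OCCC = Σ_{j<l} 2s_jl / Σ_{j<l} [s_j² + s_l² + (μ_j − μ_l)²], a
  weighted mean of pairwise CCCs; for two raters it reduces exactly to
  Lin's CCC.
* Kruskal–Wallis uses mid-ranks and the tie-correction factor
  1 − Σ(t³−t)/(N³−N), with the χ² approximation (df = k−1) even at
  n = 8 per group, as standard software does; an exact permutation
  p-value is available as a validation flag. If every pooled value is
  tied the test is degenerate and returns p = 1 by convention.
* Undefined statistics (a feature constant everywhere has no subject
  variance) propagate as NaN and **fail** the criterion; they are never
  dropped. Undefined per-repeat ICCs enter the median as worst-possible
  values. The report carries `undefined_icc`/`undefined_occc` audit
  columns.
* The dose–yield correlation uses r with the two-sided t-test,
  t = r·√((n−2)/(1−r²)).

## The feature extractor

93 features: 18 first-order, 24 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM,
5 NGTDM; the name list is frozen in `feature_manifest.json` and the
extractor refuses to drift from it. Settings that matter:

* **Discretization**: fixed bin width 25 HU anchored at the ROI
  minimum, level = floor((x − min)/25) + 1, top value clamped into the
  last bin. Min-anchoring makes all texture families invariant to
  global HU shifts (tested).
* **Dimensionality**: texture is 3-D over the 4-slice ROI cylinders;
  GLCM/GLRLM use the 13 unique 3-D directions at distance 1, features
  computed per direction then averaged (not matrix-merged); GLSZM zones
  and GLDM/NGTDM neighbourhoods use 26-connectivity.
* **No preprocessing**: no resampling, filtering, resegmentation or HU
  clipping.
* **Degenerate-case guards** (all unit-tested): constant ROI →
  Skewness/Kurtosis 0, Entropy 0, Uniformity 1; single gray level →
  GLCM Correlation 0 (the "Correlation = 1 for flat regions" convention
  is intentionally not used, since a flat region carries no correlation
  signal), Imc1/Imc2 0, MCC 1; NGTDM Coarseness capped at 1e6;
  single-voxel ROI → no co-occurrence pairs, the degenerate one-level
  matrix is used so every feature stays finite.
* **GLDM dependence**: the matrix stores, per voxel, the number of
  neighbours within Chebyshev distance 1 whose level differs by ≤ α
  (default 0); the centre voxel is not counted, so a fully isolated
  voxel has dependence 0. Feature formulas weight dependence d as
  j = d + 1 — equivalent to counting the centre voxel as self-dependent
  — which keeps the small-dependence emphases finite.

Every texture matrix implementation is checked against brute-force
enumeration oracles (exhaustive pair counting, line walking, flood
fill, explicit neighbour loops) on randomized small ROIs in the test
suite; the statistics are checked against explicit sum-of-squares /
direct-formula oracles and against pingouin/scipy.

## The synthetic phantom

The generator emulates the statistical structure a stability analysis
needs, not CT physics:

* **Geometry**: one 128×128 template slice — concentric discs of
  metastatic core (radius 20 vox), rim annulus (20–32) and liver
  (32–58) — replicated into 4 identical slices (the phantom this
  mimics is printed from repeated copies of one template image, so
  slices are independent noise samples of one pattern). 24 fixed
  cylindrical ROIs (9-voxel diameter × 4 slices), 8 per class on
  concentric rings, verified non-overlapping and inside their class;
  too-small volumes raise a sizing error naming the violated
  constraint.
* **Tissue classes** (defaults, configurable): liver 100 HU, core
  40 HU, rim 70 HU; frozen band-limited Gaussian texture fields with
  amplitudes 10/6/12 HU and correlation lengths 2/1/2 voxels. The
  30 HU class contrast against σ(1 mGy) = 25 HU noise makes classes
  cleanly separable at high dose and confusable at 0.2 mGy, the
  degradation regime of interest.
* **Noise**: stationary zero-mean Gaussian, white noise smoothed
  in-plane (kernel σ = 0.6 vox) and renormalized to exactly
  σ(D) = σ_ref·√(D_ref/D) with σ_ref = 25 HU at D_ref = 1 mGy — the
  quantum-noise scaling law; the measured log-log SD-vs-dose slope is
  −0.5 by construction. The 18-dose ladder spans 0.2–4 mGy. Each
  (dose, repeat) noise realization is fed to *all* reconstruction
  emulators, mirroring reconstruction of the same raw data four ways.
* **Reconstruction emulators**: FBP = identity (noisy,
  texture-faithful); HIR = Gaussian smoothing (σ = 0.8, moderate
  denoising); MBIR = two 3×3 in-plane median passes (strong denoising
  that alters the noise correlation structure); DLR = convex blend
  0.9·(prior + smoothed residual) + 0.1·noisy anchored on the frozen
  ground-truth texture (strong denoising that preserves the clean
  texture spectrum — the qualitative behaviour reported for
  deep-learning reconstruction). Measured flat-region noise SDs at
  1 mGy order FBP (25) > HIR (15) > MBIR (13) > DLR (10) HU.
* **Seeding**: per-acquisition seeds derive from
  SeedSequence(master_seed, spawn_key=(dose index, repeat index)), so
  the full 1440-cell dataset is bit-reproducible from one integer.

### What the generator does *not* emulate

Sinogram physics (beam hardening, scatter, helical geometry,
nonstationary noise), vendor algorithms, anatomical variation between
slices, and the absolute HU/texture spectra of real tissue. Passing
tests therefore demonstrate that the *analysis machinery* recovers
known structure under a controlled image-domain noise model — they do
not certify any particular feature as robust on scanner data, and the
real-data mode (NIfTI/DICOM readers + manifest) exists precisely so
the same pipeline can be pointed at actual acquisitions.

## Problem sizes and numerical choices

The default design (18 doses × 20 repeats × 4 modes = 1440 volumes) is
the scientific reference configuration; tests and the acceptance script
use reduced designs (e.g. 5 doses × 8 repeats × 2 modes, or the
`--small` 4×5×4 design) chosen to exercise every code path with stable
statistics at desk scale. Calibration checks use 10⁴ null simulations
for the Kruskal–Wallis type-I error and 500–1000 simulated cells for
the ≥ 95 %-of-repeats rule. Medians over an even number of repeats use
the midpoint convention. The "robust above 1 mGy" roll-up means
strictly > 1 mGy.

## Known limitations

* The DLR emulator is given the ground-truth texture prior — an
  idealization of a denoiser trained to know clean anatomy; it bounds
  the real algorithm's behaviour from above.
* FBP repeatability in this model improves monotonically with dose;
  correlated ("repetitive") scanner noise that inflates low-dose FBP
  repeatability on real phantoms is not modelled.
* The χ² approximation for Kruskal–Wallis at n = 24 is slightly
  conservative (measured null rejection ≈ 0.044 at nominal 0.05).
* Confidence intervals for ICC/OCCC and for yield fractions are not
  computed; criteria threshold point estimates only.
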