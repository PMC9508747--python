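# Methods

`mtspread` implements a connectome-based analysis of how myelin relates
to the regional burden and inter-regional spreading of fibrillar tau,
measured with tau-PET. This note documents the model, the estimators,
the synthetic-study generator, the numerical choices, and the known
limitations.

## The analysis

### Tau-PET scores

The tau tracer binds off-target, so a raw SUVR mixes background signal
with on-target fibrillar-tau signal. Pooling a cohort's baseline SUVRs
per ROI yields an approximately bimodal distribution: a two-component
univariate Gaussian mixture is fit per ROI (EM, k-means initialization,
tolerance 1e-6, at most 500 iterations, 5 restarts keeping the best
likelihood; the scikit-learn implementation). The component with the
larger mean is labeled on-target. The *tau-positivity probability* of an
observation x is the posterior

    P(on | x) = w_on φ(x; μ_on, σ_on) / [w_on φ(x; μ_on, σ_on) + w_off φ(x; μ_off, σ_off)]

computed in log space, and the *tau-PET score* is `P(on | x) · x`.
Mixtures are fit on baseline SUVRs pooled across all groups of a cohort;
follow-up scans are scored with the baseline-fitted parameters so
longitudinal change in scores is not confounded by refitting. A fit is
flagged *degenerate* when the component means are closer than half the
larger sigma or either weight is below 0.01; degenerate ROIs score 0.5
(an explicit uninformative fallback) and are flagged, never silently
dropped.

Status screening uses strict published cut-offs: global amyloid SUVR
> 1.11 (florbetapir), > 1.08 (florbetaben), > 0.575 (flutemetamol) for
amyloid positivity, and an unweighted temporal meta-ROI mean (amygdala,
entorhinal, fusiform, parahippocampal, inferior temporal, middle
temporal) < 1.29 for tau negativity. Boundary values equal to a cut-off
classify by the strict inequality exactly as printed. The meta-ROI mean
is unweighted because region volumes are unavailable at the table level.

### Spatial myelin-tau association

Cortical myelin is summarized per ROI as the parcel mean of a myelin
water fraction (MWF) volume, optionally restricted to voxels with
gray-matter probability >= 0.3. The spatial association is the Spearman
rank correlation across ROIs between cortical MWF and the group-average
tau score (mean over the chosen subjects per ROI). p-values use the
t approximation for N > 10 ROIs and a permutation distribution
(exhaustive up to N = 8, else 1e5 sampled permutations) below that.
Sensitivity variants: the same correlation on raw SUVRs, and a partial
Spearman (Pearson on rank residuals, df = N - 3) controlling for
ROI-level group-average amyloid SUVR. A stratified bootstrap (default
B = 1000) resamples subjects with replacement within strata (e.g. APOE
e4 carriers vs non-carriers) and reports percentile 95% CIs of the rho
distribution per stratum; CI overlap across strata is reported as the
decision flag for "no significant stratum difference". The resampling
stream is seeded identically in each stratum so identical strata yield
identical CIs; percentile (not BCa) intervals are used.

### Covariance in tau change

Annual change is `(followup - baseline) / interval` per subject and ROI
(two-timepoint annualized difference; intervals in years). The
*covariance in tau change* between two ROIs is the Spearman correlation
of their change values across subjects (average ranks for ties), clipped
to |rho| <= 1 - 1e-7, Fisher-z transformed, with the diagonal
(autocorrelations) set to zero. Subjects missing any ROI are dropped
listwise so every edge is estimated on the same n. The covariate-
adjusted variant residualizes the ranked change vectors on a control
design (intercept + rank-transformed numeric covariates + indicator-
coded categorical covariates, reference level dropped) and correlates
the residuals — the standard all-ranks partial-Spearman construction;
the closed-form recursion is used only as a test oracle. An ROI whose
ranks are fully explained by the controls gets partial correlations of
exactly zero; an ROI with constant change gets missing edges plus a
warning.

### Fiber-tract myelin and functional connectivity

Fiber-tract MWF per ROI pair is the mean over that pair's streamlines of
the mean MWF along each streamline: polylines are resampled at a fixed
0.5-voxel arc-length step with nearest-voxel lookup (trilinear
interpolation was rejected to keep the hand-computable oracle exact and
to match common tract-profiling defaults); out-of-bounds samples clamp
to the nearest in-bounds voxel. Edges without streamlines are missing
and stay missing in the analysis (imputation exists only inside the
generator). Functional connectivity is the Fisher-z Pearson correlation
between ROI time series for all pairs, diagonal zero; group templates
are missing-aware elementwise means of per-subject matrices. Perfect
correlations are clipped at 1 - 1e-7 before atanh so they stay finite.

### The edge-wise interaction model

The hypothesis is that the association between functional connectivity
and covariance in tau change is attenuated where the connecting fiber
tracts are more myelinated. All matrices are vectorized on the common
edge set: upper-triangle pairs with a structural connection (streamline
count > 0) and no missing value in any input — the only set on which
"MWF in fiber tracts" is defined. Outcome (covariance in change), FC,
and fiber MWF are z-standardized; the interaction regressor is the
product of the standardized main effects (not re-standardized); OLS with
intercept (optionally plus a standardized control matrix such as the
covariance in amyloid change) yields standardized coefficients with
classical SEs and two-sided t p-values. Negative FC edges are retained
unthresholded. Classical OLS is used although edges are not independent
(they share ROIs and subjects), matching the field's convention; an
edge-label permutation p-value is available (`n_permutations > 0`) but
is off by default. Designs with condition number above 1e8, zero-
variance columns, or fewer than 30 usable edges are rejected.

## The synthetic-study generator

The generator produces every input from a single master seed
(`SeedSequence`-derived stage seeds; reruns are bit-identical):

* **Atlas** — Voronoi parcels over an ellipsoidal shell (farthest-point
  sampled centers, balanced sizes). The first six ROIs carry the
  temporal meta-ROI names so status screening runs end-to-end.
* **MWF** — per-ROI means uniform in [0.05, 0.25] (typical cortical MWF)
  plus smoothed voxel noise (sd 0.01); the cortical MWF vector is
  recomputed from the volume so the pair is consistent by construction.
* **Connectome** — FC from a latent-factor time-series model (edge-level
  Fisher-z spread ~0.25, in the range of group-average resting-state
  templates); structural counts on ~50% of pairs (1 + Poisson(9));
  fiber MWF defined exactly on structural edges and coupled at strength
  0.7 to the mean endpoint cortical MWF. At desk scale the fiber-MWF
  matrix is instead sampled along generated streamlines (straight
  jittered polylines — enough geometry to exercise the sampling code,
  deliberately not curved tracts) through the MWF volume.
* **Cohort** — four groups (CN Ab-/Tau-, CN Ab+, MCI Ab+, AD dementia);
  age ~ Normal(group mean 71-76, 7) truncated to [55, 95], education ~
  Normal(14, 3) truncated to [6, 22], APOE e4 carrier rates rising with
  stage (0.27/0.53/0.65/0.64), three sites. Defaults: 40 ROIs and 120
  subjects (desk scale; the suite and default pipeline finish in
  seconds); 200 ROIs via config.
* **Baseline tau SUVR** — per subject and ROI a draw from the
  off-target N(1.15, 0.10²) or on-target N(1.80, 0.30²) component.
  Amyloid-negative subjects draw only off-target. For amyloid-positive
  subjects the per-ROI on-target probability lies in [0.10, 0.50] and is
  a monotone function of a latent that blends negated MWF ranks with
  seeded noise; the blend weight is solved by bisection so the sample
  Spearman between MWF and the probability vector equals the planted
  value (default -0.30) to ~1e-4. Planting the rank correlation exactly
  per realization (rather than only in expectation) makes subject
  sampling the only noise between the planted value and pipeline
  estimates, which is what recovery and coverage checks assume. The
  per-ROI SUVR distribution parameters are plausible defaults, exposed
  in config, not calibrated to any cohort.
* **Longitudinal change** — the planted change-correlation matrix is
  built from edge values z = a + b·FC + c·FC·MWF* (MWF* standardized,
  missing edges median-imputed for generation only), mapped through
  tanh, unit diagonal imposed, and repaired to the nearest PSD
  correlation by eigenvalue clipping at 1e-6 with diagonal
  renormalization (simple and deterministic; alternating projections
  rejected as needless complexity). Defaults (a, b, c) = (0.1, 0.5,
  -0.4): c < 0 plants the attenuation of connectivity-dependent spread
  by fiber myelin. Amyloid-positive subjects draw annual change from a
  multivariate normal with that correlation (mean 0.02, sd 0.05 SUVR/y);
  controls use 0.1·target + 0.9·I so control-group analyses are
  near-null by construction; follow-up = baseline + change × interval,
  intervals uniform in [0.7, 4.0] years. Note the follow-up value is
  noiseless given the drawn change, so the covariance estimator's only
  noise is subject sampling.
* **Amyloid tables** (plumbing) — global SUVRs placed on the correct
  side of the florbetapir cut-off per group, regional values = global +
  noise, follow-up with independent small change; these exist so the
  classification and amyloid-controlled sensitivity stages run, and
  plant no amyloid-tau structure.

What the generator does **not** emulate: scanner noise, partial-volume
effects, spatial autocorrelation of tau beyond what connectivity
induces, anatomically curved tractography, or amyloid-tau coupling.
Passing recovery tests therefore demonstrates the estimators read back
what these generators plant — not that the method is unbiased on real
cohort data.

## Study conditions used by the built-in experiments

(`mtspread.experiments`; sizes chosen as the package's standard
evaluation scale)

* mixture recovery: 6 ROIs × 400 subjects, π_on = 0.3;
* spatial recovery: 200 ROIs, 100 amyloid-positive subjects, 20 seeds;
* interaction recovery: 60 ROIs, 150 longitudinal amyloid-positive
  subjects, 20 seeds, reference effect fit on the noiseless planted
  matrix;
* null calibration: 40 ROIs, 200 replicates, outcome = constant +
  iid symmetric edge noise at sd sqrt(1.06/(n-3)), n = 150 — the
  Fisher-z Spearman noise scale;
* bootstrap coverage: 200 ROIs, two strata of 100 subjects, B = 500,
  50 simulations, subject noise sd 0.4 (the order of between-subject
  tau-score spread), rho = -0.30 planted exactly on the ROI mean
  vector;
* control-group null: desk-scale default studies, 20 seeds.

## Observed behavior worth knowing about

* **Score-transform attenuation.** The positivity-weighted score is a
  per-subject nonlinear shrinkage of the SUVR; Spearman covariance
  matrices computed from score changes are attenuated relative to the
  planted correlation (measured shrink factor ≈ 0.75 at 150 subjects),
  so the standardized interaction coefficient lands ~0.17 below the
  noiseless reference (~0.07 when raw SUVR changes are analyzed — the
  package's SUVR sensitivity branch). The sign and significance of the
  planted effect are recovered in 20/20 seeded runs either way.
* **Percentile-bootstrap bias.** Bootstrapping a rank correlation of
  noisy ROI means centers the CI on a slightly attenuated estimate; at
  two strata of n = 100 the measured per-stratum CI coverage of the
  planted rho is ≈ 0.86-0.90, not the nominal 0.95.
* **Controls are not an exact null.** By design the control group's
  change correlation is 0.1·target + 0.9·I, and the cohort-fit score
  curves leak a faint MWF gradient into control score means; with 40
  controls the interaction test fires in ~10-20% of seeded studies
  (almost always with the planted negative sign) and the spatial test
  in ~10%. Joint non-significance lands near, not reliably above,
  18/20 seeds.

## Limitations

* Classical OLS p-values on dependent edges are anti-conservative to a
  degree that grows as the subject count shrinks; the permutation
  option exists for sensitivity checks.
* No spatial-autocorrelation-preserving null models (spin tests) are
  implemented.
* No mediation or causal modeling of myelin, amyloid, and tau; the
  amyloid branch is a covariate-control sensitivity analysis only.
* Streamlines are consumed, not reconstructed; registration,
  segmentation, and fMRI preprocessing are out of scope — inputs are
  assumed to be clean ROI-level tables and volumes in a shared space.
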