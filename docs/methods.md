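# Methods

## Problem setting

Thoracic radiotherapy plans are constrained by lung DVH metrics: V5 and V20
(the percent of normal-lung volume receiving ≥ 5 / ≥ 20 Gy) and the mean lung
dose (MLD, Gy). "Normal lung" is ambiguous: the total bilateral lungs, the
lungs minus the planning gross tumor volume (PGTV = GTV + 5 mm setup margin),
or the lungs minus the planning target volume (PTV = CTV + 5 mm, where CTV is
the GTV plus a 6–8 mm microscopic-spread margin). Since the target region is
the hottest part of the plan, each successive exclusion removes the hottest
lung voxels, so for any plan in which the target dominates the dose
distribution the metrics order as

    Lung−PTV ≤ Lung−PGTV ≤ Total Lung   (for V5, V20 and MLD alike).

This package quantifies that offset and asks which definition's metrics best
predict symptomatic (grade ≥ 2) radiation pneumonitis, RP2.

## Geometry

Masks are boolean voxel arrays on a regular grid; membership is by voxel
center with no partial-volume weighting, so volumes are voxel counts times the
voxel volume and the error is bounded by the voxel size. Margin expansion is
the exact Euclidean dilation in physical units (`scipy.ndimage`
distance transform with per-axis sampling), which handles anisotropic spacing
and is verified in the tests against a brute-force per-voxel nearest-distance
oracle. Dilations are clipped at the grid boundary with a logged warning.
Normal-lung construction follows the overlap rule: `lungs AND NOT target`,
so extrapulmonary target voxels never remove lung volume. No cropping of the
PTV at anatomical boundaries is applied. Exclusion of great vessels and
trachea from the lung contour is treated as a property of the input lung mask
(the phantom simply never includes them), not as a runtime carving step.

## DVH metrics

V5, V20 and MLD are computed directly from the voxel multiset (inclusive ≥
threshold; arithmetic mean), not from the binned histogram, so they carry no
discretization error. The cumulative DVH (default bin width 0.1 Gy, finer
than any reported precision of these metrics) is produced for export and
plotting only.

## Synthetic thorax phantom

Two ellipsoidal lungs, a spherical GTV inside one lung, CTV = GTV ⊕ 6 mm,
PTV = CTV ⊕ 5 mm, PGTV = GTV ⊕ 5 mm. Dose equals the prescription (default
60 Gy, valid range 50–70 Gy) on every PTV voxel and decays as
`exp(−d/falloff)` with distance `d` outside (default falloff 9 mm, a
deliberately generic penumbra-plus-spill scale). Optional multiplicative
noise in (1 − ε, 1] is applied outside the PTV only, so it can never violate
target dominance; the ordering invariant above therefore holds by
construction for every valid configuration, and the uniform-dose limit
(falloff → ∞) collapses all three definitions to identical metrics. The
phantom emulates the geometry and monotone falloff of a planned dose
distribution; it does not emulate CT appearance, respiratory motion,
heterogeneity corrections or beam-specific dose shapes, so passing phantom
tests demonstrates correctness of the geometry/DVH pipeline, not realism of
any clinical plan.

## Synthetic cohort

The cohort generator reproduces the study conditions under which the analysis
is meant to operate: 183 patients with roughly 14% RP2 incidence.

- **Lung−PTV MLD**: lognormal with median 10.3 Gy and log-SD 0.20, truncated
  to [6, 16] Gy — positive, right-skewed, matching the observed median and
  range of that definition.
- **Offsets**: MLD(Lung−PGTV) = MLD(Lung−PTV) + 1.7 Gy and MLD(Total) adds a
  further 0.6 Gy (total +2.3 Gy), with per-patient jitter (SD 0.7 / 0.35 Gy,
  back-solved from the reported confidence-interval widths at n = 183). The
  jitter is truncated *symmetrically* at ± the mean increment, which keeps
  every increment strictly positive without biasing the mean — plain one-sided
  truncation would inflate it.
- **V5/V20**: monotone noisy transforms of MLD. V20 = 1.75·MLD + noise;
  V5 = V20 + 2.85·MLD·exp(noise), which makes V20 ≤ V5 structural rather than
  enforced after the fact. Across definitions V5 adds 2.2 then 0.6 points and
  V20 adds 3.5 then 1.0 points on average, with the same symmetric-truncation
  scheme. No joint distribution of (V5, V20, MLD) is reported anywhere, so
  this monotone-transform model is an explicit modelling choice.
- **Outcome**: RP2 ~ Bernoulli(Φ((MLD − TD50)/(m·TD50))) with TD50 = 17.5 Gy,
  m = 0.34, driven by the **Lung−PTV** MLD by default (configurable to any
  definition for misspecification studies). Because the generating model is
  exactly the model the `ntcp` module fits, parameter recovery is well-posed
  and is tested in closed loop.
- **Covariates** (age, sex, smoking, histology, stage, chemotherapy, surgery,
  target volumes, prescriptions) are drawn from typical lung-cancer IMRT
  cohort marginals and are independent of outcome by default, mirroring a
  cohort in which no clinical factor reached significance; log-odds effects
  can be injected for power studies.
- **Seeding**: one integer seeds a `numpy` `SeedSequence`, which is spawned
  into four named child streams (MLD, V-metrics, covariates, outcome), so the
  generator is bit-reproducible and streams are independent.

What the simulator does *not* capture: between-metric correlation structure
beyond the shared MLD driver, censoring/follow-up loss, planning-system
differences, and any real spatial dose information — cohort records are
tabular. Tests that pass on this generator validate the statistical machinery
under its assumed dose-response; they cannot validate the clinical claim on
real patients.

## Statistics

- **2×2 odds ratios**: OR = ad/bc with Wald CI `exp(ln OR ± 1.96·SE)`,
  SE = √(1/a+1/b+1/c+1/d), and Wald p. Wald (not profile-likelihood)
  inference is used deliberately: it exactly reproduces the published
  covariate rows from their counts (e.g. 6/15 vs 20/142 → OR 2.84,
  CI 0.99–8.17, p 0.053), identifying it as the convention behind them. A
  zero cell yields the degenerate point estimate (0 or ∞) with an explicit
  non-estimable flag instead of a silent number.
- **Univariate logistic regression**: Newton ML via statsmodels with Wald
  CI/p; on a binary covariate it equals the 2×2 closed form to machine
  precision (tested). Complete separation and constant covariates are
  flagged, never silently estimated. Median dichotomizations use ≤ median vs
  > median.
- **Mann-Whitney U**: exact enumeration of all label assignments (with
  midranks, so ties are handled) when the combined n ≤ 10; otherwise the
  normal approximation with tie and continuity corrections. The threshold of
  10 keeps enumeration ≤ 252 arrangements.
- **Paired differences**: mean with t-based 95% CI, reported
  larger-definition-minus-smaller; zero-variance inputs return a degenerate
  flag.
- **Repeated-measures ANOVA**: one-way within-subject decomposition,
  F = MS_condition/MS_error on (k−1, (k−1)(n−1)) df, computed directly so
  degenerate inputs (zero error variance, identical columns) can be flagged;
  cross-checked against pingouin in the tests. No sphericity correction is
  applied (with k = 3 nearly-parallel dose columns the correction is
  immaterial for the reported use).
- No multiple-testing correction is applied anywhere, matching the analysis
  this package mirrors.

## ROC and DeLong

AUC is the Mann-Whitney concordance (ties get half credit); curves come from
`sklearn.metrics.roc_curve`. DeLong's variance/covariance uses midrank
placement values, the standard fast formulation, so tied scores (dose metrics
rounded to 0.1) are consistent between the AUC and its variance. Zero
variance with zero difference (one score a monotone transform of the other)
returns p = 1; zero variance with a nonzero difference is flagged degenerate.
All p-values are two-sided. The implementation is verified against an
independent reference (R pROC `roc.test`) on a frozen fixture and against a
bootstrap variance. AUC confidence intervals are available via the DeLong
variance but are a convenience, not a headline output. Optimal-threshold
selection (Youden) is out of scope: clinical cutoffs here come from the NTCP
model, not the ROC curve.

## Lyman NTCP fitting

With n = 1 the Lyman volume reduction makes the effective dose the MLD, so the
model is a two-parameter probit in MLD; Φ is evaluated by the erf-based normal
CDF, not quadrature. The Bernoulli log-likelihood is maximized over a
deterministic coarse grid (TD50 ∈ [5, 60] Gy step 1; m ∈ [0.05, 2] step 0.05)
followed by Nelder-Mead refinement from the best cell — no stochastic
restarts, so fits are bit-reproducible; a refined optimum can only improve on
its grid start (enforced), and optima at the box edge are flagged
`at_boundary`. Probabilities are clipped to [1e−12, 1−1e−12] before logs so
extreme proposals cannot produce −∞/NaN. All-event or no-event outcomes are
rejected as non-identifiable. The equivalence slope = 1/(m·TD50),
intercept = −1/m against a generic probit regression is tested.

Cohort MLDs (6–16 Gy) sit well below TD50 (~17.5 Gy), so the likelihood is
informative mainly about the low-dose tail: recovery tolerances are wide
(±2 Gy on TD50, ±0.08 on m at n = 5000) and single-cohort (n = 183) fits
scatter more — the iso-risk *cutoff*, which lives inside the observed dose
range, is recovered much more tightly than the parameters themselves.

The "probability difference between definitions" is implemented as the
relative difference with respect to the smaller probability,
100·(p_high − p_low)/p_low rounded to integer percent, since that convention
reproduces the quoted 54% (0.13 vs 0.20) and 45% (0.20 vs 0.29) figures.
Whether the per-definition curves should share parameters is an open
modelling question; independent fits per definition are used.

## Pipeline

`run_analysis` validates the cohort schema (violations enumerated with row and
column), then emits the covariate OR table, the paired-difference table with
the within-subject ANOVA, the RP2 vs non-RP2 descriptive table with
Mann-Whitney p, the univariate dosimetric OR table, the AUC/DeLong comparison
table, and the per-definition Lyman fits with cutoffs at the target risk
(default 20%) plus dose-response curves. Outputs contain no timestamps and
all fits are deterministic, so reruns are byte-identical. Single-class
outcomes downgrade the report to descriptives with an explicit notice; very
few events trigger an instability notice rather than a failure. The run log
records every operation with its inputs so any reported number can be
recomputed by one library call.

## Problem sizes used in the test suite

Oracle-equality checks run on 32³–64³ grids; null-calibration simulations use
2000 replicates (Mann-Whitney, DeLong) and 1000 (ANOVA); parameter recovery
uses cohorts of 500 and 5000; CI-coverage uses 100 seeded replicates of the
183-patient cohort. These sizes give Monte-Carlo error small enough for
3-sigma acceptance bands while keeping the default suite fast.

## Known limitations

- DICOM-RT import/export and treatment-planning dose algorithms are explicitly
  unsupported; structures are exchanged as flat binary arrays with a JSON
  sidecar.
- The cohort-level published results that depend on private patient data
  (specific AUCs, table medians, the DeLong p on that cohort) are not
  reproducible from counts and are therefore demonstrated on synthetic
  cohorts, not asserted.
- Only univariate association models are provided; multivariable adjustment,
  survival endpoints and missing-data handling beyond row exclusion are out of
  scope.
- Lyman parameter uncertainty (profile likelihood / bootstrap CIs on TD50, m)
  is not part of the reported surface.
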