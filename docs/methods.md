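# Methods

This note documents the modeling choices, conventions and limitations of the
`ictos` package. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted from memory.

## Scope and design

The package rebuilds a complete radiomic treatment-benefit workflow for
nasopharyngeal carcinoma at desk scale: synthetic image/cohort generation,
preprocessing, 2D feature extraction, reliability screening, propensity
weighting, interaction modeling and survival evaluation. Patient images and
follow-up are replaced by a generator with known ground truth; consequently
cohort-specific published quantities (hazard ratios, survival percentages,
the exact number of features surviving the reliability screen) are not
reproduction targets — the printed design values and worked examples are,
and the statistical machinery is validated against closed forms, brute-force
oracles and planted-truth simulations.

## Feature catalogue

Per ROI: 19 first-order intensity features, 10 in-plane shape features, 24
gray-level co-occurrence (GLCM) features at 8 offsets (4 directions x 2
distances, reported per offset, never averaged) and 13 run-length (GLRLM)
features at 4 directions — 273 values; three sequences give 819 per patient.
The 19/10/24x8/13x4 breakdown is this package's reconstruction chosen to
meet the 273/819 totals with standard formula families; it is declared in
`features/catalogue.py` and exportable as YAML so it can be swapped. The
GLCM list omits dissimilarity (identically equal to difference average) in
favour of sum variance, so all 24 values are distinct quantities.

Conventions worth knowing:

* Texture matrices are accumulated per axial slice inside the ROI, summed
  over slices, then normalized once (GLCM additionally symmetrized). All
  computation is 2D.
* GLCM joint variance — the published model's `GLCM_variance` — is
  sum_ij P(i,j) (i - mu)^2 with mu = sum_ij P(i,j) i on gray levels 1..32.
* GLRLM long-run high-gray-level emphasis (`GLRLM_LRHGLE`) is
  sum R(i,l) i^2 l^2 / sum R(i,l).
* First-order moments use population (1/n) denominators; skewness is the
  Fisher moment skewness, defined as 0 on a zero-variance ROI.
* Shape is measured on the maximum-area slice (areas in mm^2 via in-plane
  spacing).
* Degenerate inputs are flagged, not fatal: a constant ROI discretizes to
  bin 1, a pair-free GLCM offset returns a zero matrix with dispersion
  features 0 by convention. A run-free GLRLM is an error (an ROI always has
  runs).

## Preprocessing

Bilinear in-plane resampling to 1.0 mm (pixel-center alignment; masks
nearest-neighbor; slice count unchanged), whole-volume z-scoring over
in-body (nonzero) voxels, and fixed-bin-count discretization (32 bins over
the ROI min–max). These defaults are explicit stand-ins for an unavailable
acquisition-specific recipe and are configurable (`PreprocessConfig`).
Normalizing over the whole body rather than the ROI preserves first-order
contrasts; z-scoring before fixed-bin-count discretization makes every
downstream feature invariant to affine intensity rescaling (a property
test).

## Synthetic data

**Phantoms.** Three co-registered stacks with an elliptical body and a
cylindrical tumor ROI. Three monotone knobs target the three published model
features: a skew-normal noise component plus a tilt in the sign balance of
extreme-intensity "anchor" patches (histogram skewness); anchor-patch
coverage fraction at fixed ±5 amplitude (GLCM joint variance — coverage, not
amplitude, so the min–max bin grid stays stable); and noise-free constant
plateaus along the row direction whose length and amplitude grow together
(LRHGLE). Noise tails are clipped at 2.5 SD so single outliers do not set
the bin grid. Texture is attenuated on T1 (0.4) and T2 (0.7) relative to
contrast-enhanced T1, where the published model lives. Monotonicity holds in
expectation and is tested by Monte-Carlo group ordering; the knobs are
correlated in their feature read-outs (as real radiomic features are), so
feature-level loadings on the latent axes are ~0.5–0.8, not 1.

**Cohorts.** Each patient carries latent axes z ~ N(0,1)^3 driving both the
phantom knobs and the treatment effect. The ICT-vs-CCRT log hazard ratio is
delta(z) = -0.66 + 0.668 z_skew + 0.442 z_hetero - 0.410 z_run: coefficient
magnitudes echo the published model, and the base effect is set so the
benefit subgroup approaches the HR ~ 0.25 design scenario while the
whole-cohort HR stays in the 0.5–0.8 range. Event times are exponential with
the control-arm baseline calibrated to a 65% 5-year failure-free fraction
(time unit months; event = composite failure-free-survival endpoint).
Clinical covariates (age, sex, stage, nodal necrosis, tumor volume, pEBV
DNA) carry modest prognostic log-hazard effects (0.25–0.30 per high-risk
factor) and, in the observational scenario, drive arm assignment through a
logistic model with slope `confounding_strength`. Censoring: a
`censor_rate` fraction is censored uniformly before its event time (so
censor_rate = 1 yields a fully censored cohort exactly), plus
administrative censoring at 84 months (~7 years, consistent with a ~70-month
median follow-up). Default cohort size 250 per cohort, matching the study's
scale.

**What the generator does not emulate** — MR physics (bias fields, k-space,
partial volume), anatomy, registration error, scanner heterogeneity, and
non-proportional hazards. Passing tests therefore demonstrate correctness of
the *procedure* and recoverability of a planted interaction under idealized
imaging, not clinical performance on real images.

**Desk-scale consequence.** Phantom ROIs are ~1000 voxels, so a 1-voxel
segmentation jitter is proportionally harsher than re-contouring a real
tumor; with the default 15-subject reliability set, roughly half to
three-quarters of features survive the double ICC ≥ 0.8 rule (seed
dependent), below the ~84% reported on real data. Both observers are
emulated with 1-voxel jitter for this reason.

## Statistical components

* **ICC**: two-way random effects, absolute agreement, single measurement —
  ICC(2,1) from the ANOVA decomposition, vectorized across features; the
  citation-level variant is not recoverable from the study text, so the form
  is declared and configurable. The retention rule is inclusive (≥ 0.8),
  resolving the text's mixed "> 0.8"/"≥ 0.8". Cross-checked against
  `pingouin` in the tests.
* **Propensity/IPTW**: logistic regression (statsmodels) of arm on the seven
  pre-specified covariates; stage variables as dummy indicators, pEBV DNA as
  the ≥ 2000 copies/ml split used throughout. Stabilized ATE weights with
  1st/99th-percentile score truncation (both declared defaults, not sourced
  from the study, and configurable). Balance is summarized as standardized
  mean differences, |mu1 - mu0| / sqrt((s1^2 + s0^2)/2), with the proportion
  analogue for binaries.
* **Interaction screen**: one weighted Cox fit per feature with treatment,
  feature and product terms; ranked by the Wald p of the product.
  Non-convergent fits get p = 1 and are logged. Whether the original
  screening was weighted is unstated; weighted is the default
  (`screen_weighted=False` to disable).
* **Modified-covariate fit**: Cox on W = x(2T-1)/2 only, IPTW weights as
  case weights (the composition of weighting with the working model is a
  declared choice), Efron ties, lifelines optimizer. Backward selection
  drops the largest Wald p until all p < 0.05, breaking ties toward the
  later-ranked feature (deterministic). The candidate set entering the
  multivariable stage is capped at 10 (configurable `max_candidates`; the
  original cap is unprinted).
* **Score orientation**: ICTOS = -gamma^T x, deterministically, so positive
  scores mean lower predicted hazard under induction chemotherapy; the 0
  cutoff is the predicted-equality point, labels are high (> 0) / low (≤ 0).
* **Survival**: weighted Kaplan–Meier via lifelines with Greenwood variance
  and log(-log) confidence bands (plain-Greenwood not exposed; the transform
  is the declared choice). Read-offs at exactly 36/60 months take the step
  function's current value. The weighted log-rank is the Cox score test
  computed in closed form from weighted risk sets (equals the classic
  log-rank at unit weights without ties). Power uses the event-driven normal
  approximation power = Phi(sqrt(D p (1-p)) |ln HR| - z_{1-alpha/2}).
* **Required cohort size** rounds subgroup_n / prevalence to the nearest
  integer (matching the printed 110/0.47 -> 234; a ceiling would give 235
  because the printed 47% is itself rounded).
* **Risk stratification** counts four binary factors (N2–3, T4, volume ≥ 34
  ml, pEBV DNA ≥ 2000 copies/ml); "more than two" is read literally as
  count ≥ 3 by default but the threshold is a parameter, because ≥ 2 is a
  defensible alternative reading.

## Numerical conventions

Cox convergence follows lifelines defaults; screening failures degrade to
p = 1 rather than aborting. GLCM information-measure features guard zero
entropies; correlation of a dispersion-free matrix is 0 by convention.
Z-score standardization uses the population denominator, recorded in the
parameters and reused verbatim on validation data. All generators are
`numpy.random.default_rng` streams seeded from user-supplied integers; equal
seeds give bit-identical outputs, and the workflow writes a provenance
record (seed, config hash, package version) sufficient to re-execute a run.

## End-to-end expectations

On the default planted-benefit study (250 training patients with
confounding 0.8, 250 randomized validation patients), the pipeline selects a
small model whose features correlate with the true benefit axes, the fitted
score correlates positively with the true per-patient benefit, and the
high-ICTOS group's treatment hazard ratio is below the low group's. Because
feature read-outs of the latent axes are strongly inter-correlated, the
*names* selected vary with the seed among near-equivalent proxies — the
planted signal, not a fixed name list, is the recovery target. The
treatment-interaction p-value on the validation cohort is typically not
significant at this scale; detecting it reliably needs either larger cohorts
or stronger feature loadings than the desk-scale phantoms provide.

## Limitations

2D features only (no 3D, wavelet or filtered families); no bias-field
correction or inter-sequence registration (inputs assumed co-registered); no
competing risks; no doubly-robust or efficiency-augmented variants of the
modified-covariate estimator; confidence intervals for ICC are not
computed. The propensity model is main-effects only. Secondary endpoints
need no bespoke code — every evaluator runs on any (time, event) pair.
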