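# ictos

An MRI radiomic treatment-benefit biomarker pipeline for locoregionally
advanced nasopharyngeal carcinoma (LANPC).

Adding induction chemotherapy (ICT) to concurrent chemoradiotherapy (CCRT)
improves failure-free survival (FFS) on average, but at substantial toxicity,
and individual tumors respond very differently. This package implements, at
desk scale, the full procedure for building and validating the **Induction
Chemotherapy Outcome Score (ICTOS)** — a *predictive* (not merely prognostic)
imaging biomarker that identifies which patients gain FFS benefit from the
added ICT. It is aimed at researchers in quantitative imaging and
treatment-effect modeling who want a tested, reusable implementation of every
stage, exercisable without any patient data: a synthetic-data module generates
MR-like phantoms and two-arm survival cohorts with a *known, planted* benefit
subgroup, so each stage — and the pipeline end to end — is verifiable against
ground truth.

## The model

For patient $i$ with treatment $T_i \in \{0{=}\mathrm{CCRT}, 1{=}\mathrm{ICT{+}CCRT}\}$
and standardized radiomic features $x_i$, the hazard of failure is modeled as

$$\lambda(t \mid x_i, T_i) = \lambda_0(t)\, \exp\!\big(\gamma^\top W_i\big),
\qquad W_i = x_i\,\tfrac{2T_i - 1}{2},$$

the **modified covariate** working model (no main effects), whose partial
likelihood estimates the treatment–feature interaction directly: the relative
hazard of ICT for feature vector $x$ is $\exp(\gamma^\top x)$. The score

$$\mathrm{ICTOS}(x) = -\gamma^\top x$$

is therefore oriented so that $\mathrm{ICTOS} > 0$ predicts lower hazard
under ICT (benefit, "high ICTOS") and $\mathrm{ICTOS} \le 0$ predicts none
("low ICTOS"). The published three-feature model,

$$\mathrm{ICTOS} = -0.668\,\mathrm{skewness} - 0.442\,\mathrm{GLCM\_variance}
+ 0.410\,\mathrm{GLRLM\_LRHGLE},$$

on z-scored contrast-enhanced-T1 features, ships as a read-only fixture
(`ictos.load_published_model()`).

The surrounding pipeline reproduces the study procedure:

1. **Feature extraction** — 273 2D features per ROI (19 first-order, 10
   shape, 24 GLCM × 4 directions × 2 distances, 13 GLRLM × 4 directions)
   from each of axial T1, T2 and contrast-enhanced T1, i.e. 819 per patient,
   after in-plane resampling, z-score intensity normalization and 32-bin
   gray-level discretization.
2. **Reliability screen** — two-way random-effects, absolute-agreement
   ICC(2,1) on repeat segmentations; keep features with intra- and
   inter-observer ICC ≥ 0.8.
3. **IPTW** — stabilized inverse-probability-of-treatment weights from a
   logistic propensity model on age, sex, pEBV DNA, cervical nodal necrosis,
   primary tumor volume, N stage and T stage, balancing the observational
   training cohort (standardized mean differences before/after).
4. **Selection and fit** — per-feature weighted Cox interaction screen
   (ranked by Wald $p_{\mathrm{interaction}}$), greedy $|r| > 0.8$ redundancy
   filter, modified-covariate fit, backward stepwise selection at
   $\alpha = 0.05$.
5. **Evaluation** — weighted Kaplan–Meier curves with Greenwood (log–log)
   confidence bands, weighted Cox hazard ratios and log-rank tests, the
   treatment×group interaction test, log-rank power (event-driven normal
   approximation) and the clinical risk stratification of low-ICTOS patients
   (N2–3, T4, tumor volume ≥ 34 ml, pEBV DNA ≥ 2000 copies/ml).

## Worked example

```python
import ictos

power = ictos.logrank_power(ictos.PowerSpec(
    n_patients=110, n_events=29, allocation=0.5, hazard_ratio=0.25, alpha=0.05))
print(f"{power:.2f}")                      # 0.96
print(ictos.required_cohort_size(110, 0.47))  # 234

model = ictos.load_published_model()
s = model.score({"skewness": -2.02, "GLCM_variance": -1.26, "GLRLM_LRHGLE": 4.58})
print(f"{s.value:.2f} {s.label}")          # 3.78 high
```

The first two numbers are the study's design calculations: with 29 events
among 110 patients split 1:1, a true hazard ratio of 0.25 is detected with
probability 0.96 at two-sided 5%, and if that benefit subgroup is 47% of
LANPC, 234 patients are needed. The score 3.78 (> 0) labels the example
patient "high ICTOS": predicted to benefit from added induction chemotherapy.

Running the full study on synthetic cohorts
(`python examples/05_end_to_end_study.py`) prints, with the default seeds:

```
ICC-reliable features: 440 / 819
max SMD after IPTW: 0.073
high ICTOS group: n=146, arm HR = 0.57 (95% CI 0.32-1.03)
low  ICTOS group: n=104, arm HR = 0.76 (95% CI 0.40-1.45)
corr(fitted score, true benefit): 0.49
```

i.e. the pipeline balances the confounded training cohort, fits a benefit
model from images alone, and on the independent randomized cohort the
high-ICTOS group shows the smaller treatment hazard ratio while the fitted
score tracks the generator's true per-patient benefit. The other scripts in
`examples/` walk through each capability separately.

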