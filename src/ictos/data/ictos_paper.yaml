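name: ictos-published
description: >
  Published three-feature ICTOS linear model on standardized (z-scored)
  contrast-enhanced T1 radiomic features. Coefficients as printed (rounded
  to three decimals); scores > 0 predict benefit from induction chemotherapy.
features:
  - skewness
  - GLCM_variance
  - GLRLM_LRHGLE
coefficients:
  skewness: -0.668
  GLCM_variance: -0.442
  GLRLM_LRHGLE: 0.410
cutoff: 0.0
treatment_coding: "arm: 0 = CCRT alone, 1 = ICT+CCRT; W = x(2T-1)/2"
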