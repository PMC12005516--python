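# Model parameter set: baseline event rates, disability weights, and add-on
# therapy effects for insulin-treated type 2 diabetes.
#
# Conventions:
#   {mean, lo, hi} : point estimate with 95% CI -> Gaussian sampling
#                    (ratios on the log scale, mean-corrected; see docs/methods.md)
#   {lo, hi}       : interval with no stated central value -> Uniform sampling,
#                    midpoint in point-estimate mode
#   {point: x}     : fixed value, never sampled
# Rates are events per person-year unless the key says otherwise.

baseline:
  severe_hypo_rate: {mean: 0.052, lo: 0.042, hi: 0.064}   # insulin users, no add-on
  kidney_failure_rate: {lo: 0.0029, hi: 0.0074}
  mortality:
    # deaths per 1,000 person-years = coeff * exp(slope * age)
    coeff_per_1000: 1.769
    slope_per_year: 0.0565

disutility:
  severe_hypo: {value: {mean: 0.10, lo: 0.09, hi: 0.11}, duration_days: {lo: 1, hi: 1}}
  gi_severe: {value: {point: 0.188}, duration_days: {lo: 3, hi: 4}}
  pancreatitis: {value: {point: 0.324}, duration_days: {lo: 28, hi: 53}}
  urogenital: {value: {point: 0.051}, duration_days: {lo: 3, hi: 14}}
  dka: {value: {lo: 0.1, hi: 0.2}, duration_days: {lo: 3, hi: 7}}
  cvd: {value: {lo: 0.041, hi: 0.179}}          # chronic, per year in state
  kidney: {value: {lo: 0.104, hi: 0.571}}       # chronic, per year in state
  weight_per_kg: {value: {lo: 0.00012, hi: 0.00441}}  # per kg above/below baseline, per year

therapies:
  glp1ra_inj:
    insulin_reduction: {mean: 0.17, lo: 0.14, hi: 0.19}
    weight_change_kg: {mean: -3.4, lo: -4.5, hi: -2.3}
    hr_cvd: {mean: 0.82, lo: 0.68, hi: 0.98}
    hr_kidney: {mean: 0.79, lo: 0.66, hi: 0.94}
    hr_mortality: {mean: 0.80, lo: 0.67, hi: 0.95}
    rr_severe_hypo: {mean: 0.46, lo: 0.38, hi: 0.55}
    side_effects:
      gi_severe: {rate: {lo: 0.15, hi: 0.20}, kind: first_year_incidence}
      pancreatitis: {rate: {lo: 0.0012, hi: 0.0021}, kind: annual_rate}
  sglt2i:
    insulin_reduction: {mean: 0.11, lo: 0.06, hi: 0.16}
    weight_change_kg: {mean: -1.8, lo: -1.9, hi: -1.7}
    hr_cvd: {mean: 0.85, lo: 0.77, hi: 0.93}
    hr_kidney: {mean: 0.63, lo: 0.58, hi: 0.69}
    hr_mortality: {mean: 0.79, lo: 0.70, hi: 0.88}
    rr_severe_hypo: {mean: 1.24, lo: 0.77, hi: 2.00}
    side_effects:
      urogenital: {rate: {point: 0.0874}, kind: annual_rate, sex: female}
      urogenital_m: {rate: {point: 0.0119}, kind: annual_rate, sex: male, cause: urogenital}
      dka: {rate: {lo: 0.0006, hi: 0.0049}, kind: annual_rate}
  combo:
    # built on top of sglt2i: incremental insulin sparing, additive weight loss
    # and side effects, extra CVD risk-ratio multiplier; kidney and mortality
    # ratios inherited from sglt2i.
    incremental_insulin_reduction: {mean: 0.20, lo: 0.15, hi: 0.25}
    extra_weight_change_kg: {point: -1.61}
    extra_cvd_multiplier: {point: 0.85}
    hba1c_change_pct: {point: -0.74}      # recorded covariate change only
    sbp_change_mmhg: {point: -3.32}       # recorded covariate change only
  glp1ra_oral:
    # oral formulation: configurable fraction of the injectable insulin-sparing
    # effect; all other effects default to the injectable values.
    sparing_multiplier: 0.5
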