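# Per-country marginal distributions of insulin users in the pooled LMIC
# survey set, plus the pooled ("OVERALL") marginals.  Medians and IQRs are in
# the units noted; insulin_use_prevalence is the fraction of the total adult
# population reporting both a diabetes diagnosis and insulin use.
#
# population_size values are approximate national adult population counts
# (synthetic defaults, rounded public figures) used only for
# population-proportional cross-country weighting; they are not survey data.
# cvd_risk_scale is the country recalibration multiplier for the baseline
# cardiovascular risk equation (1.0 = no recalibration).
OVERALL:
  country: OVERALL
  n_insulin_users: 4837
  age_median: 57.00
  age_iqr_lo: 48.00
  age_iqr_hi: 64.00
  frac_female: 0.623
  weight_median: 75.00
  weight_iqr_lo: 64.00
  weight_iqr_hi: 87.40
  insulin_use_prevalence: 0.0196
  population_size: 898365000
  cvd_risk_scale: 1.0
DZA:
  country: DZA
  n_insulin_users: 172
  age_median: 54.00
  age_iqr_lo: 42.75
  age_iqr_hi: 62.00
  frac_female: 0.640
  weight_median: 77.00
  weight_iqr_lo: 68.10
  weight_iqr_hi: 87.35
  insulin_use_prevalence: 0.0247
  population_size: 44000000
  cvd_risk_scale: 1.0
BGD:
  country: BGD
  n_insulin_users: 109
  age_median: 50.00
  age_iqr_lo: 41.00
  age_iqr_hi: 58.00
  frac_female: 0.477
  weight_median: 64.00
  weight_iqr_lo: 56.00
  weight_iqr_hi: 70.25
  insulin_use_prevalence: 0.0133
  population_size: 165000000
  cvd_risk_scale: 1.0
BRA:
  country: BRA
  n_insulin_users: 629
  age_median: 62.00
  age_iqr_lo: 52.00
  age_iqr_hi: 70.00
  frac_female: 0.628
  weight_median: 72.70
  weight_iqr_lo: 63.10
  weight_iqr_hi: 84.45
  insulin_use_prevalence: 0.0108
  population_size: 213000000
  cvd_risk_scale: 1.0
CRI:
  country: CRI
  n_insulin_users: 131
  age_median: 61.50
  age_iqr_lo: 54.00
  age_iqr_hi: 72.00
  frac_female: 0.733
  weight_median: 73.50
  weight_iqr_lo: 66.00
  weight_iqr_hi: 85.00
  insulin_use_prevalence: 0.0392
  population_size: 5100000
  cvd_risk_scale: 1.0
EGY:
  country: EGY
  n_insulin_users: 227
  age_median: 51.00
  age_iqr_lo: 43.50
  age_iqr_hi: 56.00
  frac_female: 0.674
  weight_median: 89.00
  weight_iqr_lo: 76.00
  weight_iqr_hi: 102.00
  insulin_use_prevalence: 0.0149
  population_size: 102000000
  cvd_risk_scale: 1.0
IRN:
  country: IRN
  n_insulin_users: 359
  age_median: 60.00
  age_iqr_lo: 53.00
  age_iqr_hi: 67.50
  frac_female: 0.632
  weight_median: 75.00
  weight_iqr_lo: 66.03
  weight_iqr_hi: 83.47
  insulin_use_prevalence: 0.0118
  population_size: 84000000
  cvd_risk_scale: 1.0
JOR:
  country: JOR
  n_insulin_users: 157
  age_median: 59.00
  age_iqr_lo: 51.00
  age_iqr_hi: 64.00
  frac_female: 0.624
  weight_median: 85.90
  weight_iqr_lo: 74.93
  weight_iqr_hi: 97.58
  insulin_use_prevalence: 0.0280
  population_size: 10200000
  cvd_risk_scale: 1.0
LBY:
  country: LBY
  n_insulin_users: 131
  age_median: 52.00
  age_iqr_lo: 47.00
  age_iqr_hi: 60.00
  frac_female: 0.542
  weight_median: 83.00
  weight_iqr_lo: 71.75
  weight_iqr_hi: 92.80
  insulin_use_prevalence: 0.0378
  population_size: 6900000
  cvd_risk_scale: 1.0
MHL:
  country: MHL
  n_insulin_users: 106
  age_median: 53.00
  age_iqr_lo: 47.00
  age_iqr_hi: 63.00
  frac_female: 0.566
  weight_median: 70.40
  weight_iqr_lo: 62.30
  weight_iqr_hi: 84.00
  insulin_use_prevalence: 0.0355
  population_size: 59000
  cvd_risk_scale: 1.0
MEX:
  country: MEX
  n_insulin_users: 606
  age_median: 60.00
  age_iqr_lo: 50.25
  age_iqr_hi: 69.00
  frac_female: 0.601
  weight_median: 73.35
  weight_iqr_lo: 63.30
  weight_iqr_hi: 83.73
  insulin_use_prevalence: 0.0330
  population_size: 128000000
  cvd_risk_scale: 1.0
MAR:
  country: MAR
  n_insulin_users: 108
  age_median: 59.00
  age_iqr_lo: 51.00
  age_iqr_hi: 67.00
  frac_female: 0.722
  weight_median: 74.50
  weight_iqr_lo: 65.00
  weight_iqr_hi: 83.75
  insulin_use_prevalence: 0.0199
  population_size: 37000000
  cvd_risk_scale: 1.0
ZAF:
  country: ZAF
  n_insulin_users: 246
  age_median: 57.00
  age_iqr_lo: 50.00
  age_iqr_hi: 66.00
  frac_female: 0.642
  weight_median: 76.50
  weight_iqr_lo: 67.12
  weight_iqr_hi: 90.62
  insulin_use_prevalence: 0.0304
  population_size: 59000000
  cvd_risk_scale: 1.0
SDN:
  country: SDN
  n_insulin_users: 106
  age_median: 50.50
  age_iqr_lo: 41.00
  age_iqr_hi: 56.00
  frac_female: 0.642
  weight_median: 70.10
  weight_iqr_lo: 62.85
  weight_iqr_hi: 80.05
  insulin_use_prevalence: 0.0137
  population_size: 44000000
  cvd_risk_scale: 1.0
TON:
  country: TON
  n_insulin_users: 173
  age_median: 53.00
  age_iqr_lo: 46.00
  age_iqr_hi: 61.00
  frac_female: 0.665
  weight_median: 95.35
  weight_iqr_lo: 82.77
  weight_iqr_hi: 106.05
  insulin_use_prevalence: 0.0450
  population_size: 106000
  cvd_risk_scale: 1.0
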