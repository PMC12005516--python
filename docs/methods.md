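# Methods

This note documents the model implemented in `insulinshift`: its structure,
the conventions behind every numerical choice, what the synthetic data do
and do not emulate, and the known limitations.

## Model structure

Four stages, mirroring the module layout:

1. **Population** (`population`): synthetic insulin-user cohorts per
   country, calibrated to published survey marginals; survey CSV I/O;
   inclusion filtering; population-proportional cross-country weighting.
2. **Dosing** (`dosing`): current daily insulin dose as a linear function
   of body weight under three dosing-factor scenarios.
3. **Intervention** (`therapies`): per-strategy effect sets — insulin
   sparing, weight change, event-rate ratios, side-effect streams — and
   their application to baseline event rates.
4. **Outcomes** (`outcomes`, `uncertainty`): annual-cycle competing-risk
   simulation, DALY accounting, Monte Carlo propagation, decompositions.

## Synthetic populations

Only marginals are published per country: median/IQR of body weight and
age, fraction female, the surveyed count, and insulin-use prevalence. The
generator draws:

* **weight** log-normal, `ln W ~ N(ln median, σ)` with
  `σ = ln(q75/q25)/(2·z₀.₇₅)` — positive support and the right skew typical
  of body-weight data; the sample median converges to the target and the
  IQR to a geometrically symmetric approximation of it;
* **age** normal truncated to [18, 100], fitted the same way, rounded to
  whole years;
* **sex** Bernoulli(fraction female), independent of weight and age — the
  within-country joint distribution is not published, so independence given
  the marginals is the only defensible choice;
* **unpublished covariates** needed by the cardiovascular risk equation,
  from fixed plausible marginals for an insulin-treated T2DM population:
  SBP ~ N(135, 18) mmHg truncated [80, 220], total cholesterol
  ~ N(5.0, 1.1) mmol/L, 15% current smokers, 35% on BP medication, 10%
  prior CVD, HbA1c ~ N(8.5, 1.5)% truncated [5, 16].

All generated records are diagnosed insulin users (the profiles describe
that subpopulation); survey weights default to 1 within a country, and
pooling across countries rescales each country's total weight to its adult
population share. What passing calibration tests show is that the pipeline
reproduces *marginal-calibrated* populations; they say nothing about joint
covariate structure, survey design effects, or within-person biomarker
dynamics in real data, none of which are modeled.

## Dosing and insulin sparing

Dose is `factor × weight`, unrounded internally; table cells round
half-up to 2 decimals only at rendering. No cap or floor beyond
positivity; concurrent metformin is carried as a flag and leaves the dose
unchanged. Because the map is monotone and linear, every dose quantile is
exactly `factor ×` the weight quantile — the pipeline's dose tables use
this identity rather than re-estimating quantiles from samples.

Scenario–CI pairing: the low dose scenario applies the *upper* CI bound of
the sparing fraction and the high scenario the *lower* bound. This is the
unique pairing that reproduces all published low/high dose cells exactly,
and it brackets the plausible post-therapy dose range.

Combination therapy composes sparing multiplicatively with the SGLT2i
effect, `1 − (1−r_sglt2i)(1−r_inc)`, adds the extra weight loss (−1.61 kg)
and both side-effect profiles, multiplies the SGLT2i CVD ratio by 0.85,
and inherits the SGLT2i kidney and mortality ratios (the mortality ratio
for dual therapy is nowhere stated; inheriting monotherapy's is the
conservative choice). Its hypoglycemia RR is likewise unstated and is
composed multiplicatively (0.46 × 1.24), consistent with the treatment of
every other ratio. Oral GLP-1RA applies a configurable multiplier
(default 0.5) to the injectable sparing fraction; all other effects default
to the injectable values.

## Event simulation conventions

* Annual cycles. Death is drawn first each year (competing risk); a person
  dying that year contributes the full year of person-time but experiences
  no nonfatal events and no morbidity accrual for that year ("death at the
  end of the year").
* Chronic states (CVD, kidney failure) are absorbing Bernoulli onsets with
  probability `1 − exp(−rate)`; prevalent CVD at entry blocks new onsets
  but its ongoing disutility is not charged (it is identical across arms
  and not attributable to the simulated choice).
* Acute recurrent events (severe hypoglycemia, pancreatitis, urogenital
  infection, DKA) are Poisson counts with the annual rate as mean — so the
  expected event count per person-year equals the input rate, which a
  once-per-year Bernoulli would systematically undershoot — while the
  occurrence probability remains `1 − exp(−rate)`. Counts are drawn by
  exact inverse-CDF lookup of a shared uniform (truncated at 8 events per
  person-year; the omitted mass is < 10⁻¹⁰ at the modeled rates), which
  keeps draws usable as common random numbers.
* Severe gastrointestinal effects of GLP-1RA ("15–20% incidence") are a
  one-off first-year-on-therapy incidence, reflecting their early,
  transient nature; all other side effects are annual rates. Urogenital
  rates are sex-specific (87.4 vs 11.9 per 1,000 person-years).
* Mortality: Gompertz hazard `1.769·exp(0.0565·age)` interpreted **per
  1,000 person-years** (≈ 4.4%/year at the median age 57, plausible for
  insulin-treated T2DM; a per-person-year reading would imply certain
  death). The hazard updates as people age and is multiplied by the
  therapy's mortality ratio.
* Common random numbers: one uniform tensor with a fixed channel layout is
  drawn per simulation seed, so arms with different parameters share their
  randomness; nulling every effect reproduces the baseline arm
  bit-identically.

## DALY accounting

All flows are discounted by `(1+ρ)^(−t)` with end-of-year timing (an event
in year 1 is discounted one year), ρ = 3%/year by default.

* Acute events: `disutility × duration_days/365` at the event year.
* Chronic states: disutility per year from the onset year while alive.
* Weight: `disutility_per_kg × kg_change` per year on therapy — negative
  under weight loss, i.e., averted burden.
* Deaths: discounted years of life lost against remaining life expectancy,
  **truncated by default at the end of the evaluation window**
  (`yll_full_life=True` restores lifetime YLL).
* Population scale: survey-weighted DALYs per 1,000 person-years among
  insulin users, multiplied by the country's insulin-use prevalence to
  refer to the overall adult population.

**Evaluation window.** The default horizon is **2 years**, with all DALY
accrual (YLD, chronic burden, YLL) confined to the window. The rationale:
the intervention effects come from trials of roughly one to two years'
duration, and the outcome is defined as a per-person-year burden "adjusted
for duration of effect". This is also the only accounting under which the
relative sizes of the published benefit channels are reproducible — with
lifetime YLL, an all-cause mortality ratio of 0.79–0.80 applied to a
~44/1,000 py hazard dwarfs every morbidity channel and mortality would
account for essentially all of the improvement, contrary to the reported
predominance of weight-related morbidity for GLP-1RA and the near parity
of weight and mortality for SGLT2i, both of which emerge from the 2-year
window. The horizon is a plain argument everywhere and tables can be
recomputed under any window; cross-window *levels* are not comparable.

**Life expectancy** defaults to a synthetic life table obtained by
integrating survival under the same Gompertz hazard to age 110 (half-year
correction in the death year); a country life-table CSV
(`age,sex,mortality_rate_per_1000`) can replace it.

**Cardiovascular baseline risk** uses a documented Globorisk-style
proportional-hazards stand-in (linear predictor over age, sex, SBP,
smoking, total cholesterol, diabetes; reference 10-year risk 0.12 scaled
by `exp(lp)` and the per-country `cvd_risk_scale` multiplier; converted to
a constant annual hazard `−ln(1−R₁₀)/10`). The published country-specific
coefficient sets are not reproduced; any callable with the same signature
can be plugged in, and no reported quantity depends on the stand-in's
absolute level — only on its ratio under therapy.

## Parameter uncertainty

Every CI-parameterized input is Gaussian with `sd = (hi − lo)/3.92`,
truncated to its support (rates ≥ 0, proportions in [0, 1)). Hazard/risk
ratios are sampled on the **log** scale — a natural-scale Gaussian is
inconsistent with their asymmetric intervals (e.g., 1.24 [0.77, 2.00]) —
with the log-mean shifted by `−σ²/2` so the arithmetic mean of draws
equals the stated point estimate; `ratio_scale="natural"` restores
natural-scale sampling. Interval-only inputs (e.g., DKA rate 0.6–4.9 per
1,000 py, chronic disutilities) are uniform over their range and sit at
the midpoint in point-estimate mode. Draws are reproducible from a seed;
reporting is median [IQR] across draws, 1,000 draws being a reasonable
default and 200–400 sufficient for stable medians.

**Benefit decomposition** switches each channel (hypoglycemia, weight,
CVD, kidney, mortality, side effects) on alone against the no-therapy
baseline with common random numbers, and normalizes the six one-at-a-time
improvements to sum to 100% of the joint improvement; the side-effect
share can be negative. One-at-a-time attribution ignores channel
interactions, which are small here because the channels act on disjoint
causes (they interact only through survival).

**Uncertainty-source attribution** varies one source at a time — therapy
efficacy parameters, baseline event rates, simulation seeds — freezing the
other two, averages parameter-source outcomes over a small set of common
simulation seeds, and normalizes the three variances to 100%. The shares
are themselves Monte Carlo estimates and noticeably noisy below ~40 outer
draws.

## Defaults at a glance

| Parameter | Default | Units / note |
|---|---|---|
| dosing factors | 0.64 / 0.37 / 0.84 | IU/kg/day, main/low/high |
| insulin sparing | 0.17 / 0.11 / +0.20 | GLP-1RA / SGLT2i / combo increment |
| severe hypoglycemia | 0.052 (RR 0.46 / 1.24) | events/py; GLP-1RA / SGLT2i |
| kidney failure | 0.0029–0.0074 | events/py, uniform |
| mortality | 1.769·e^(0.0565·age) | per 1,000 py; HR 0.80 / 0.79 |
| CVD ratios | 0.82 / 0.85 (× 0.85 combo) | hazard/risk ratios |
| weight change | −3.4 / −1.8 / −3.41 | kg; disutility 0.00012–0.00441 per kg·yr |
| discount rate | 0.03 | per year, end-of-year timing |
| horizon | 2 | years (evaluation window) |
| Monte Carlo draws | 1,000 nominal | 400 in the acceptance script |

## Limitations

* Independence of weight, age and sex within country; no survey design
  variance; covariates beyond the published marginals are invented
  plausibly, so absolute CVD levels are illustrative.
* No HbA1c-mediated microvascular modeling, no retinopathy, no
  amputation/fracture risks (not class effects), no insulin
  discontinuation or initiation-delay scenarios, no costs.
* Basal vs prandial insulin is not distinguished; neither is type 1
  diabetes, which the source surveys cannot separate.
* The absolute DALY level depends strongly on the evaluation window and on
  the DALY conventions above; orderings across arms and channel rankings
  are the robust outputs, and only those are asserted in the test suite.
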