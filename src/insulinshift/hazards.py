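"""Baseline hazards: all-cause mortality, life expectancy, cardiovascular risk.

Mortality for insulin-treated type 2 diabetes follows a Gompertz-type
schedule, ``coeff * exp(slope * age)`` deaths per 1,000 person-years
(defaults 1.769 and 0.0565 /year, ~44 deaths per 1,000 person-years at the
cohort median age of 57).  The synthetic life table used for years of life
lost is derived from that same schedule by integrating survival to the
terminal age; a country life-table CSV (``age,sex,mortality_rate_per_1000``)
can override it.

The 10-year cardiovascular risk uses a Globorisk-style proportional-hazards
linear predictor over age, sex, systolic blood pressure, smoking, total
cholesterol and diabetes, recalibrated per country through the profile's
``cvd_risk_scale`` multiplier.  The published country-specific coefficient
set is not reproduced here — the default predictor is a documented,
pluggable stand-in whose absolute level is configurable, and any callable
with the same signature can replace it.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .params import ModelParams
from .population import CountryProfile

__all__ = [
    "baseline_mortality_rate",
    "make_life_expectancy",
    "load_life_table",
    "ten_year_cvd_risk",
    "baseline_cvd_rate",
]

logger = logging.getLogger(__name__)

_TERMINAL_AGE = 110


def baseline_mortality_rate(age, coeff_per_1000: float = 1.769, slope: float = 0.0565):
    """All-cause mortality hazard, deaths per person-year.

    The schedule is parameterized per 1,000 person-years and divided by
    1,000 here; a per-person-year reading of the same coefficients would
    imply certain death at every adult age.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be nonnegative")
    rate = coeff_per_1000 * np.exp(slope * a) / 1000.0
    return float(rate) if np.ndim(age) == 0 else rate


def make_life_expectancy(
    params: ModelParams | None = None,
    coeff_per_1000: float | None = None,
    slope: float | None = None,
) -> Callable:
    """Remaining life expectancy (years) as a callable of age.

    Built by integrating survival under the baseline mortality schedule from
    each age to the terminal age (110), with a half-year correction for the
    year of death.
    """
    if params is not None:
        coeff_per_1000 = params.mortality_coeff_per_1000
        slope = params.mortality_slope
    coeff_per_1000 = 1.769 if coeff_per_1000 is None else coeff_per_1000
    slope = 0.0565 if slope is None else slope

    ages = np.arange(0, _TERMINAL_AGE + 1)
    m = baseline_mortality_rate(ages, coeff_per_1000, slope)
    return _life_expectancy_from_schedule(ages, m)


def _life_expectancy_from_schedule(ages: np.ndarray, m: np.ndarray) -> Callable:
    p_surv = np.exp(-m)  # within-year survival
    le = np.zeros(len(ages))
    # backward recursion: LE(a) = S(a)*(1 + LE(a+1)) + (1-S(a))*0.5
    for i in range(len(ages) - 2, -1, -1):
        le[i] = p_surv[i] * (1.0 + le[i + 1]) + (1.0 - p_surv[i]) * 0.5

    def life_expectancy(age):
        a = np.clip(np.asarray(age, dtype=float), ages[0], ages[-1])
        out = np.interp(a, ages, le)
        return float(out) if np.ndim(age) == 0 else out

    return life_expectancy


def load_life_table(path: str | Path) -> Callable:
    """Life-expectancy callable from a ``age,sex,mortality_rate_per_1000`` CSV.

    If the table carries both sexes the schedules are averaged (the
    downstream callable takes age only).
    """
    df = pd.read_csv(path)
    required = {"age", "sex", "mortality_rate_per_1000"}
    if not required.issubset(df.columns):
        raise ValueError(f"life table {path} must have columns {sorted(required)}")
    sched = (
        df.groupby("age")["mortality_rate_per_1000"].mean().sort_index()
    )
    ages = sched.index.to_numpy(dtype=float)
    m = sched.to_numpy(dtype=float) / 1000.0
    return _life_expectancy_from_schedule(ages, m)


# Globorisk-style default linear predictor (documented stand-in, pluggable).
_CVD_REF_RISK10 = 0.12  # 10-year risk at the reference covariate pattern
_CVD_COEF = {
    "age": 0.068,        # per year from 60
    "male": 0.42,
    "smoker": 0.48,
    "sbp": 0.016,        # per mmHg from 140
    "tchol": 0.14,       # per mmol/L from 5.2
    "diabetes": 0.55,
}


def ten_year_cvd_risk(
    age, female, smoker, sbp, tchol, diabetes=True, scale: float = 1.0
):
    """Default 10-year first-CVD-event risk (proportional-hazards form)."""
    lp = (
        _CVD_COEF["age"] * (np.asarray(age, dtype=float) - 60.0)
        + _CVD_COEF["male"] * (1.0 - np.asarray(female, dtype=float))
        + _CVD_COEF["smoker"] * np.asarray(smoker, dtype=float)
        + _CVD_COEF["sbp"] * (np.asarray(sbp, dtype=float) - 140.0)
        + _CVD_COEF["tchol"] * (np.asarray(tchol, dtype=float) - 5.2)
        + _CVD_COEF["diabetes"] * np.asarray(diabetes, dtype=float)
    )
    risk = 1.0 - (1.0 - _CVD_REF_RISK10) ** (np.exp(lp) * scale)
    return np.clip(risk, 0.0, 0.95)


def baseline_cvd_rate(
    records: pd.DataFrame,
    profile: CountryProfile,
    risk_fn: Callable = ten_year_cvd_risk,
) -> np.ndarray:
    """Per-person annual CVD event rate from the 10-year risk equation.

    A 10-year risk ``R`` converts to a constant annual hazard
    ``-ln(1 - R)/10``.  People with missing covariates get the country mean
    rate (logged warning) rather than an imputed covariate pattern.
    """
    age = pd.to_numeric(records["age"], errors="coerce")
    sbp = pd.to_numeric(records["sbp_mmhg"], errors="coerce")
    tchol = pd.to_numeric(records["tchol_mmoll"], errors="coerce")
    female = records["sex"].astype(str).eq("female")
    smoker = records["smoker"].astype(bool)

    complete = age.notna() & sbp.notna() & tchol.notna()
    rate = np.full(len(records), np.nan)
    if complete.any():
        risk10 = risk_fn(
            age[complete].to_numpy(),
            female[complete].to_numpy(),
            smoker[complete].to_numpy(),
            sbp[complete].to_numpy(),
            tchol[complete].to_numpy(),
            diabetes=True,
            scale=profile.cvd_risk_scale,
        )
        rate[complete.to_numpy()] = -np.log1p(-np.asarray(risk10)) / 10.0
    if (~complete).any():
        n_miss = int((~complete).sum())
        if complete.any():
            fallback = float(np.nanmean(rate))
        else:
            fallback = -np.log1p(-_CVD_REF_RISK10 * profile.cvd_risk_scale) / 10.0
        logger.warning(
            "%s: %d record(s) missing CVD covariates; using country mean rate",
            profile.country, n_miss,
        )
        rate[~complete.to_numpy()] = fallback
    return rate
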