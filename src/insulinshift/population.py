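"""Synthetic survey populations of insulin users and survey-table I/O.

The packaged country profile file carries, for each country, the marginal
distributions of insulin users observed in pooled national surveys (median
and IQR of age and body weight, fraction female, insulin-use prevalence in
the overall adult population).  :func:`generate_population` draws a synthetic
cohort matching those marginals; :func:`load_survey`/:func:`write_survey`
read and write the harmonized survey CSV schema documented in the README.

Joint structure beyond the published marginals is not available, so weight,
age and sex are drawn independently; body weight is log-normal (positive,
right-skewed, as body-weight data are), age is a normal truncated to
[18, 100].  Both are parameterized by matching the 25th/50th/75th
percentiles to the profile's median and IQR.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .utils import Z75

__all__ = [
    "SURVEY_COLUMNS",
    "CountryProfile",
    "load_country_profiles",
    "generate_population",
    "write_survey",
    "load_survey",
    "filter_insulin_users",
    "country_report_mask",
    "pooled_survey_weights",
]

logger = logging.getLogger(__name__)

#: Harmonized survey CSV schema (column order is part of the contract).
SURVEY_COLUMNS = [
    "person_id",
    "country",
    "age",
    "sex",
    "weight_kg",
    "hba1c_pct",
    "fpg_mgdl",
    "diabetes_dx",
    "on_dm_meds",
    "on_insulin",
    "smoker",
    "sbp_mmhg",
    "on_bp_meds",
    "prior_cvd",
    "tchol_mmoll",
    "survey_weight",
]

_BOOL_COLUMNS = ["diabetes_dx", "on_dm_meds", "on_insulin", "smoker", "on_bp_meds", "prior_cvd"]
_OPTIONAL_NUMERIC = ["hba1c_pct", "fpg_mgdl", "tchol_mmoll"]


@dataclass(frozen=True)
class CountryProfile:
    """Marginal distributions of insulin users in one country's survey."""

    country: str
    n_insulin_users: int
    weight_median: float
    weight_iqr_lo: float
    weight_iqr_hi: float
    age_median: float
    age_iqr_lo: float
    age_iqr_hi: float
    frac_female: float
    insulin_use_prevalence: float
    population_size: float
    cvd_risk_scale: float = 1.0

    def __post_init__(self) -> None:
        for stem in ("weight", "age"):
            lo = getattr(self, f"{stem}_iqr_lo")
            med = getattr(self, f"{stem}_median")
            hi = getattr(self, f"{stem}_iqr_hi")
            if not (lo <= med <= hi):
                raise ValueError(f"{self.country}: {stem} IQR not ordered around median")
        if not 0.0 <= self.frac_female <= 1.0:
            raise ValueError(f"{self.country}: frac_female outside [0, 1]")
        if not 0.0 < self.insulin_use_prevalence < 1.0:
            raise ValueError(f"{self.country}: insulin_use_prevalence outside (0, 1)")
        if self.cvd_risk_scale <= 0:
            raise ValueError(f"{self.country}: cvd_risk_scale must be positive")


def _default_profile_path() -> Path:
    return Path(
        importlib.resources.files("insulinshift").joinpath("data/country_profiles.yaml")  # type: ignore[arg-type]
    )


def load_country_profiles(
    path: str | Path | None = None, include_overall: bool = False
) -> dict[str, CountryProfile]:
    """Load country profiles (YAML); ``None`` loads the packaged defaults.

    The pooled pseudo-country ``OVERALL`` is excluded unless requested; it is
    used for pooled-population generation, never in per-country reporting.
    """
    p = Path(path) if path is not None else _default_profile_path()
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, CountryProfile] = {}
    for code, entry in raw.items():
        if code == "OVERALL" and not include_overall:
            continue
        out[code] = CountryProfile(**entry)
    return out


def generate_population(profile: CountryProfile, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` synthetic insulin users matching the profile's marginals.

    Deterministic for a fixed seed.  All generated records are insulin users
    with a provider diagnosis (the profile describes the insulin-using
    subpopulation); HbA1c is drawn from a plausible insulin-treated range and
    fasting glucose is left missing.  Survey weights default to 1 within a
    country; cross-country pooling reweights via :func:`pooled_survey_weights`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")

    rng = np.random.default_rng(seed)

    sigma_w = np.log(profile.weight_iqr_hi / profile.weight_iqr_lo) / (2 * Z75)
    weight = np.exp(rng.normal(np.log(profile.weight_median), sigma_w, size=n))

    sigma_a = (profile.age_iqr_hi - profile.age_iqr_lo) / (2 * Z75)
    a, b = (18 - profile.age_median) / sigma_a, (100 - profile.age_median) / sigma_a
    age = stats.truncnorm.rvs(
        a, b, loc=profile.age_median, scale=sigma_a, size=n, random_state=rng
    )
    age = np.round(age).astype(int)

    female = rng.random(n) < profile.frac_female
    # Covariates below are not published per country; fixed plausible
    # marginals for an insulin-treated T2DM population (see docs/methods.md).
    sbp = stats.truncnorm.rvs(
        (80 - 135) / 18, (220 - 135) / 18, loc=135.0, scale=18.0, size=n, random_state=rng
    )
    smoker = rng.random(n) < 0.15
    on_bp_meds = rng.random(n) < 0.35
    prior_cvd = rng.random(n) < 0.10
    tchol = stats.truncnorm.rvs(
        (2.0 - 5.0) / 1.1, (12.0 - 5.0) / 1.1, loc=5.0, scale=1.1, size=n, random_state=rng
    )
    hba1c = stats.truncnorm.rvs(
        (5.0 - 8.5) / 1.5, (16.0 - 8.5) / 1.5, loc=8.5, scale=1.5, size=n, random_state=rng
    )

    return pd.DataFrame(
        {
            "person_id": [f"{profile.country}-{i:06d}" for i in range(n)],
            "country": profile.country,
            "age": age,
            "sex": np.where(female, "female", "male"),
            "weight_kg": weight,
            "hba1c_pct": hba1c,
            "fpg_mgdl": np.nan,
            "diabetes_dx": True,
            "on_dm_meds": True,
            "on_insulin": True,
            "smoker": smoker,
            "sbp_mmhg": sbp,
            "on_bp_meds": on_bp_meds,
            "prior_cvd": prior_cvd,
            "tchol_mmoll": tchol,
            "survey_weight": 1.0,
        },
        columns=SURVEY_COLUMNS,
    )


def write_survey(records: pd.DataFrame, path: str | Path) -> None:
    """Write the harmonized survey CSV (booleans as 0/1, missing as empty)."""
    df = records.loc[:, SURVEY_COLUMNS].copy()
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(int)
    df.to_csv(path, index=False, na_rep="")


def load_survey(path: str | Path) -> pd.DataFrame:
    """Read a harmonized survey CSV.

    Raises on missing mandatory columns; rows with an unparseable numeric or
    a non-positive body weight are rejected with a logged warning.  Missing
    optional biomarkers stay missing (NaN) — they are never imputed.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey file {path} is missing columns: {missing}")
    df = df.loc[:, SURVEY_COLUMNS]

    bad = np.zeros(len(df), dtype=bool)
    numeric = ["age", "weight_kg", "sbp_mmhg", "survey_weight"] + _OPTIONAL_NUMERIC
    parsed: dict[str, pd.Series] = {}
    for col in numeric:
        vals = pd.to_numeric(df[col].where(df[col].str.strip() != ""), errors="coerce")
        unparseable = vals.isna() & (df[col].str.strip() != "")
        if col not in _OPTIONAL_NUMERIC:
            unparseable |= df[col].str.strip() == ""
        if unparseable.any():
            logger.warning(
                "%s: %d row(s) with unparseable or missing %s rejected",
                path, int(unparseable.sum()), col,
            )
        bad |= unparseable.to_numpy()
        parsed[col] = vals

    nonpos = (parsed["weight_kg"] <= 0).fillna(False).to_numpy()
    if nonpos.any():
        logger.warning("%s: %d row(s) with non-positive weight rejected", path, int(nonpos.sum()))
    bad |= nonpos

    negw = (parsed["survey_weight"] < 0).fillna(False).to_numpy()
    if negw.any():
        logger.warning("%s: %d row(s) with negative survey weight rejected", path, int(negw.sum()))
    bad |= negw

    out = df.loc[~bad].copy()
    for col, vals in parsed.items():
        out[col] = vals.loc[~bad]
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype(str).str.strip().isin(["1", "1.0", "True", "true"])
    out["age"] = out["age"].astype(float)
    return out.reset_index(drop=True)


def filter_insulin_users(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the analysis inclusion rule.

    Keeps people currently on insulin who also have a diabetes history:
    provider diagnosis, fasting glucose >= 126 mg/dL, or HbA1c >= 6.5%
    (boundaries inclusive).  Missing biomarkers count as not meeting their
    criterion; the operation is idempotent.
    """
    fpg = pd.to_numeric(records["fpg_mgdl"], errors="coerce")
    hba1c = pd.to_numeric(records["hba1c_pct"], errors="coerce")
    has_dm = (
        records["diabetes_dx"].astype(bool)
        | (fpg >= 126.0).fillna(False)
        | (hba1c >= 6.5).fillna(False)
    )
    mask = records["on_insulin"].astype(bool) & has_dm
    return records.loc[mask].reset_index(drop=True)


def country_report_mask(
    profiles: dict[str, CountryProfile] | list[CountryProfile], min_n: int = 100
) -> list[str]:
    """Countries with enough surveyed insulin users for per-country reporting.

    Pooled results are always computed over every country regardless of this
    mask; the mask only gates the per-country table columns.
    """
    items = profiles.values() if isinstance(profiles, dict) else profiles
    return [p.country for p in items if p.country != "OVERALL" and p.n_insulin_users >= min_n]


def pooled_survey_weights(
    records: pd.DataFrame, profiles: dict[str, CountryProfile]
) -> pd.Series:
    """Rescale survey weights so countries contribute by population share.

    Within a country, relative survey weights are preserved; across
    countries, each country's total weight is proportional to its adult
    population size.
    """
    w = records["survey_weight"].astype(float).copy()
    total_pop = sum(p.population_size for c, p in profiles.items() if c != "OVERALL")
    for code, grp in records.groupby("country"):
        if code not in profiles:
            raise KeyError(f"no profile for country {code}")
        share = profiles[code].population_size / total_pop
        denom = grp["survey_weight"].astype(float).sum()
        if denom <= 0:
            raise ValueError(f"{code}: survey weights sum to zero")
        w.loc[grp.index] = grp["survey_weight"].astype(float) * share / denom
    return w
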