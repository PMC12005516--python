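"""Annual-cycle event simulation under competing risks, and DALY accounting.

Each simulated year: death is drawn first (competing risk; a person who dies
still contributes that year as person-time but experiences no nonfatal
events), then chronic-state onsets (cardiovascular disease, kidney failure —
absorbing states, at most one onset) as Bernoulli with probability
``1 - exp(-rate)``, then acute recurrent events (severe hypoglycemia and
therapy side effects) as Poisson counts with the annual rate as mean — so
observed event counts recover the input rates while the occurrence
probability remains ``1 - exp(-rate)``.  Ages advance each cycle and the
mortality hazard updates with age.

DALY accounting (all flows discounted by ``(1+r)^-t`` with end-of-year
timing, default r = 3%/year):

* acute events contribute ``disutility x duration_days/365``;
* chronic states contribute their disutility per year from onset while
  alive, within the evaluation window;
* therapy weight change contributes ``disutility_per_kg x kg_change`` per
  year on therapy (negative for weight loss — averted burden);
* deaths contribute years of life lost against remaining life expectancy,
  by default truncated at the evaluation window ("duration of effect"
  accounting; set ``yll_full_life=True`` for lifetime YLL).

All randomness comes from a fixed-layout uniform tensor drawn once per
simulation seed, so two runs with the same seed but different therapy
parameters share their random numbers (common random numbers across arms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .hazards import baseline_cvd_rate, baseline_mortality_rate, make_life_expectancy
from .params import ModelParams
from .population import CountryProfile
from .therapies import EventRateSet, TherapyEffect, modified_rates

__all__ = [
    "DEFAULT_HORIZON",
    "DEFAULT_DISCOUNT",
    "DisutilityTable",
    "EventHistory",
    "CohortHistory",
    "DalyResult",
    "build_event_rates",
    "simulate_cohort",
    "simulate_person",
    "dalys_from_cohort",
    "daly_from_history",
    "population_daly",
]

#: Default evaluation window in years (see docs/methods.md for rationale).
DEFAULT_HORIZON = 2
DEFAULT_DISCOUNT = 0.03

ACUTE_CAUSES = ("severe_hypo", "gi_severe", "pancreatitis", "urogenital", "dka")
CHRONIC_CAUSES = ("cvd", "kidney")
ALL_CAUSES = ACUTE_CAUSES + CHRONIC_CAUSES + ("weight", "mortality")

# fixed channel layout for the common-random-number uniform tensor
_CHANNELS = (
    "death", "cvd_onset", "kidney_onset",
    "severe_hypo", "gi_annual", "gi_first", "pancreatitis", "urogenital", "dka",
)
_POISSON_KMAX = 8  # exact inverse-CDF truncation; P(X>8) < 1e-10 for mu <= 0.5


@dataclass(frozen=True)
class DisutilityTable:
    """Utility decrements and durations per modeled cause.

    ``acute`` maps cause to ``(disutility, duration_days)``; ``chronic``
    maps cause to a per-year disutility while in the state;
    ``weight_per_kg`` is the per-kilogram annual disutility used for the
    weight channel.
    """

    acute: Mapping[str, tuple[float, float]]
    chronic: Mapping[str, float]
    weight_per_kg: float

    def __post_init__(self) -> None:
        for cause, (d, dur) in self.acute.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"{cause}: disutility outside [0, 1]")
            if dur <= 0:
                raise ValueError(f"{cause}: duration must be positive")
        for cause, d in self.chronic.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"{cause}: disutility outside [0, 1]")

    @classmethod
    def from_params(
        cls, params: ModelParams, values: Mapping[str, float] | None = None
    ) -> "DisutilityTable":
        def _v(key: str, param) -> float:
            if values is not None and key in values:
                return float(values[key])
            return param.point

        acute = {}
        for cause in ACUTE_CAUSES:
            entry = params.disutility[cause]
            acute[cause] = (
                _v(f"disutility.{cause}.value", entry["value"]),
                _v(f"disutility.{cause}.duration_days", entry["duration_days"]),
            )
        chronic = {
            cause: _v(f"disutility.{cause}.value", params.disutility[cause]["value"])
            for cause in CHRONIC_CAUSES
        }
        return cls(
            acute=acute,
            chronic=chronic,
            weight_per_kg=_v(
                "disutility.weight_per_kg.value",
                params.disutility["weight_per_kg"]["value"],
            ),
        )


@dataclass
class CohortHistory:
    """Vectorized event history of a simulated cohort.

    Years are 1-based; ``death_year`` is 0 for survivors.  ``events`` holds
    per-cause ``(n, horizon)`` count arrays; chronic onset years are 0 when
    the state was never entered during the simulation (prevalent disease at
    entry blocks onsets but is not an onset).
    """

    horizon: int
    age0: np.ndarray
    death_year: np.ndarray
    person_years: np.ndarray
    events: dict[str, np.ndarray]
    cvd_onset: np.ndarray
    kidney_onset: np.ndarray
    weight_change: float

    @property
    def n(self) -> int:
        return len(self.age0)

    def survivor_mask(self) -> np.ndarray:
        """(n, horizon) bool: alive through the end of each year."""
        t = np.arange(1, self.horizon + 1)
        dy = self.death_year[:, None]
        return (dy == 0) | (t[None, :] < dy)


@dataclass
class EventHistory:
    """One person's simulated history (see :class:`CohortHistory`)."""

    horizon: int
    person_years: float
    death_year: int | None
    age_at_death: float | None
    acute_events: dict[str, list[tuple[int, int]]]  # cause -> [(year, count)]
    chronic_onsets: dict[str, int]  # cause -> onset year
    weight_change: float = 0.0


@dataclass
class DalyResult:
    """Discounted DALYs lost, total and decomposed.

    ``total = yld + yll`` and ``sum(by_cause.values()) = total`` (the weight
    component may be negative: averted burden).  For population runs the
    scale is DALYs per 1,000 person-years of the overall country population.
    """

    total: float
    by_cause: dict[str, float]
    yld: float
    yll: float
    discount_rate: float
    person_years: float
    n: int = 1

    def __post_init__(self) -> None:
        if abs(self.total - (self.yld + self.yll)) > 1e-9 * max(1.0, abs(self.total)):
            raise ValueError("total != yld + yll")
        if abs(sum(self.by_cause.values()) - self.total) > 1e-9 * max(1.0, abs(self.total)):
            raise ValueError("by_cause does not sum to total")


def _poisson_counts(u: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Poisson counts by exact inverse-CDF lookup of uniforms (CRN-friendly)."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), u.shape)
    term = np.exp(-mu)
    cdf = term.copy()
    counts = (u > cdf).astype(np.int64)
    for k in range(1, _POISSON_KMAX):
        term = term * mu / k
        cdf = cdf + term
        counts += u > cdf
    return counts


def build_event_rates(
    records: pd.DataFrame,
    profile: CountryProfile,
    params: ModelParams,
    values: Mapping[str, float] | None = None,
    risk_fn=None,
) -> EventRateSet:
    """Baseline (pre-therapy) per-person annual event rates."""

    def _v(key, param):
        if values is not None and key in values:
            return float(values[key])
        return param.point

    kwargs = {} if risk_fn is None else {"risk_fn": risk_fn}
    return EventRateSet(
        severe_hypo=_v("baseline.severe_hypo_rate", params.severe_hypo_rate),
        cvd=baseline_cvd_rate(records, profile, **kwargs),
        kidney_failure=_v("baseline.kidney_failure_rate", params.kidney_failure_rate),
    )


def _side_effect_rate_arrays(
    rates: EventRateSet, female: np.ndarray
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Resolve side-effect specs to per-person (annual, first-year) rates."""
    n = len(female)
    annual = {c: np.zeros(n) for c in ("gi_severe", "pancreatitis", "urogenital", "dka")}
    first = {c: np.zeros(n) for c in annual}
    for spec in rates.side_effects:
        if spec.cause not in annual:
            raise ValueError(f"side effect {spec.name}: unknown cause {spec.cause}")
        mask = np.ones(n, dtype=bool)
        if spec.sex == "female":
            mask = female
        elif spec.sex == "male":
            mask = ~female
        target = first if spec.kind == "first_year_incidence" else annual
        target[spec.cause] = target[spec.cause] + spec.rate * mask
    return annual, first


def simulate_cohort(
    age,
    female,
    prior_cvd,
    rates: EventRateSet,
    horizon: int = DEFAULT_HORIZON,
    seed: int = 0,
    mortality_fn: Callable | None = None,
) -> CohortHistory:
    """Simulate ``horizon`` annual cycles for a cohort; seed-deterministic."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    age0 = np.asarray(age, dtype=float)
    female = np.asarray(female, dtype=bool)
    prior = np.asarray(prior_cvd, dtype=bool)
    n = len(age0)
    if mortality_fn is None:
        mortality_fn = baseline_mortality_rate

    rng = np.random.default_rng(seed)
    U = rng.random((len(_CHANNELS), n, horizon))
    ch = {name: U[i] for i, name in enumerate(_CHANNELS)}

    cvd_rate = np.broadcast_to(np.asarray(rates.cvd, dtype=float), (n,))
    annual_se, first_se = _side_effect_rate_arrays(rates, female)

    alive = np.ones(n, dtype=bool)
    has_cvd = prior.copy()
    has_kid = np.zeros(n, dtype=bool)
    death_year = np.zeros(n, dtype=np.int64)
    cvd_onset = np.zeros(n, dtype=np.int64)
    kid_onset = np.zeros(n, dtype=np.int64)
    person_years = np.zeros(n)
    events = {c: np.zeros((n, horizon), dtype=np.int64) for c in ACUTE_CAUSES}

    cur_age = age0.copy()
    for t in range(1, horizon + 1):
        j = t - 1
        person_years += alive  # the dying year still counts as person-time

        if rates.mortality_rate_override is not None:
            m = np.full(n, rates.mortality_rate_override)
        else:
            m = mortality_fn(cur_age)
        m = m * rates.mortality_hr
        dying = alive & (ch["death"][:, j] < -np.expm1(-m))
        survivors = alive & ~dying
        death_year[dying] = t

        new_cvd = survivors & ~has_cvd & (ch["cvd_onset"][:, j] < -np.expm1(-cvd_rate))
        has_cvd |= new_cvd
        cvd_onset[new_cvd] = t
        new_kid = survivors & ~has_kid & (
            ch["kidney_onset"][:, j] < -np.expm1(-rates.kidney_failure)
        )
        has_kid |= new_kid
        kid_onset[new_kid] = t

        events["severe_hypo"][:, j] = survivors * _poisson_counts(
            ch["severe_hypo"][:, j], rates.severe_hypo
        )
        for cause, channel in (
            ("gi_severe", "gi_annual"),
            ("pancreatitis", "pancreatitis"),
            ("urogenital", "urogenital"),
            ("dka", "dka"),
        ):
            events[cause][:, j] = survivors * _poisson_counts(
                ch[channel][:, j], annual_se[cause]
            )
        if t == 1:
            for cause in first_se:
                inc = first_se[cause]
                if np.any(inc > 0):
                    events[cause][:, j] += (survivors & (ch["gi_first"][:, j] < inc)).astype(
                        np.int64
                    )

        cur_age = cur_age + 1.0
        alive = survivors

    return CohortHistory(
        horizon=horizon,
        age0=age0,
        death_year=death_year,
        person_years=person_years,
        events=events,
        cvd_onset=cvd_onset,
        kidney_onset=kid_onset,
        weight_change=rates.weight_change,
    )


def simulate_person(
    person,
    rates: EventRateSet,
    horizon: int = DEFAULT_HORIZON,
    seed: int = 0,
    mortality_fn: Callable | None = None,
) -> EventHistory:
    """Simulate one person (mapping with ``age``, ``sex``, ``prior_cvd``)."""
    cohort = simulate_cohort(
        [float(person["age"])],
        [str(person.get("sex", "female")) == "female"],
        [bool(person.get("prior_cvd", False))],
        rates,
        horizon=horizon,
        seed=seed,
        mortality_fn=mortality_fn,
    )
    return cohort_to_histories(cohort)[0]


def cohort_to_histories(cohort: CohortHistory) -> list[EventHistory]:
    """Expand a cohort history into per-person :class:`EventHistory` records."""
    out = []
    for i in range(cohort.n):
        dy = int(cohort.death_year[i])
        acute = {}
        for cause, arr in cohort.events.items():
            acute[cause] = [
                (t + 1, int(arr[i, t])) for t in range(cohort.horizon) if arr[i, t] > 0
            ]
        chronic = {}
        if cohort.cvd_onset[i] > 0:
            chronic["cvd"] = int(cohort.cvd_onset[i])
        if cohort.kidney_onset[i] > 0:
            chronic["kidney"] = int(cohort.kidney_onset[i])
        out.append(
            EventHistory(
                horizon=cohort.horizon,
                person_years=float(cohort.person_years[i]),
                death_year=dy if dy > 0 else None,
                age_at_death=float(cohort.age0[i] + dy) if dy > 0 else None,
                acute_events=acute,
                chronic_onsets=chronic,
                weight_change=cohort.weight_change,
            )
        )
    return out


def _yll_years(duration, t_death, v):
    """Discounted stream of ``duration`` years starting the year after death."""
    duration = np.asarray(duration, dtype=float)
    t_death = np.asarray(t_death, dtype=float)
    full = np.floor(duration)
    frac = duration - full
    if v == 1.0:
        discounted_full = full
    else:
        discounted_full = v * (1.0 - v**full) / (1.0 - v)
    return v**t_death * (discounted_full + frac * v ** (full + 1.0))


def dalys_from_cohort(
    cohort: CohortHistory,
    disutilities: DisutilityTable,
    discount: float = DEFAULT_DISCOUNT,
    life_expectancy: Callable | None = None,
    yll_full_life: bool = False,
) -> dict[str, np.ndarray]:
    """Per-person discounted DALY components, one (n,) array per cause."""
    if life_expectancy is None:
        life_expectancy = make_life_expectancy()
    v = 1.0 / (1.0 + discount)
    t = np.arange(1, cohort.horizon + 1)
    df = v**t  # end-of-year discounting

    out: dict[str, np.ndarray] = {}
    for cause in ACUTE_CAUSES:
        d, dur = disutilities.acute.get(cause, (0.0, 1.0))  # absent cause: no burden
        out[cause] = (cohort.events[cause] * df[None, :]).sum(axis=1) * d * (dur / 365.0)

    surv = cohort.survivor_mask()
    for cause, onset in (("cvd", cohort.cvd_onset), ("kidney", cohort.kidney_onset)):
        in_state = surv & (onset[:, None] > 0) & (t[None, :] >= onset[:, None])
        out[cause] = (in_state * df[None, :]).sum(axis=1) * disutilities.chronic.get(cause, 0.0)

    out["weight"] = (
        (surv * df[None, :]).sum(axis=1)
        * disutilities.weight_per_kg
        * cohort.weight_change
    )

    yll = np.zeros(cohort.n)
    died = cohort.death_year > 0
    if died.any():
        t_d = cohort.death_year[died].astype(float)
        le = np.asarray(life_expectancy(cohort.age0[died] + t_d), dtype=float)
        dur = le if yll_full_life else np.minimum(le, cohort.horizon - t_d)
        yll[died] = _yll_years(dur, t_d, v)
    out["mortality"] = yll
    return out


def _result_from_components(
    comps: dict[str, np.ndarray],
    weights: np.ndarray,
    person_years: np.ndarray,
    discount: float,
    scale: float = 1.0,
) -> DalyResult:
    wsum_py = float(np.sum(weights * person_years))
    if wsum_py <= 0:
        raise ValueError("no person-time simulated")
    by_cause = {
        c: float(np.sum(weights * arr)) / wsum_py * 1000.0 * scale
        for c, arr in comps.items()
    }
    yll = by_cause["mortality"]
    yld = sum(val for c, val in by_cause.items() if c != "mortality")
    return DalyResult(
        total=yld + yll,
        by_cause=by_cause,
        yld=yld,
        yll=yll,
        discount_rate=discount,
        person_years=wsum_py,
        n=len(person_years),
    )


def daly_from_history(
    history: EventHistory,
    disutilities: DisutilityTable,
    discount: float = DEFAULT_DISCOUNT,
    life_expectancy: Callable | None = None,
    yll_full_life: bool = False,
) -> DalyResult:
    """DALYs for a single simulated person (plain-loop reference path).

    Deliberately written as explicit per-year loops, independent of the
    vectorized cohort path, so the two can cross-check each other.
    """
    if life_expectancy is None:
        life_expectancy = make_life_expectancy()
    v = 1.0 / (1.0 + discount)

    by_cause: dict[str, float] = {c: 0.0 for c in ALL_CAUSES}
    for cause, eventlist in history.acute_events.items():
        d, dur = disutilities.acute[cause]
        for year, count in eventlist:
            by_cause[cause] += count * d * (dur / 365.0) * v**year

    last_alive = history.death_year - 1 if history.death_year else history.horizon
    for cause, onset in history.chronic_onsets.items():
        for year in range(onset, last_alive + 1):
            by_cause[cause] += disutilities.chronic[cause] * v**year

    for year in range(1, last_alive + 1):
        by_cause["weight"] += (
            disutilities.weight_per_kg * history.weight_change * v**year
        )

    if history.death_year is not None:
        le = float(life_expectancy(history.age_at_death))
        dur = le if yll_full_life else min(le, history.horizon - history.death_year)
        full, frac = int(np.floor(dur)), dur - np.floor(dur)
        stream = sum(v**k for k in range(1, full + 1)) + frac * v ** (full + 1)
        by_cause["mortality"] = v**history.death_year * stream

    yll = by_cause["mortality"]
    yld = sum(val for c, val in by_cause.items() if c != "mortality")
    return DalyResult(
        total=yld + yll,
        by_cause=by_cause,
        yld=yld,
        yll=yll,
        discount_rate=discount,
        person_years=history.person_years,
        n=1,
    )


def population_daly(
    persons: pd.DataFrame,
    therapy: TherapyEffect | None,
    profile: CountryProfile,
    params: ModelParams,
    values: Mapping[str, float] | None = None,
    horizon: int = DEFAULT_HORIZON,
    seed: int = 0,
    discount: float = DEFAULT_DISCOUNT,
    life_expectancy: Callable | None = None,
    pooled_weights: pd.Series | None = None,
    risk_fn=None,
    yll_full_life: bool = False,
) -> DalyResult:
    """Discounted DALYs lost per 1,000 person-years of the overall population.

    DALYs are first computed per 1,000 person-years among the insulin users
    in ``persons`` (survey-weighted), then scaled by the profile's
    insulin-use prevalence so the result refers to the whole adult
    population.  With ``therapy=None`` this is the pre-therapy baseline.
    The same ``seed`` yields identical event streams across therapy arms.
    """
    if len(persons) == 0:
        raise ValueError("empty population")
    rates = build_event_rates(persons, profile, params, values, risk_fn=risk_fn)
    if therapy is not None:
        rates = modified_rates(rates, therapy)

    mortality_fn = lambda a: baseline_mortality_rate(
        a, params.mortality_coeff_per_1000, params.mortality_slope
    )
    cohort = simulate_cohort(
        persons["age"].to_numpy(dtype=float),
        persons["sex"].astype(str).eq("female").to_numpy(),
        persons["prior_cvd"].astype(bool).to_numpy(),
        rates,
        horizon=horizon,
        seed=seed,
        mortality_fn=mortality_fn,
    )
    if life_expectancy is None:
        life_expectancy = make_life_expectancy(params)
    comps = dalys_from_cohort(
        cohort,
        DisutilityTable.from_params(params, values),
        discount=discount,
        life_expectancy=life_expectancy,
        yll_full_life=yll_full_life,
    )
    w = (
        pooled_weights.to_numpy(dtype=float)
        if pooled_weights is not None
        else persons["survey_weight"].to_numpy(dtype=float)
    )
    return _result_from_components(
        comps, w, cohort.person_years, discount, scale=profile.insulin_use_prevalence
    )
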