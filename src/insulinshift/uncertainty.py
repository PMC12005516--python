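"""Monte Carlo parameter uncertainty, benefit decomposition, variance sources.

Sampling model: every CI-parameterized input is Gaussian with the standard
deviation implied by its 95% interval, ``sd = (hi - lo)/(2 x 1.96)``,
truncated to its admissible support.  Rate/risk ratios are sampled on the
log scale (a natural-scale Gaussian is inconsistent with their asymmetric
intervals) with the log-mean shifted by ``-sd_log^2/2`` so the arithmetic
mean of draws equals the stated point estimate; a natural-scale switch is
available for strict symmetry.  Interval-only inputs are uniform over their
range.

Within one draw, every therapy arm is evaluated with the same simulation
seed (common random numbers), so between-arm differences reflect parameters,
not sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .outcomes import DEFAULT_DISCOUNT, DEFAULT_HORIZON, population_daly
from .params import ModelParams, Param
from .population import CountryProfile
from .therapies import CHANNELS, TherapyEffect, build_therapy, restrict_channels

__all__ = [
    "ParamSpec",
    "ParameterDraw",
    "build_param_specs",
    "point_draw",
    "draw_parameters",
    "run_ensemble",
    "decompose_contributions",
    "decompose_uncertainty",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain input: flat key, its :class:`Param`, sampling family."""

    key: str
    param: Param
    family: str  # ratio | proportion | rate | real | uniform


@dataclass(frozen=True)
class ParameterDraw:
    """One sampled value per uncertain parameter."""

    draw_id: int
    seed: int
    values: Mapping[str, float]


def build_param_specs(params: ModelParams) -> list[ParamSpec]:
    """Registry of every sampled parameter in a parameter set."""
    specs = [
        ParamSpec("baseline.severe_hypo_rate", params.severe_hypo_rate, "rate"),
        ParamSpec("baseline.kidney_failure_rate", params.kidney_failure_rate, "uniform"),
    ]
    for cause, entry in params.disutility.items():
        if entry["value"].kind != "fixed":
            specs.append(
                ParamSpec(f"disutility.{cause}.value", entry["value"], "proportion")
            )
        dur = entry["duration_days"]
        if dur is not None and dur.kind != "fixed" and dur.lo != dur.hi:
            specs.append(ParamSpec(f"disutility.{cause}.duration_days", dur, "uniform"))

    for tname in ("glp1ra_inj", "sglt2i"):
        cfg = params.therapies[tname]
        specs.append(
            ParamSpec(
                f"therapy.{tname}.insulin_reduction",
                Param.from_config(cfg["insulin_reduction"]),
                "proportion",
            )
        )
        specs.append(
            ParamSpec(
                f"therapy.{tname}.weight_change_kg",
                Param.from_config(cfg["weight_change_kg"]),
                "real",
            )
        )
        for ratio_key in ("hr_cvd", "hr_kidney", "hr_mortality", "rr_severe_hypo"):
            specs.append(
                ParamSpec(
                    f"therapy.{tname}.{ratio_key}",
                    Param.from_config(cfg[ratio_key]),
                    "ratio",
                )
            )
        for se_name, entry in (cfg.get("side_effects") or {}).items():
            p = Param.from_config(entry["rate"])
            if p.kind == "fixed":
                continue
            family = (
                "proportion" if entry.get("kind") == "first_year_incidence" else "uniform"
            )
            specs.append(
                ParamSpec(f"therapy.{tname}.side_effects.{se_name}", p, family)
            )
    specs.append(
        ParamSpec(
            "therapy.combo.incremental_insulin_reduction",
            Param.from_config(params.therapies["combo"]["incremental_insulin_reduction"]),
            "proportion",
        )
    )
    return sorted(specs, key=lambda s: s.key)


def point_draw(params: ModelParams) -> ParameterDraw:
    """The degenerate draw fixing every parameter at its point estimate."""
    return ParameterDraw(
        draw_id=-1,
        seed=0,
        values={s.key: s.param.point for s in build_param_specs(params)},
    )


def _sample_spec(
    spec: ParamSpec, n: int, rng: np.random.Generator, ratio_scale: str
) -> np.ndarray:
    p = spec.param
    if p.kind == "fixed" or p.lo == p.hi:
        return np.full(n, p.point)
    if spec.family == "uniform" or p.kind == "range":
        return rng.uniform(p.lo, p.hi, size=n)

    sd = (p.hi - p.lo) / (2 * _Z95)
    if spec.family == "ratio" and ratio_scale == "log":
        sd_log = np.log(p.hi / p.lo) / (2 * _Z95)
        # mean-corrected: arithmetic mean of draws equals the point estimate
        mu = np.log(p.mean) - 0.5 * sd_log**2
        return np.exp(rng.normal(mu, sd_log, size=n))

    bounds = {
        "ratio": (1e-9, np.inf),  # natural-scale ratios, truncated positive
        "rate": (0.0, np.inf),
        "proportion": (0.0, 1.0 - 1e-9),
        "real": (-np.inf, np.inf),
    }[spec.family]
    a = (bounds[0] - p.mean) / sd
    b = (bounds[1] - p.mean) / sd
    return stats.truncnorm.rvs(a, b, loc=p.mean, scale=sd, size=n, random_state=rng)


def draw_parameters(
    params: ModelParams,
    n_draws: int,
    seed: int,
    ratio_scale: str = "log",
) -> list[ParameterDraw]:
    """Sample ``n_draws`` joint parameter draws; deterministic for a seed."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if ratio_scale not in ("log", "natural"):
        raise ValueError("ratio_scale must be 'log' or 'natural'")
    specs = build_param_specs(params)
    rng = np.random.default_rng(seed)
    samples = {s.key: _sample_spec(s, n_draws, rng, ratio_scale) for s in specs}
    return [
        ParameterDraw(
            draw_id=i, seed=seed, values={k: float(v[i]) for k, v in samples.items()}
        )
        for i in range(n_draws)
    ]


def _sim_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)


def run_ensemble(
    persons: pd.DataFrame,
    therapy_names: Sequence[str],
    draws: Sequence[ParameterDraw],
    profile: CountryProfile,
    params: ModelParams,
    horizon: int = DEFAULT_HORIZON,
    seed: int = 0,
    discount: float = DEFAULT_DISCOUNT,
    pooled_weights: pd.Series | None = None,
    **daly_kwargs,
) -> dict[str, dict]:
    """Distribution of population DALYs per therapy arm across draws.

    Returns, per arm (including the no-therapy arm ``"none"``), the vector
    of totals across draws plus its median and IQR — the reporting
    convention used throughout.
    """
    if len(draws) < 1:
        raise ValueError("need at least one parameter draw")
    arms: dict[str, list[float]] = {"none": []}
    for name in therapy_names:
        arms[name] = []
    seeds = _sim_seeds(seed, len(draws))
    for i, draw in enumerate(draws):
        sim_seed = int(seeds[i])
        for name in arms:
            therapy = None if name == "none" else build_therapy(name, params, draw.values)
            res = population_daly(
                persons,
                therapy,
                profile,
                params,
                values=draw.values,
                horizon=horizon,
                seed=sim_seed,
                discount=discount,
                pooled_weights=pooled_weights,
                **daly_kwargs,
            )
            arms[name].append(res.total)
    out = {}
    for name, vals in arms.items():
        arr = np.asarray(vals)
        out[name] = {
            "dalys": arr,
            "median": float(np.median(arr)),
            "iqr": (float(np.quantile(arr, 0.25)), float(np.quantile(arr, 0.75))),
        }
    return out


def decompose_contributions(
    persons: pd.DataFrame,
    therapy: TherapyEffect | str,
    profile: CountryProfile,
    params: ModelParams,
    values: Mapping[str, float] | None = None,
    horizon: int = DEFAULT_HORIZON,
    seed: int = 0,
    pooled_weights: pd.Series | None = None,
    **daly_kwargs,
) -> pd.DataFrame:
    """Percent of the DALY improvement attributable to each benefit channel.

    One-at-a-time activation with common random numbers: each channel is
    switched on alone against the no-therapy baseline, and contributions are
    normalized to sum to 100%.  The side-effect channel can be negative.
    Raises if the full therapy yields no improvement.
    """
    effect = (
        build_therapy(therapy, params, values) if isinstance(therapy, str) else therapy
    )
    common = dict(
        profile=profile,
        params=params,
        values=values,
        horizon=horizon,
        seed=seed,
        pooled_weights=pooled_weights,
        **daly_kwargs,
    )
    base = population_daly(persons, None, **common)
    all_on = population_daly(persons, effect, **common)
    total_improvement = base.total - all_on.total
    if total_improvement <= 0:
        raise ValueError(
            "therapy does not improve total DALYs under these parameters; "
            "percentage attribution is undefined"
        )
    rows = []
    for channel in CHANNELS:
        variant = restrict_channels(effect, {channel})
        imp = base.total - population_daly(persons, variant, **common).total
        rows.append({"channel": channel, "improvement": imp})
    df = pd.DataFrame(rows)
    denom = df["improvement"].sum()
    if denom <= 0:
        raise ValueError("channel improvements sum to zero; attribution undefined")
    df["percent"] = 100.0 * df["improvement"] / denom
    df.attrs["total_improvement"] = total_improvement
    return df


def decompose_uncertainty(
    persons: pd.DataFrame,
    therapy: str,
    profile: CountryProfile,
    params: ModelParams,
    n_outer: int = 30,
    n_inner: int = 2,
    seed: int = 0,
    horizon: int = DEFAULT_HORIZON,
    pooled_weights: pd.Series | None = None,
    **daly_kwargs,
) -> dict[str, float]:
    """Variance share of each uncertainty source in the therapy-arm DALYs.

    One-source-at-a-time attribution: for each source — efficacy of the new
    medications (``therapy.*`` parameters), baseline event rates
    (``baseline.*``), and Monte Carlo sampling (simulation seeds) — the
    other two are frozen at their point values / a fixed seed set while the
    source varies across ``n_outer`` draws.  Parameter-source outcomes are
    averaged over ``n_inner`` common simulation seeds; shares are normalized
    to 100%.
    """
    if n_outer < 2 or n_inner < 2:
        raise ValueError("n_outer and n_inner must be >= 2")
    point = point_draw(params).values
    inner_seeds = [int(s) for s in _sim_seeds(seed, n_inner)]
    common = dict(
        profile=profile,
        params=params,
        horizon=horizon,
        pooled_weights=pooled_weights,
        **daly_kwargs,
    )

    def evaluate(values: Mapping[str, float], sim_seed: int) -> float:
        eff = build_therapy(therapy, params, values)
        return population_daly(
            persons, eff, values=values, seed=sim_seed, **common
        ).total

    variances: dict[str, float] = {}
    for label, prefix, src_seed in (
        ("parameter_efficacy", "therapy.", seed + 1),
        ("baseline_rates", "baseline.", seed + 2),
    ):
        outcomes = []
        for draw in draw_parameters(params, n_outer, src_seed):
            values = dict(point)
            values.update(
                {k: v for k, v in draw.values.items() if k.startswith(prefix)}
            )
            outcomes.append(
                float(np.mean([evaluate(values, s) for s in inner_seeds]))
            )
        variances[label] = float(np.var(outcomes, ddof=1))

    sampling_outcomes = [
        evaluate(point, int(s)) for s in _sim_seeds(seed + 3, n_outer)
    ]
    variances["sampling"] = float(np.var(sampling_outcomes, ddof=1))

    total = sum(variances.values())
    if total <= 0:
        raise ValueError("all variance sources are degenerate (zero variance)")
    return {k: 100.0 * v / total for k, v in variances.items()}
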