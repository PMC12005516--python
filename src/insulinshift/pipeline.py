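"""End-to-end orchestration: run the model and emit paper-style tables.

Outputs (CSV, one per table):

* ``table1_baseline.csv`` — cohort characteristics and estimated current
  insulin dose under the three dosing scenarios;
* ``table2_glp1ra.csv`` / ``table3_sglt2i.csv`` — dose after therapy and
  absolute change, by scenario (CI-bound pairing for low/high);
* ``table4_dalys.csv`` — DALYs lost per 1,000 person-years of the overall
  population, before therapy and under each strategy;
* ``fig1_decomposition.csv`` — percent contribution of each benefit channel;
* ``s2_combo_oral.csv`` — combination and oral-formulation results;
* ``manifest.json`` — seed, config, input-file hashes and versions, enough
  to reproduce the run byte-for-byte.

Dose tables are deterministic transforms of the profile weight quantiles
and are always computed in point-estimate mode; DALY tables use Monte Carlo
draws when ``n_draws > 1``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dosing import DEFAULT_SCENARIOS
from .outcomes import DEFAULT_DISCOUNT, DEFAULT_HORIZON
from .params import load_params
from .population import (
    country_report_mask,
    generate_population,
    load_country_profiles,
    load_survey,
)
from .therapies import apply_insulin_sparing, build_therapy, scenario_bound_pairing
from .uncertainty import (
    decompose_contributions,
    draw_parameters,
    point_draw,
    run_ensemble,
)
from .utils import round_half_up

__all__ = ["RunConfig", "run_pipeline", "render_cell"]

logger = logging.getLogger(__name__)

VALID_THERAPIES = ("glp1ra_inj", "sglt2i", "combo", "glp1ra_oral")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    outdir: str = "results"
    mode: str = "synthetic"  # synthetic | csv
    survey_path: str | None = None
    profiles_path: str | None = None
    params_path: str | None = None
    therapies: tuple[str, ...] = ("glp1ra_inj", "sglt2i")
    scenarios: tuple[str, ...] = ("main", "low", "high")
    n_draws: int = 1
    horizon: int = DEFAULT_HORIZON
    discount: float = DEFAULT_DISCOUNT
    seed: int = 0
    min_n: int = 100
    n_per_country: int | None = None  # default: the profile's surveyed count

    def validate(self) -> None:
        bad = [t for t in self.therapies if t not in VALID_THERAPIES]
        if bad:
            raise ValueError(
                f"unknown therapy name(s) {bad}; valid names: {list(VALID_THERAPIES)}"
            )
        bad = [s for s in self.scenarios if s not in DEFAULT_SCENARIOS]
        if bad:
            raise ValueError(
                f"unknown dosing scenario(s) {bad}; valid: {list(DEFAULT_SCENARIOS)}"
            )
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.mode == "csv" and not self.survey_path:
            raise ValueError("mode 'csv' requires survey_path")
        for p in (self.survey_path, self.profiles_path, self.params_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        if self.seed is None:
            raise ValueError("seed must be set (no silent nondeterminism)")
        if self.n_draws < 1 or self.horizon < 1:
            raise ValueError("n_draws and horizon must be >= 1")


def render_cell(median: float, q25: float | None = None, q75: float | None = None) -> str:
    """Format a table cell as ``median [q25, q75]``, rounded half-up to 2 dp."""
    m = f"{round_half_up(median):.2f}"
    if q25 is None or q75 is None:
        return m
    return f"{m} [{round_half_up(q25):.2f}, {round_half_up(q75):.2f}]"


def _country_seed(seed: int, idx: int) -> int:
    return int(np.random.SeedSequence([seed, idx]).generate_state(1, np.uint32)[0])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dose_quantiles(profile) -> dict[str, dict[str, float]]:
    return {
        name: {
            "median": profile.weight_median * sc.factor,
            "q25": profile.weight_iqr_lo * sc.factor,
            "q75": profile.weight_iqr_hi * sc.factor,
        }
        for name, sc in DEFAULT_SCENARIOS.items()
    }


def _therapy_dose_table(profiles, therapy, scenarios) -> pd.DataFrame:
    """Dose after therapy and change, per scenario and country (exact)."""
    table: dict[str, dict[str, str]] = {}
    for code, profile in profiles.items():
        dq = _dose_quantiles(profile)
        col: dict[str, str] = {}
        for sname in scenarios:
            quantile = scenario_bound_pairing(DEFAULT_SCENARIOS[sname], therapy)
            after = {
                k: apply_insulin_sparing(v, therapy, quantile)[0]
                for k, v in dq[sname].items()
            }
            change = {
                k: apply_insulin_sparing(v, therapy, quantile)[1]
                for k, v in dq[sname].items()
            }
            col[f"after_{sname}"] = render_cell(
                after["median"], after["q25"], after["q75"]
            )
            col[f"change_{sname}"] = render_cell(
                change["median"], change["q25"], change["q75"]
            )
        table[code] = col
    return pd.DataFrame(table)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write every output table; returns paths."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    params = load_params(config.params_path)
    profiles_all = load_country_profiles(config.profiles_path, include_overall=True)
    profiles = {c: p for c, p in profiles_all.items() if c != "OVERALL"}
    overall = profiles_all.get("OVERALL")
    mask = country_report_mask(profiles, config.min_n)
    report_profiles = {}
    if overall is not None:
        report_profiles["OVERALL"] = overall
    report_profiles.update({c: profiles[c] for c in sorted(mask)})

    # --- populations ------------------------------------------------------
    populations: dict[str, pd.DataFrame] = {}
    if config.mode == "csv":
        survey = load_survey(config.survey_path)
        from .population import filter_insulin_users

        survey = filter_insulin_users(survey)
        for code in report_profiles:
            pop = survey if code == "OVERALL" else survey[survey["country"] == code]
            if len(pop) == 0:
                logger.warning("no surveyed insulin users for %s; column skipped", code)
                continue
            populations[code] = pop.reset_index(drop=True)
    else:
        for idx, (code, profile) in enumerate(sorted(report_profiles.items())):
            n = config.n_per_country or profile.n_insulin_users
            populations[code] = generate_population(
                profile, n, _country_seed(config.seed, idx)
            )

    # --- table 1: baseline characteristics and current dose ---------------
    t1: dict[str, dict[str, str]] = {}
    for code, p in report_profiles.items():
        dq = _dose_quantiles(p)
        t1[code] = {
            "n": str(p.n_insulin_users),
            "age_years": render_cell(p.age_median, p.age_iqr_lo, p.age_iqr_hi),
            "female_pct": f"{round_half_up(100 * p.frac_female, 1):.1f}",
            "weight_kg": render_cell(p.weight_median, p.weight_iqr_lo, p.weight_iqr_hi),
            **{
                f"dose_{s}": render_cell(dq[s]["median"], dq[s]["q25"], dq[s]["q75"])
                for s in config.scenarios
            },
            "insulin_use_pct": f"{round_half_up(100 * p.insulin_use_prevalence):.2f}",
        }
    table1 = pd.DataFrame(t1)

    # --- tables 2/3 and S2 dose block: therapy effects on dose -------------
    dose_tables: dict[str, pd.DataFrame] = {}
    for tname in ("glp1ra_inj", "sglt2i", "combo", "glp1ra_oral"):
        therapy = build_therapy(tname, params)
        dose_tables[tname] = _therapy_dose_table(
            report_profiles, therapy, config.scenarios
        )

    # --- table 4: DALYs ----------------------------------------------------
    if config.n_draws > 1:
        draws = draw_parameters(params, config.n_draws, config.seed)
    else:
        draws = [point_draw(params)]
    t4: dict[str, dict[str, str]] = {}
    for code, profile in report_profiles.items():
        if code not in populations:
            continue
        ens = run_ensemble(
            populations[code],
            list(config.therapies),
            draws,
            profile,
            params,
            horizon=config.horizon,
            seed=config.seed,
            discount=config.discount,
        )
        col = {}
        for arm, stats_ in ens.items():
            label = "before" if arm == "none" else f"after_{arm}"
            if config.n_draws > 1:
                col[label] = render_cell(
                    stats_["median"], stats_["iqr"][0], stats_["iqr"][1]
                )
            else:
                col[label] = render_cell(stats_["median"])
        t4[code] = col
    table4 = pd.DataFrame(t4)

    # --- figure 1 data: benefit decomposition (pooled population) ----------
    fig_profile = overall if overall is not None else next(iter(profiles.values()))
    fig_pop = (
        populations["OVERALL"]
        if "OVERALL" in populations
        else next(iter(populations.values()))
    )
    fig_rows = []
    for tname in config.therapies:
        per_draw = []
        for i, draw in enumerate(draws):
            df = decompose_contributions(
                fig_pop,
                tname,
                fig_profile,
                params,
                values=draw.values,
                horizon=config.horizon,
                seed=_country_seed(config.seed, 1000 + i),
            )
            per_draw.append(df.set_index("channel")["percent"])
        stack = pd.concat(per_draw, axis=1)
        for channel in stack.index:
            vals = stack.loc[channel].to_numpy()
            fig_rows.append(
                {
                    "therapy": tname,
                    "channel": channel,
                    "percent": round_half_up(float(np.median(vals))),
                    "iqr_lo": round_half_up(float(np.quantile(vals, 0.25))),
                    "iqr_hi": round_half_up(float(np.quantile(vals, 0.75))),
                }
            )
    fig1 = pd.DataFrame(fig_rows)

    # --- write -------------------------------------------------------------
    outputs: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame, index_label: str = "row") -> None:
        path = outdir / name
        df.to_csv(path, index_label=index_label)
        outputs[name] = path

    _write("table1_baseline.csv", table1)
    _write("table2_glp1ra.csv", dose_tables["glp1ra_inj"])
    _write("table3_sglt2i.csv", dose_tables["sglt2i"])
    _write("table4_dalys.csv", table4)
    fig1.to_csv(outdir / "fig1_decomposition.csv", index=False)
    outputs["fig1_decomposition.csv"] = outdir / "fig1_decomposition.csv"
    s2 = pd.concat(
        {"combo": dose_tables["combo"], "glp1ra_oral": dose_tables["glp1ra_oral"]},
        names=["therapy", "row"],
    )
    s2.to_csv(outdir / "s2_combo_oral.csv")
    outputs["s2_combo_oral.csv"] = outdir / "s2_combo_oral.csv"

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "countries_reported": sorted(mask),
        "input_hashes": {
            "params": _sha256(
                Path(config.params_path)
                if config.params_path
                else Path(__file__).parent / "data" / "therapy_params.yaml"
            ),
            "profiles": _sha256(
                Path(config.profiles_path)
                if config.profiles_path
                else Path(__file__).parent / "data" / "country_profiles.yaml"
            ),
        },
        "versions": {
            "insulinshift": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest.json"] = outdir / "manifest.json"
    logger.info("pipeline run complete: %d outputs in %s", len(outputs), outdir)
    return outputs
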