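import numpy as np
import pandas as pd
import pytest

import insulinshift as ins
from insulinshift.outcomes import (
    DisutilityTable,
    EventHistory,
    cohort_to_histories,
    dalys_from_cohort,
    simulate_cohort,
)
from insulinshift.therapies import EventRateSet


class TestBaselineMortality:
    def test_median_age_value(self):
        """Gompertz schedule at the cohort median age: ~44.3 per 1,000 py."""
        assert ins.baseline_mortality_rate(57) * 1000 == pytest.approx(
            1.769 * np.exp(0.0565 * 57), rel=1e-12
        )
        assert ins.baseline_mortality_rate(57) * 1000 == pytest.approx(44.30, abs=0.01)

    def test_age_zero_is_coefficient(self):
        assert ins.baseline_mortality_rate(0) * 1000 == pytest.approx(1.769)

    def test_strictly_increasing_in_age(self):
        ages = np.arange(18, 100)
        rates = ins.baseline_mortality_rate(ages)
        assert np.all(np.diff(rates) > 0)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            ins.baseline_mortality_rate(-1)


class TestBaselineCvdRate:
    def _records(self, **overrides):
        base = {
            "age": [50.0, 60.0],
            "sex": ["male", "male"],
            "smoker": [False, False],
            "sbp_mmhg": [140.0, 140.0],
            "tchol_mmoll": [5.2, 5.2],
        }
        base.update(overrides)
        return pd.DataFrame(base)

    def test_ten_year_risk_to_annual_rate_closed_form(self, overall):
        rate = ins.baseline_cvd_rate(
            self._records(), overall, risk_fn=lambda *a, **k: np.full(2, 0.10)
        )
        assert rate == pytest.approx(-np.log(0.9) / 10)
        assert rate[0] == pytest.approx(0.010536, abs=1e-6)

    def test_zero_risk_gives_zero_rate(self, overall):
        rate = ins.baseline_cvd_rate(
            self._records(), overall, risk_fn=lambda *a, **k: np.zeros(2)
        )
        assert np.all(rate == 0.0)

    def test_monotone_in_age_over_covariate_grid(self, overall):
        # brute force: older is riskier at every covariate pattern
        for sex in ("male", "female"):
            for smoker in (False, True):
                for sbp in (120.0, 160.0):
                    for tchol in (4.0, 6.5):
                        df = pd.DataFrame(
                            {
                                "age": [50.0, 60.0],
                                "sex": [sex, sex],
                                "smoker": [smoker, smoker],
                                "sbp_mmhg": [sbp, sbp],
                                "tchol_mmoll": [tchol, tchol],
                            }
                        )
                        r = ins.baseline_cvd_rate(df, overall)
                        assert r[1] > r[0]

    def test_missing_covariates_fall_back_to_country_mean(self, overall, caplog):
        df = self._records(sbp_mmhg=[140.0, np.nan])
        import logging

        with caplog.at_level(logging.WARNING):
            r = ins.baseline_cvd_rate(df, overall)
        assert r[1] == pytest.approx(r[0])  # mean of the single complete record
        assert any("missing CVD covariates" in rec.message for rec in caplog.records)

    def test_country_recalibration_scales_risk(self, overall, profiles):
        df = self._records()
        hi = ins.CountryProfile(**{**overall.__dict__, "cvd_risk_scale": 2.0})
        assert np.all(ins.baseline_cvd_rate(df, hi) > ins.baseline_cvd_rate(df, overall))


class TestSimulateCohort:
    def _zero_rates(self, **kw):
        defaults = dict(
            severe_hypo=0.0, cvd=0.0, kidney_failure=0.0, mortality_rate_override=0.0
        )
        defaults.update(kw)
        return EventRateSet(**defaults)

    def test_all_rates_zero_empty_history(self):
        coh = simulate_cohort(
            np.full(20, 50.0), np.ones(20, bool), np.zeros(20, bool),
            self._zero_rates(), horizon=10, seed=1,
        )
        assert np.all(coh.person_years == 10.0)
        assert np.all(coh.death_year == 0)
        assert all(arr.sum() == 0 for arr in coh.events.values())

    def test_certain_death_limit(self):
        coh = simulate_cohort(
            np.full(50, 50.0), np.ones(50, bool), np.zeros(50, bool),
            self._zero_rates(mortality_rate_override=1000.0), horizon=10, seed=1,
        )
        assert np.all(coh.death_year == 1)
        assert np.all(coh.person_years == 1.0)

    def test_person_years_bounded_with_equality_iff_no_deaths(self):
        rates = self._zero_rates(mortality_rate_override=0.1)
        coh = simulate_cohort(
            np.full(200, 60.0), np.ones(200, bool), np.zeros(200, bool),
            rates, horizon=5, seed=2,
        )
        assert coh.person_years.sum() <= 200 * 5
        deaths = (coh.death_year > 0).sum()
        assert deaths > 0
        early_deaths = ((coh.death_year > 0) & (coh.death_year < 5)).sum()
        assert (coh.person_years < 5).sum() == early_deaths

    def test_deterministic_and_crn_across_null_arms(self, params, overall, pooled_pop):
        pop = pooled_pop.head(300)
        a = ins.population_daly(pop, None, overall, params, seed=5)
        b = ins.population_daly(pop, ins.null_therapy(), overall, params, seed=5)
        assert a.total == b.total
        assert a.by_cause == b.by_cause

    def test_dying_year_counts_person_time_but_no_events(self):
        rates = EventRateSet(
            severe_hypo=50.0, cvd=0.0, kidney_failure=0.0,
            mortality_rate_override=1000.0,
        )
        coh = simulate_cohort(
            np.full(30, 50.0), np.ones(30, bool), np.zeros(30, bool),
            rates, horizon=3, seed=0,
        )
        # competing risk applied first: everyone dies in year 1 before events
        assert coh.events["severe_hypo"].sum() == 0
        assert np.all(coh.person_years == 1.0)

    def test_chronic_states_absorbing(self):
        rates = EventRateSet(
            severe_hypo=0.0, cvd=5.0, kidney_failure=0.0, mortality_rate_override=0.0
        )
        coh = simulate_cohort(
            np.full(100, 50.0), np.ones(100, bool), np.zeros(100, bool),
            rates, horizon=6, seed=3,
        )
        assert np.all(coh.cvd_onset >= 1)  # rate 5/py: onset ~certain, once only


class TestDalyArithmetic:
    def _table(self, chronic_cvd=0.2):
        return DisutilityTable(
            acute={"severe_hypo": (0.10, 1.0)},
            chronic={"cvd": chronic_cvd, "kidney": 0.3},
            weight_per_kg=0.002,
        )

    def _history(self, **kw):
        base = dict(
            horizon=5,
            person_years=5.0,
            death_year=None,
            age_at_death=None,
            acute_events={},
            chronic_onsets={},
            weight_change=0.0,
        )
        base.update(kw)
        return EventHistory(**base)

    def test_single_acute_event_undiscounted(self):
        h = self._history(acute_events={"severe_hypo": [(1, 1)]})
        res = ins.daly_from_history(h, self._table(), discount=0.0)
        assert res.total == pytest.approx(0.10 / 365)
        assert res.total == pytest.approx(2.74e-4, rel=0.01)

    def test_discounting_scales_event_year(self):
        h = self._history(acute_events={"severe_hypo": [(1, 1)]})
        r0 = ins.daly_from_history(h, self._table(), discount=0.0)
        r3 = ins.daly_from_history(h, self._table(), discount=0.03)
        assert r3.total == pytest.approx(r0.total / 1.03)

    def test_chronic_state_five_years_undiscounted(self):
        h = self._history(chronic_onsets={"cvd": 1})
        res = ins.daly_from_history(h, self._table(), discount=0.0)
        assert res.total == pytest.approx(1.0)

    def test_weight_loss_is_negative_burden(self):
        h = self._history(weight_change=-3.4)
        res = ins.daly_from_history(h, self._table(), discount=0.0)
        assert res.total == pytest.approx(-3.4 * 0.002 * 5)
        assert res.by_cause["weight"] < 0

    def test_total_is_yld_plus_yll_and_causes_conserve(self):
        h = self._history(
            death_year=3, age_at_death=60.0, person_years=3.0,
            acute_events={"severe_hypo": [(2, 2)]}, chronic_onsets={"cvd": 1},
        )
        res = ins.daly_from_history(h, self._table(), life_expectancy=lambda a: 10.0)
        assert res.total == pytest.approx(res.yld + res.yll)
        assert sum(res.by_cause.values()) == pytest.approx(res.total)
        assert res.yll > 0


class TestCohortPerPersonConsistency:
    def test_vectorized_path_matches_reference_loop(self, params, overall, glp1):
        """Cohort DALY arrays equal the per-person plain-loop computation."""
        pop = ins.generate_population(overall, 60, seed=11)
        from insulinshift.outcomes import build_event_rates
        from insulinshift.therapies import modified_rates

        rates = modified_rates(build_event_rates(pop, overall, params), glp1)
        # stress the comparison: high rates so events, deaths and onsets occur
        rates.severe_hypo = 0.8
        rates.kidney_failure = 0.3
        rates.cvd = np.full(60, 0.4)
        rates.mortality_hr = 3.0
        coh = simulate_cohort(
            pop["age"].to_numpy(float),
            pop["sex"].eq("female").to_numpy(),
            pop["prior_cvd"].to_numpy(bool),
            rates, horizon=6, seed=13,
        )
        table = DisutilityTable.from_params(params)
        le = ins.make_life_expectancy(params)
        comps = dalys_from_cohort(coh, table, discount=0.03, life_expectancy=le)
        hists = cohort_to_histories(coh)
        assert len(hists) == 60
        for i, h in enumerate(hists):
            ref = ins.daly_from_history(h, table, discount=0.03, life_expectancy=le)
            vec_total = sum(comps[c][i] for c in comps)
            assert vec_total == pytest.approx(ref.total, abs=1e-12)
            for cause in ref.by_cause:
                assert comps[cause][i] == pytest.approx(ref.by_cause[cause], abs=1e-12)


class TestPopulationDaly:
    def test_empty_population_rejected(self, params, overall):
        with pytest.raises(ValueError):
            ins.population_daly(pd.DataFrame(columns=["age"]), None, overall, params)

    def test_discounted_less_than_undiscounted(self, params, overall, pooled_pop):
        pop = pooled_pop.head(800)
        r0 = ins.population_daly(pop, None, overall, params, seed=3, discount=0.0)
        r3 = ins.population_daly(pop, None, overall, params, seed=3, discount=0.03)
        assert 0 < r3.total < r0.total

    def test_prevalence_scaling_linear(self, params, overall, pooled_pop):
        pop = pooled_pop.head(400)
        half = ins.CountryProfile(
            **{**overall.__dict__, "insulin_use_prevalence": overall.insulin_use_prevalence / 2}
        )
        full = ins.population_daly(pop, None, overall, params, seed=9)
        scaled = ins.population_daly(pop, None, half, params, seed=9)
        assert scaled.total == pytest.approx(full.total / 2)

    def test_zero_prevalence_limit(self, params, overall, pooled_pop):
        tiny = ins.CountryProfile(
            **{**overall.__dict__, "insulin_use_prevalence": 1e-12}
        )
        res = ins.population_daly(pooled_pop.head(200), None, tiny, params, seed=1)
        assert res.total == pytest.approx(0.0, abs=1e-9)

    def test_doubling_disutilities_doubles_yld(self, params, overall, pooled_pop):
        pop = pooled_pop.head(500)
        draw = ins.point_draw(params).values
        doubled = {
            k: (2 * v if k.startswith("disutility.") and k.endswith(".value") else v)
            for k, v in draw.items()
        }
        doubled["disutility.weight_per_kg.value"] = 2 * draw["disutility.weight_per_kg.value"]
        a = ins.population_daly(pop, None, overall, params, values=draw, seed=4, discount=0.0)
        b = ins.population_daly(pop, None, overall, params, values=doubled, seed=4, discount=0.0)
        assert b.yld == pytest.approx(2 * a.yld, rel=1e-12)
        assert b.yll == pytest.approx(a.yll, rel=1e-12)

    def test_simulate_person_matches_cohort_of_one(self, params):
        person = {"age": 57.0, "sex": "female", "prior_cvd": False}
        rates = EventRateSet(severe_hypo=0.5, cvd=0.1, kidney_failure=0.05)
        h = ins.simulate_person(person, rates, horizon=5, seed=21)
        h2 = ins.simulate_person(person, rates, horizon=5, seed=21)
        assert h == h2  # deterministic
        assert h.person_years <= 5.0
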