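import logging

import numpy as np
import pandas as pd
import pytest

import insulinshift as ins
from insulinshift.population import SURVEY_COLUMNS


def _mini_survey(**overrides):
    base = {
        "person_id": "p1",
        "country": "BGD",
        "age": 55.0,
        "sex": "female",
        "weight_kg": 70.0,
        "hba1c_pct": 8.0,
        "fpg_mgdl": np.nan,
        "diabetes_dx": True,
        "on_dm_meds": True,
        "on_insulin": True,
        "smoker": False,
        "sbp_mmhg": 130.0,
        "on_bp_meds": False,
        "prior_cvd": False,
        "tchol_mmoll": 5.0,
        "survey_weight": 1.0,
    }
    base.update(overrides)
    return base


class TestGeneratePopulation:
    def test_marginal_calibration(self, overall):
        """At n=10,000 the sample marginals hit the profile targets within 2%."""
        pop = ins.generate_population(overall, 10_000, seed=1)
        assert np.median(pop["weight_kg"]) == pytest.approx(75.0, rel=0.02)
        assert np.median(pop["age"]) == pytest.approx(57.0, rel=0.02)
        assert pop["sex"].eq("female").mean() == pytest.approx(0.623, rel=0.02)
        # weight is right-skewed with positive support
        assert (pop["weight_kg"] > 0).all()
        assert pop["weight_kg"].mean() > pop["weight_kg"].median()

    def test_weight_median_within_one_percent(self, overall):
        pop = ins.generate_population(overall, 10_000, seed=1)
        assert abs(np.median(pop["weight_kg"]) - 75.0) / 75.0 < 0.01

    def test_single_record_satisfies_invariants(self, overall):
        pop = ins.generate_population(overall, 1, seed=0)
        assert len(pop) == 1
        row = pop.iloc[0]
        assert row["weight_kg"] > 0
        assert 18 <= row["age"] <= 100
        assert row["survey_weight"] >= 0
        assert row["on_insulin"]

    def test_deterministic_for_fixed_seed(self, overall):
        a = ins.generate_population(overall, 500, seed=42)
        b = ins.generate_population(overall, 500, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = ins.generate_population(overall, 500, seed=43)
        assert not a["weight_kg"].equals(c["weight_kg"])

    def test_rejects_nonpositive_n(self, overall):
        with pytest.raises(ValueError):
            ins.generate_population(overall, 0, seed=1)

    def test_ages_truncated_to_adult_range(self, profiles):
        pop = ins.generate_population(profiles["BGD"], 5000, seed=3)
        assert pop["age"].between(18, 100).all()


class TestSurveyIO:
    def test_round_trip_preserves_all_fields(self, overall, tmp_path):
        pop = ins.generate_population(overall, 200, seed=9)
        path = tmp_path / "survey.csv"
        ins.write_survey(pop, path)
        back = ins.load_survey(path)
        pd.testing.assert_frame_equal(back, pop, check_dtype=False)

    def test_well_formed_rows_loaded(self, tmp_path):
        df = pd.DataFrame([_mini_survey(person_id=f"p{i}") for i in range(3)])
        path = tmp_path / "s.csv"
        ins.write_survey(df, path)
        assert len(ins.load_survey(path)) == 3

    def test_missing_mandatory_column_rejected(self, tmp_path):
        df = pd.DataFrame([_mini_survey()]).drop(columns=["weight_kg"])
        path = tmp_path / "s.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="weight_kg"):
            ins.load_survey(path)

    def test_negative_weight_row_rejected_with_warning(self, tmp_path, caplog):
        df = pd.DataFrame(
            [_mini_survey(), _mini_survey(person_id="p2", weight_kg=-5.0)]
        )
        path = tmp_path / "s.csv"
        ins.write_survey(df, path)
        with caplog.at_level(logging.WARNING):
            out = ins.load_survey(path)
        assert len(out) == 1
        assert any("non-positive weight" in r.message for r in caplog.records)

    def test_unparseable_numeric_row_rejected(self, tmp_path, caplog):
        df = pd.DataFrame([_mini_survey(), _mini_survey(person_id="p2")])
        df["sbp_mmhg"] = df["sbp_mmhg"].astype(object)
        df.loc[1, "sbp_mmhg"] = "high"
        path = tmp_path / "s.csv"
        df_out = df.copy()
        for c in ["diabetes_dx", "on_dm_meds", "on_insulin", "smoker", "on_bp_meds", "prior_cvd"]:
            df_out[c] = df_out[c].astype(int)
        df_out.to_csv(path, index=False)
        with caplog.at_level(logging.WARNING):
            out = ins.load_survey(path)
        assert len(out) == 1

    def test_missing_optional_biomarkers_stay_missing(self, tmp_path):
        df = pd.DataFrame([_mini_survey(hba1c_pct=np.nan)])
        path = tmp_path / "s.csv"
        ins.write_survey(df, path)
        out = ins.load_survey(path)
        assert np.isnan(out.loc[0, "hba1c_pct"])
        assert np.isnan(out.loc[0, "fpg_mgdl"])


class TestInclusionCriteria:
    @pytest.mark.parametrize(
        "overrides,kept",
        [
            # current insulin use + glucose at the diagnostic threshold (inclusive)
            (dict(diabetes_dx=False, hba1c_pct=np.nan, fpg_mgdl=126.0), True),
            (dict(diabetes_dx=False, hba1c_pct=np.nan, fpg_mgdl=125.9), False),
            # HbA1c threshold is inclusive too
            (dict(diabetes_dx=False, hba1c_pct=6.5, fpg_mgdl=np.nan), True),
            (dict(diabetes_dx=False, hba1c_pct=6.4, fpg_mgdl=np.nan), False),
            # not on insulin: excluded regardless of diagnosis
            (dict(on_insulin=False, diabetes_dx=True), False),
            # diagnosis alone suffices
            (dict(diabetes_dx=True, hba1c_pct=np.nan, fpg_mgdl=np.nan), True),
            # all three criteria missing/failed: excluded, never imputed
            (dict(diabetes_dx=False, hba1c_pct=np.nan, fpg_mgdl=np.nan), False),
        ],
    )
    def test_inclusion_rule(self, overrides, kept):
        df = pd.DataFrame([_mini_survey(**overrides)])
        out = ins.filter_insulin_users(df)
        assert len(out) == (1 if kept else 0)

    def test_idempotent(self, overall):
        pop = ins.generate_population(overall, 300, seed=2)
        once = ins.filter_insulin_users(pop)
        twice = ins.filter_insulin_users(once)
        pd.testing.assert_frame_equal(once, twice)


class TestCountryReporting:
    def test_packaged_profiles_give_fourteen_countries(self, profiles):
        assert len(ins.country_report_mask(profiles, min_n=100)) == 14

    def test_min_n_zero_gives_all(self, profiles):
        assert len(ins.country_report_mask(profiles, min_n=0)) == len(profiles)

    def test_small_surveys_masked_out(self, profiles):
        small = {
            c: ins.CountryProfile(**{**p.__dict__, "n_insulin_users": 99})
            for c, p in profiles.items()
        }
        assert ins.country_report_mask(small) == []

    def test_pooled_weights_proportional_to_population(self, profiles):
        pops = pd.concat(
            [
                ins.generate_population(profiles["BGD"], 50, seed=1),
                ins.generate_population(profiles["TON"], 200, seed=2),
            ],
            ignore_index=True,
        )
        w = ins.pooled_survey_weights(pops, profiles)
        by_country = w.groupby(pops["country"]).sum()
        # Bangladesh's total weight share reflects its (much larger) population
        # despite having fewer surveyed records
        ratio = by_country["BGD"] / by_country["TON"]
        assert ratio == pytest.approx(165_000_000 / 106_000, rel=1e-9)


class TestProfileValidation:
    def test_disordered_iqr_rejected(self, profiles):
        good = profiles["BGD"].__dict__
        with pytest.raises(ValueError):
            ins.CountryProfile(**{**good, "weight_iqr_lo": 80.0})

    def test_prevalence_bounds(self, profiles):
        good = profiles["BGD"].__dict__
        with pytest.raises(ValueError):
            ins.CountryProfile(**{**good, "insulin_use_prevalence": 0.0})
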