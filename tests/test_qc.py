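"""Data-editing rules: threshold examples, pairing logic, and invariances."""

import numpy as np
import pandas as pd
import pytest

from sheepmethane import qc


def make_records(ch4, cohort="growing", **overrides):
    n = len(ch4)
    base = {
        "record_id": [f"R{i}" for i in range(n)],
        "animal_id": [f"A{i}" for i in range(n)],
        "flock_id": ["F1"] * n,
        "measurement_date": [pd.Timestamp("2022-05-01")] * n,
        "pac_run": [1] * n,
        "ch4_g_d": ch4,
        "co2_g_d": [700.0] * n,
        "body_weight_kg": [50.0 if cohort == "growing" else 70.0] * n,
        "age_days": [200 if cohort == "growing" else 900] * n,
        "cohort": [cohort] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestContemporaryGroups:
    def test_single_run_single_group(self):
        rec, _ = qc.assign_contemporary_groups(make_records([10.0] * 12))
        assert rec["cg_key"].nunique() == 1
        assert (rec["cg_size"] == 12).all()

    def test_runs_split_groups(self):
        df = make_records([10.0] * 10, pac_run=[1] * 5 + [2] * 5)
        rec, _ = qc.assign_contemporary_groups(df)
        assert rec["cg_key"].nunique() == 2

    def test_small_group_removed_downstream(self):
        df = make_records([10.0] * 9, pac_run=[1] * 5 + [2] * 4)
        rec, _ = qc.assign_contemporary_groups(df)
        kept, log = qc.filter_small_groups(rec)
        assert len(kept) == 5
        assert set(log["rule"]) == {"cg_below_min_size"}

    def test_missing_key_rejected_with_reason(self):
        df = make_records([10.0] * 6)
        df.loc[2, "pac_run"] = np.nan
        rec, log = qc.assign_contemporary_groups(df)
        assert len(rec) == 5
        assert log.iloc[0]["rule"] == "missing_group_key"

    def test_sizes_count_distinct_animals(self):
        df = make_records([10.0] * 6, animal_id=["A1", "A1", "A2", "A3", "A4", "A5"])
        rec, _ = qc.assign_contemporary_groups(df)
        assert (rec["cg_size"] == 5).all()


class TestEmissionFilters:
    def test_low_methane_removed(self):
        df = make_records([3.9, 10.0, 11.0, 12.0, 13.0])
        kept, log = qc.apply_emission_filters(df)
        assert "R0" not in set(kept["record_id"])
        assert log.iloc[0]["rule"] == "ch4_below_4" and log.iloc[0]["value"] == 3.9

    def test_toy_cohort_all_retained(self):
        kept, log = qc.apply_emission_filters(make_records([5.0, 6.0, 7.0, 8.0, 9.0]))
        assert len(kept) == 5 and len(log) == 0

    def test_three_sd_screen(self):
        ch4 = [10.0] * 30 + [10.4] * 30 + [60.0]
        kept, log = qc.apply_emission_filters(make_records(ch4))
        assert len(kept) == 60
        assert (log["rule"] == "ch4_3sd").sum() == 1

    def test_high_co2_kept_for_methane_flagged_for_co2(self):
        df = make_records([10.0] * 5, co2_g_d=[700.0, 2600.0, 700.0, 700.0, 700.0])
        kept, log = qc.apply_emission_filters(df)
        assert len(kept) == 5
        assert not kept.loc[kept["record_id"] == "R1", "co2_valid"].item()
        assert (log["rule"] == "co2_above_2500").sum() == 1

    def test_empty_input(self):
        kept, log = qc.apply_emission_filters(make_records([]))
        assert len(kept) == 0 and len(log) == 0


class TestWeightAndWindowFilters:
    def test_growing_weight_window(self):
        df = make_records([10.0] * 3, body_weight_kg=[24.5, 50.0, 80.5])
        kept, log = qc.apply_weight_and_window_filters(df)
        assert list(kept["record_id"]) == ["R1"]
        assert (log["rule"] == "weight_window").sum() == 2

    def test_ewe_weight_window(self):
        df = make_records([20.0] * 2, cohort="ewe", body_weight_kg=[54.0, 70.0])
        kept, _ = qc.apply_weight_and_window_filters(df)
        assert list(kept["record_id"]) == ["R1"]

    def test_carcass_window_and_closest_pairing(self):
        # two methane records 10 d and 25 d before slaughter -> the 10-d one pairs
        df = make_records([10.0, 11.0], animal_id=["A1", "A1"],
                          measurement_date=[pd.Timestamp("2022-05-01"),
                                            pd.Timestamp("2022-05-16")])
        carcass = pd.DataFrame({
            "animal_id": ["A1"],
            "slaughter_date": [pd.Timestamp("2022-05-26")],
            "carcass_weight_kg": [20.0],
            "age_at_slaughter_d": [300],
        })
        kept, _ = qc.apply_weight_and_window_filters(df, carcass=carcass)
        paired = kept.dropna(subset=["carcass_weight_kg"])
        assert list(paired["record_id"]) == ["R1"]

    def test_overweight_carcass_excluded(self):
        df = make_records([10.0])
        carcass = pd.DataFrame({
            "animal_id": ["A0"], "slaughter_date": [pd.Timestamp("2022-05-10")],
            "carcass_weight_kg": [26.5], "age_at_slaughter_d": [300],
        })
        kept, log = qc.apply_weight_and_window_filters(df, carcass=carcass)
        assert kept["carcass_weight_kg"].isna().all()
        assert (log["rule"] == "carcass_weight_window").sum() == 1

    def test_dmi_window_and_sd_screen(self):
        df = make_records([10.0] * 3, animal_id=["A1", "A2", "A3"])
        dmi = pd.DataFrame({
            "animal_id": ["A1", "A2", "A3", "A3"],
            "date": [pd.Timestamp("2022-05-10"),   # within 30 d
                     pd.Timestamp("2022-07-01"),   # outside 30 d
                     pd.Timestamp("2022-05-05"),
                     pd.Timestamp("2022-05-02")],
            "dmi_kg_d": [1.5, 1.6, 1.4, 1.45],
        })
        kept, _ = qc.apply_weight_and_window_filters(df, dmi=dmi)
        k = kept.set_index("animal_id")["dmi_kg_d"]
        assert k["A1"] == 1.5
        assert np.isnan(k["A2"])
        assert k["A3"] == 1.45  # nearest-dated of the two in-window records

    def test_unlinkable_production_row_logged(self):
        df = make_records([10.0])
        dmi = pd.DataFrame({"animal_id": ["ZZZ"],
                            "date": [pd.Timestamp("2022-05-01")],
                            "dmi_kg_d": [1.5]})
        _, log = qc.apply_weight_and_window_filters(df, dmi=dmi)
        assert (log["rule"] == "unlinkable_animal").sum() == 1


class TestCohortEligibility:
    def test_age_windows(self):
        df = make_records([10.0] * 2, age_days=[100, 200])
        kept, log = qc.filter_cohort_eligibility(df)
        assert list(kept["record_id"]) == ["R1"]
        df2 = make_records([20.0] * 2, cohort="ewe", age_days=[370, 4000])
        kept2, _ = qc.filter_cohort_eligibility(df2)
        assert len(kept2) == 0


class TestAdgFilter:
    def test_band_enforced(self):
        cov = pd.DataFrame({"record_id": ["R0", "R1", "R2"],
                            "adg_g_d": [140.0, 250.0, 360.0]})
        out, log = qc.apply_adg_filter(cov)
        assert out["adg_g_d"].notna().tolist() == [False, True, False]
        assert set(log["rule"]) == {"adg_window"}


class TestInvariances:
    def _bundle(self):
        from sheepmethane import default_config, simulate_flocks
        return simulate_flocks(default_config("growing", seed=6, n_animals=250))

    def test_filters_are_subsetting_and_value_preserving(self):
        b = self._bundle()
        rec, _ = qc.assign_contemporary_groups(b["emissions"])
        kept, _ = qc.apply_emission_filters(rec, cohort="growing")
        assert set(kept["record_id"]) <= set(b["emissions"]["record_id"])
        orig = b["emissions"].set_index("record_id")["ch4_g_d"]
        assert np.allclose(kept.set_index("record_id")["ch4_g_d"],
                           orig.loc[kept["record_id"]])

    def test_row_order_does_not_change_retained_set(self):
        b = self._bundle()
        rec, _ = qc.assign_contemporary_groups(b["emissions"])
        kept1, _ = qc.apply_emission_filters(rec, cohort="growing")
        shuffled = rec.sample(frac=1.0, random_state=99)
        kept2, _ = qc.apply_emission_filters(shuffled, cohort="growing")
        assert set(kept1["record_id"]) == set(kept2["record_id"])

    def test_retained_plus_removed_equals_input(self):
        b = self._bundle()
        rec, _ = qc.assign_contemporary_groups(b["emissions"])
        kept, log = qc.apply_emission_filters(rec, cohort="growing")
        removed = log[log["rule"] != "co2_above_2500"]
        assert len(kept) + len(removed) == len(rec)
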