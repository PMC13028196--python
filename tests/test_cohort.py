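import datetime as dt

import pandas as pd
import pytest

from conftest import make_dispensings
from gldtraj import cohort
from gldtraj.config import CohortConfig


def patient(pid, birth_year=1950, reg_start="2011-01-01", reg_end="2022-12-31",
            sex="male"):
    return {
        "patient_id": pid,
        "birth_year": birth_year,
        "sex": sex,
        "registration_start": pd.Timestamp(reg_start),
        "registration_end": pd.Timestamp(reg_end),
    }


def monthly(pid, code, start, end):
    return [(pid, code, d) for d in pd.date_range(start, end, freq="30D")]


class TestFindIndexDate:
    def test_earliest_in_window(self):
        disp = make_dispensings([
            ("P1", "A10BA02", "2016-09-01"), ("P1", "A10BA02", "2017-01-10"),
        ])
        assert cohort.find_index_date("P1", disp) == dt.date(2016, 9, 1)

    def test_only_before_window_absent(self):
        disp = make_dispensings([("P1", "A10BA02", "2016-06-30")])
        assert cohort.find_index_date("P1", disp) is None

    def test_window_start_boundary_inclusive(self):
        disp = make_dispensings([("P1", "A10BA02", "2016-07-01")])
        assert cohort.find_index_date("P1", disp) == dt.date(2016, 7, 1)

    def test_non_gld_ignored(self):
        disp = make_dispensings([("P1", "C07AB02", "2016-09-01")])
        assert cohort.find_index_date("P1", disp) is None


class TestSelectCohort:
    def full_history(self, pid, code="A10BA02"):
        return monthly(pid, code, "2011-02-01", "2022-10-01")

    def test_age_below_35_excluded(self):
        patients = pd.DataFrame([patient("P1", birth_year=1982)])
        disp = make_dispensings(self.full_history("P1"))
        members, flow = cohort.select_cohort(patients, disp)
        assert members.empty
        assert flow.set_index("step").loc["age_below_minimum", "n_excluded"] == 1

    def test_spot_user_excluded(self):
        patients = pd.DataFrame([patient("P1")])
        disp = make_dispensings([("P1", "A10BA02", "2016-09-01")])
        members, flow = cohort.select_cohort(patients, disp)
        assert members.empty
        assert flow.set_index("step").loc["spot_user", "n_excluded"] == 1

    def test_insulin_only_preindex_excluded(self):
        patients = pd.DataFrame([patient("P1")])
        disp = make_dispensings(monthly("P1", "A10AE04", "2011-02-01", "2022-10-01"))
        members, flow = cohort.select_cohort(patients, disp)
        assert members.empty
        assert flow.set_index("step").loc[
            "insulin_only_preindex", "n_excluded"] == 1

    def test_mixed_preindex_retained(self):
        rows = monthly("P1", "A10AE04", "2011-02-01", "2022-10-01")
        rows += monthly("P1", "A10BA02", "2013-01-01", "2014-01-01")
        patients = pd.DataFrame([patient("P1")])
        members, _ = cohort.select_cohort(patients, make_dispensings(rows))
        assert len(members) == 1

    def test_no_preindex_a10_retained(self):
        rows = monthly("P1", "A10BA02", "2016-08-01", "2022-10-01")
        patients = pd.DataFrame([patient("P1")])
        members, _ = cohort.select_cohort(patients, make_dispensings(rows))
        assert len(members) == 1

    def test_short_registration_excluded(self):
        patients = pd.DataFrame([patient("P1", reg_start="2013-01-01")])
        disp = make_dispensings(self.full_history("P1"))
        members, flow = cohort.select_cohort(patients, disp)
        assert members.empty
        assert flow.set_index("step").loc[
            "incomplete_registration", "n_excluded"] == 1

    def test_retained_member_fields(self):
        patients = pd.DataFrame([patient("P1", birth_year=1950, sex="female")])
        disp = make_dispensings(self.full_history("P1"))
        members, _ = cohort.select_cohort(patients, disp)
        m = members.iloc[0]
        assert m["index_date"] == dt.date(2016, 7, 4)
        assert m["age_at_index"] == 66
        assert m["age_band"] == "65-74"

    def test_empty_input(self):
        members, flow = cohort.select_cohort(
            pd.DataFrame(columns=["patient_id", "birth_year", "sex",
                                  "registration_start", "registration_end"]),
            make_dispensings([]),
        )
        assert members.empty
        assert (flow["n_excluded"] == 0).all()

    def test_dummy_predicate_hook(self):
        patients = pd.DataFrame([patient("P1"), patient("DUMMY1")])
        rows = self.full_history("P1") + self.full_history("DUMMY1")
        cfg = CohortConfig(dummy_id_predicate=lambda p: p.startswith("DUMMY"))
        members, flow = cohort.select_cohort(patients, make_dispensings(rows), cfg)
        assert list(members["patient_id"]) == ["P1"]
        assert flow.set_index("step").loc["dummy_patient", "n_excluded"] == 1


class TestCohortProperties:
    def test_idempotent_on_selected(self, small_population):
        _, patients, disp = small_population
        members, _ = cohort.select_cohort(patients, disp)
        again, flow = cohort.select_cohort(
            patients[patients["patient_id"].isin(members["patient_id"])], disp
        )
        assert len(again) == len(members)
        steps = flow.set_index("step")["n_excluded"]
        assert steps.drop("input_patients").sum() == 0

    def test_tally_conservation(self, small_population):
        _, patients, disp = small_population
        members, flow = cohort.select_cohort(patients, disp)
        excluded = flow["n_excluded"].sum()
        assert len(patients) - excluded == len(members)

    def test_retained_members_pass_each_rule(self, small_population):
        _, patients, disp = small_population
        members, _ = cohort.select_cohort(patients, disp)
        cfg = CohortConfig()
        disp2 = disp.copy()
        disp2["dispense_date"] = pd.to_datetime(disp2["dispense_date"])
        a10 = disp2[disp2["atc_code"].str.startswith("A10")]
        pat = patients.set_index("patient_id")
        sample = members.sample(n=min(40, len(members)), random_state=0)
        for _, m in sample.iterrows():
            assert m["age_at_index"] >= cfg.min_age_at_index
            idx = pd.Timestamp(m["index_date"])
            sub = a10[a10["patient_id"] == m["patient_id"]]
            win = sub[(sub["dispense_date"] >= idx)
                      & (sub["dispense_date"] <= idx + pd.Timedelta(days=365))]
            assert len(win) >= cfg.min_a10_dispensings
            reg_s = pd.Timestamp(pat.loc[m["patient_id"], "registration_start"])
            reg_e = pd.Timestamp(pat.loc[m["patient_id"], "registration_end"])
            assert reg_s <= idx - pd.DateOffset(years=5)
            assert reg_e >= idx + pd.DateOffset(years=5)
            pre = sub[(sub["dispense_date"] < idx)
                      & (sub["dispense_date"] >= idx - pd.DateOffset(years=5))]
            if len(pre):
                assert not pre["atc_code"].str.startswith("A10A").all()
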