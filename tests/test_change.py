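import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_dispensings, make_member
from gldtraj import change, regimen
from oracle_change import oracle_classify

D0 = dt.date(2017, 3, 1)

CODE_OF = {"met": "A10BA02", "su": "A10BB01", "ins": "A10AB01", "dpp4": "A10BH01"}


def s(codes: set[str], date=D0):
    return regimen.snapshot_from_codes("P1", date, {CODE_OF[c] for c in codes})


class TestClassifyChange:
    @pytest.mark.parametrize(
        "prev, nxt, state, subtype",
        [
            ({"met"}, {"met", "su"}, "IN", "Mono—Addition of SU"),
            ({"met", "su", "ins"}, {"met", "su"}, "DI",
             "Comb—Discontinuation of insulin"),
            ({"met"}, {"met", "dpp4"}, "NC", "none"),
            ({"su"}, {"met"}, "DI", "Mono—Switching from SU to non-SU"),
            ({"ins"}, {"su"}, "DI", "Mono—Switching from insulin to SU"),
            ({"met", "su"}, {"met", "su", "ins"}, "IN",
             "Comb—Addition of insulin"),
            ({"met", "su"}, {"met", "ins"}, "IN",
             "Comb—Switching from SU to insulin"),
            ({"su"}, set(), "DI", "Mono—Discontinuation of SU"),
            ({"met"}, set(), "NC", "none"),
            (set(), {"su"}, "IN", "Mono—Addition of SU"),
        ],
    )
    def test_rules(self, prev, nxt, state, subtype):
        assert change.classify_change(s(prev), s(nxt)) == (state, subtype)

    def test_exhaustive_agreement_with_oracle(self):
        drugs = list(CODE_OF)
        subsets = [
            set(c) for r in range(5) for c in itertools.combinations(drugs, r)
        ]
        for prev, nxt in itertools.product(subsets, subsets):
            got = change.classify_change(s(prev), s(nxt))
            assert got == oracle_classify(prev, nxt), (prev, nxt)

    def test_reversal_antisymmetry_for_add_drop(self):
        """Adding a hypo class reversed is discontinuing that class."""
        for base in ({"met"}, {"met", "dpp4"}):
            for drug, name in (("su", "SU"), ("ins", "insulin")):
                a, b = s(base), s(base | {drug})
                st_in, sub_in = change.classify_change(a, b)
                st_di, sub_di = change.classify_change(b, a)
                assert st_in == "IN" and st_di == "DI"
                assert sub_in.endswith(f"Addition of {name}")
                assert sub_di.endswith(f"Discontinuation of {name}")

    @given(
        prev=st.sets(st.sampled_from(list(CODE_OF))),
        nxt=st.sets(st.sampled_from(list(CODE_OF))),
    )
    def test_total_function_with_consistent_subtype(self, prev, nxt):
        state, subtype = change.classify_change(s(prev), s(nxt))
        if state == "NC":
            assert subtype == "none"
        elif state == "IN":
            assert subtype in change.INTENSIFICATION_SUBTYPES
        else:
            assert subtype in change.DEINTENSIFICATION_SUBTYPES


class TestAnnualStates:
    def test_identical_snapshots_all_nc(self):
        rows = [("P1", "A10BA02", d)
                for d in pd.date_range("2016-08-15", "2021-10-01", freq="30D")]
        member = make_member(index_date="2016-09-01")
        events = change.annual_states(member, make_dispensings(rows))
        assert [e.state for e in events] == ["NC"] * 5

    def test_single_addition_in_year_two(self):
        rows = [("P1", "A10BA02", d)
                for d in pd.date_range("2016-08-15", "2021-10-01", freq="30D")]
        rows += [("P1", "A10BB01", d)
                 for d in pd.date_range("2018-03-01", "2021-10-01", freq="30D")]
        member = make_member(index_date="2016-09-01")
        events = change.annual_states(member, make_dispensings(rows))
        assert [e.state for e in events] == ["NC", "IN", "NC", "NC", "NC"]
        assert events[1].subtype == "Mono—Addition of SU"


def events_frame(sequences):
    rows = []
    for i, seq in enumerate(sequences):
        for k, state in enumerate(seq, start=1):
            rows.append({"patient_id": f"P{i}", "interval_index": k,
                         "state": state, "subtype": "none"})
    return pd.DataFrame(rows)


class TestTransitionTables:
    def test_hand_counted_toy(self):
        ev = events_frame([
            ("NC", "NC", "NC", "NC", "NC"),
            ("IN", "NC", "NC", "NC", "NC"),
            ("DI", "IN", "NC", "NC", "NC"),
        ])
        tables = change.transition_tables(ev)
        assert list(tables[0].subtotals) == [1, 1, 1]
        t2 = tables[1].counts
        assert t2.loc["NC", "NC"] == 1
        assert t2.loc["IN", "NC"] == 1
        assert t2.loc["DI", "IN"] == 1

    def test_conservation_across_periods(self, large_run):
        tables = change.transition_tables(large_run["events"])
        n = large_run["members"].shape[0]
        for k, t in enumerate(tables):
            assert int(t.counts.to_numpy().sum()) == n
            assert (t.subtotals == t.counts.sum(axis=0)).all()
            if k + 1 < len(tables):
                nxt = tables[k + 1]
                assert (nxt.counts.sum(axis=1).to_numpy()
                        == t.subtotals.to_numpy()).all()

    def test_wrong_event_count_raises(self):
        ev = events_frame([("NC",) * 5])
        ev = pd.concat([ev, pd.DataFrame([{
            "patient_id": "PX", "interval_index": 1,
            "state": "NC", "subtype": "none"}])], ignore_index=True)
        with pytest.raises(ValueError, match="PX"):
            change.transition_tables(ev)


class TestPooledSubtypes:
    def test_single_event_is_hundred_percent(self):
        ev = pd.DataFrame([
            {"patient_id": "P0", "interval_index": 1, "state": "IN",
             "subtype": "Mono—Addition of SU"},
        ])
        out = change.pooled_subtypes(ev)
        assert out.loc[0, "pct_within_category"] == 100.0

    def test_within_category_percentages_sum_to_100(self, large_run):
        out = change.pooled_subtypes(large_run["events"])
        for _, grp in out.groupby("category"):
            assert abs(grp["pct_within_category"].sum() - 100.0) < 0.5


class TestStratifiedRates:
    def test_single_stratum_equals_unstratified(self):
        ev = events_frame([("NC",) * 5, ("IN", "NC", "NC", "NC", "NC")])
        members = pd.DataFrame([
            {"patient_id": "P0", "age_band": "50-64", "sex": "male"},
            {"patient_id": "P1", "age_band": "50-64", "sex": "male"},
        ])
        out = change.stratified_rates(ev, members)
        first = out[out["interval_index"] == 1].iloc[0]
        assert first["pct_NC"] == 50.0 and first["pct_IN"] == 50.0

    def test_strata_counts_sum_to_interval_totals(self, large_run):
        out = change.stratified_rates(large_run["events"], large_run["members"])
        tables = change.transition_tables(large_run["events"])
        for t in tables:
            sub = out[out["interval_index"] == t.interval_index]
            for state in change.STATES:
                assert sub[f"n_{state}"].sum() == t.subtotals[state]

    def test_rates_sum_to_100_within_stratum(self, large_run):
        out = change.stratified_rates(large_run["events"], large_run["members"])
        totals = out[[f"pct_{s}" for s in change.STATES]].sum(axis=1)
        assert ((totals - 100.0).abs() < 0.5).all()


class TestNetOutcome:
    def test_transient_change_nets_to_no_change(self):
        rows = [("P1", "A10BA02", d)
                for d in pd.date_range("2016-08-15", "2021-10-01", freq="30D")]
        rows += [("P1", "A10BB01", d)
                 for d in pd.date_range("2017-03-01", "2019-02-01", freq="30D")]
        member = make_member(index_date="2016-09-01")
        assert change.net_five_year_outcome(member, make_dispensings(rows)) == "NC"

    def test_su_present_at_index_absent_at_year5(self):
        rows = [("P1", "A10BA02", d)
                for d in pd.date_range("2016-08-15", "2021-10-01", freq="30D")]
        rows += [("P1", "A10BB01", d)
                 for d in pd.date_range("2016-08-15", "2018-02-01", freq="30D")]
        member = make_member(index_date="2016-09-01")
        assert change.net_five_year_outcome(member, make_dispensings(rows)) == "DI"


def test_sex_differential_hazards_recovered():
    """A configured female de-intensification excess shows up in the
    stratified crude rates."""
    from gldtraj import cohort as cohort_mod
    from gldtraj import synthetic
    from gldtraj.config import SimulationConfig

    cfg = SimulationConfig(
        n_patients=6000, seed=5,
        rate_modifiers={"IN": {}, "DI": {"female": 2.5}},
        frac_short_registration=0.0, frac_spot_users=0.0,
        frac_insulin_only_preindex=0.0,
    )
    patients, disp = synthetic.generate_population(cfg)
    members, _ = cohort_mod.select_cohort(patients, disp)
    events, _, _ = change.cohort_events(members, disp)
    j = events.merge(members[["patient_id", "sex"]], on="patient_id")
    rate = j.groupby("sex")["state"].apply(lambda x: (x == "DI").mean())
    assert rate["female"] > rate["male"]
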