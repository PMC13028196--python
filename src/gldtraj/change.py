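"""Annual treatment-change classification and its tabulations.

Each consecutive pair of anniversary snapshots is classified as

* **NC** (no change): no change in hypoglycemia-associated classes
  (sulfonylurea, insulin); changes confined to "other" glucose-lowering
  drugs count as NC;
* **IN** (intensification): a hypoglycemia-associated class is added, or
  therapy is switched towards one (other→SU, other/SU→insulin);
* **DI** (de-intensification): a hypoglycemia-associated class is
  discontinued, or therapy is switched away from one (insulin→SU/other,
  SU→other).

Subtypes follow the systematic "``{Mono|Comb}—{action}``" naming, where
the prefix reflects the therapy type (monotherapy or combination) at the
start of the interval.  Ties between simultaneous insulin and SU moves
are resolved by insulin dominance: the insulin-level move names the
interval.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import regimen
from .regimen import RegimenSnapshot

NC, IN, DI = "NC", "IN", "DI"
STATES = (NC, IN, DI)

# Subtype vocabulary (systematic; the 19 labels printed in the source
# tables are the common subset of these).
_ACTIONS_IN = (
    "Addition of SU",
    "Addition of insulin",
    "Switching from non-SU to SU",
    "Switching from non-SU to insulin",
    "Switching from SU to insulin",
)
_ACTIONS_DI = (
    "Discontinuation of SU",
    "Discontinuation of insulin",
    "Switching from SU to non-SU",
    "Switching from insulin to non-SU",
    "Switching from insulin to SU",
)
INTENSIFICATION_SUBTYPES = tuple(
    f"{p}—{a}" for a in _ACTIONS_IN for p in ("Mono", "Comb")
)
DEINTENSIFICATION_SUBTYPES = tuple(
    f"{p}—{a}" for a in _ACTIONS_DI for p in ("Mono", "Comb")
)


@dataclass(frozen=True)
class ChangeEvent:
    patient_id: str
    interval_index: int  # 1..5
    state: str  # NC / IN / DI
    subtype: str  # systematic label, or "none" for NC
    begin_label: str
    end_label: str


def classify_change(prev: RegimenSnapshot, next: RegimenSnapshot) -> tuple[str, str]:
    """Classify one patient-interval from its two endpoint snapshots.

    Returns ``(state, subtype)`` with subtype ``"none"`` for NC.
    """
    ins_add = next.has_insulin and not prev.has_insulin
    ins_drop = prev.has_insulin and not next.has_insulin
    su_add = next.has_su and not prev.has_su
    su_drop = prev.has_su and not next.has_su
    other_dropped = bool(prev.other_subgroups - next.other_subgroups)
    other_new = bool(next.other_subgroups - prev.other_subgroups)

    if not (ins_add or ins_drop or su_add or su_drop):
        return NC, "none"

    prefix = "Comb" if prev.therapy_type == "combination" else "Mono"

    if (ins_add or su_add) and not (ins_drop or su_drop):
        # pure intensification; insulin dominates when both are added
        if ins_add:
            action = (
                "Switching from non-SU to insulin" if other_dropped
                else "Addition of insulin"
            )
        else:
            action = (
                "Switching from non-SU to SU" if other_dropped
                else "Addition of SU"
            )
        return IN, f"{prefix}—{action}"

    if (ins_drop or su_drop) and not (ins_add or su_add):
        # pure de-intensification; insulin dominates when both are dropped
        target = "insulin" if ins_drop else "SU"
        if other_new:
            action = f"Switching from {target} to non-SU"
        else:
            action = f"Discontinuation of {target}"
        return DI, f"{prefix}—{action}"

    # mixed hypo-class deltas: the insulin move decides the direction
    if ins_add:  # SU dropped, insulin added
        return IN, f"{prefix}—Switching from SU to insulin"
    return DI, f"{prefix}—Switching from insulin to SU"


def annual_states(
    member,
    dispensings: pd.DataFrame,
    window_days: int = regimen.DEFAULT_WINDOW_DAYS,
    n_years: int = 5,
) -> list[ChangeEvent]:
    """The five interval states for one cohort member (net annual change).

    States derive solely from consecutive anniversary snapshots, so only
    changes sustained to the anniversary are seen.
    """
    dates = regimen.anniversary_dates(member.index_date, n_years)
    snaps = [
        regimen.snapshot(dispensings, member.patient_id, d, window_days)
        for d in dates
    ]
    return events_from_snapshots(member.patient_id, snaps)


def events_from_snapshots(
    patient_id: str, snaps: list[RegimenSnapshot]
) -> list[ChangeEvent]:
    events = []
    for k in range(1, len(snaps)):
        state, subtype = classify_change(snaps[k - 1], snaps[k])
        events.append(
            ChangeEvent(
                patient_id=patient_id,
                interval_index=k,
                state=state,
                subtype=subtype,
                begin_label=regimen.classify_regimen(snaps[k - 1]).label,
                end_label=regimen.classify_regimen(snaps[k]).label,
            )
        )
    return events


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "interval_index": e.interval_index,
                "state": e.state,
                "subtype": e.subtype,
            }
            for e in events
        ]
    )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, as in the printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TransitionTable:
    interval_index: int
    counts: pd.DataFrame  # begin-state rows × end-state cols (period 1: 1 row "ALL")
    subtotals: pd.Series  # end-state counts
    subtotal_pct: pd.Series  # one-decimal percentages of the cohort


def transition_tables(events: pd.DataFrame) -> list[TransitionTable]:
    """Annual transition matrices in the shape of the printed Table 2.

    ``events`` is the long frame (patient_id, interval_index, state).
    Every patient must contribute exactly one state per interval.
    """
    ev = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    n_int = int(ev["interval_index"].max())
    per_patient = ev.groupby("patient_id")["interval_index"].count()
    bad = per_patient[per_patient != n_int]
    if len(bad):
        raise ValueError(
            f"patients with != {n_int} interval states: {list(bad.index[:5])}"
        )
    n = per_patient.size
    wide = ev.pivot(index="patient_id", columns="interval_index", values="state")
    out = []
    for k in range(1, n_int + 1):
        end = pd.Categorical(wide[k], categories=STATES)
        if k == 1:
            counts = pd.crosstab(
                pd.Series(["ALL"] * n, index=wide.index, name="begin"),
                end, dropna=False,
            )
        else:
            begin = pd.Categorical(wide[k - 1], categories=STATES)
            counts = pd.crosstab(begin, end, dropna=False)
            counts.index = list(STATES)
        counts.columns = list(STATES)
        subtot = counts.sum(axis=0)
        pct = subtot.map(lambda c: round_half_up(100.0 * c / n, 1))
        out.append(TransitionTable(k, counts, subtot, pct))
    return out


def transition_tables_frame(tables: list[TransitionTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        for b in t.counts.index:
            rows.append(
                {"interval_index": t.interval_index, "begin_state": b}
                | {f"end_{s}": int(t.counts.loc[b, s]) for s in STATES}
            )
        rows.append(
            {"interval_index": t.interval_index, "begin_state": "subtotal"}
            | {f"end_{s}": int(t.subtotals[s]) for s in STATES}
        )
        rows.append(
            {"interval_index": t.interval_index, "begin_state": "subtotal_pct"}
            | {f"end_{s}": t.subtotal_pct[s] for s in STATES}
        )
    return pd.DataFrame(rows)


def pooled_subtypes(events: pd.DataFrame) -> pd.DataFrame:
    """Subtype frequencies pooled over all person-intervals, ranked within
    category, with within-category percentages (one decimal)."""
    ev = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    ev = ev[ev["state"] != NC]
    rows = []
    for cat, name in ((IN, "Intensification"), (DI, "De-intensification")):
        sub = ev[ev["state"] == cat]["subtype"].value_counts()
        total = int(sub.sum())
        for rank, (label, count) in enumerate(sub.items(), start=1):
            rows.append(
                {
                    "category": name,
                    "rank": rank,
                    "subtype": label,
                    "count": int(count),
                    "pct_within_category": round_half_up(100.0 * count / total, 1)
                    if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


AGE_BANDS = ("35-49", "50-64", "65-74", ">=75")


def age_band(age: int) -> str:
    if age < 35:
        raise ValueError("cohort members are 35 or older")
    if age <= 49:
        return "35-49"
    if age <= 64:
        return "50-64"
    if age <= 74:
        return "65-74"
    return ">=75"


def stratified_rates(events: pd.DataFrame, members: pd.DataFrame) -> pd.DataFrame:
    """Crude per-interval NC/IN/DI rates by age band and sex."""
    ev = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    m = members[["patient_id", "age_band", "sex"]]
    j = ev.merge(m, on="patient_id", how="left")
    rows = []
    for (k, band, sex), grp in j.groupby(
        ["interval_index", "age_band", "sex"], observed=True
    ):
        n = len(grp)
        counts = grp["state"].value_counts()
        row = {"interval_index": k, "age_band": band, "sex": sex, "n": n}
        for s in STATES:
            c = int(counts.get(s, 0))
            row[f"n_{s}"] = c
            row[f"pct_{s}"] = round_half_up(100.0 * c / n, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def net_five_year_outcome(
    member,
    dispensings: pd.DataFrame,
    window_days: int = regimen.DEFAULT_WINDOW_DAYS,
) -> str:
    """Net 5-year state: index snapshot compared directly with Year 5."""
    dates = regimen.anniversary_dates(member.index_date, 5)
    s0 = regimen.snapshot(dispensings, member.patient_id, dates[0], window_days)
    s5 = regimen.snapshot(dispensings, member.patient_id, dates[5], window_days)
    state, _ = classify_change(s0, s5)
    return state


def net_outcomes_from_snapshots(patient_id: str, snaps) -> str:
    state, _ = classify_change(snaps[0], snaps[-1])
    return state


def cohort_events(
    members: pd.DataFrame,
    dispensings: pd.DataFrame,
    window_days: int = regimen.DEFAULT_WINDOW_DAYS,
    n_years: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Classify the whole cohort in one vectorised pass.

    Returns ``(events, net_outcomes, index_labels)``: the long
    (patient, interval, state, subtype) table, the net index-vs-Year-5
    state per patient, and the baseline regimen label at index.
    """
    disp = dispensings[dispensings["atc_code"].str.startswith("A10")].copy()
    disp["dispense_date"] = pd.to_datetime(disp["dispense_date"])
    pids = members["patient_id"].to_numpy()
    index_dates = [regimen._as_date(d) for d in members["index_date"]]

    # codes active in the window around each anniversary, per patient
    code_sets: list[dict[str, frozenset]] = []
    w = pd.Timedelta(days=window_days)
    for k in range(n_years + 1):
        adate = pd.Series(
            [pd.Timestamp(regimen.add_years(d, k)) for d in index_dates],
            index=pids,
        )
        target = disp["patient_id"].map(adate)
        sel = disp[(disp["dispense_date"] >= target - w)
                   & (disp["dispense_date"] <= target + w)]
        sets = sel.groupby("patient_id")["atc_code"].agg(frozenset)
        code_sets.append(sets.to_dict())
    empty = frozenset()
    ev_rows, net_rows, label_rows = [], [], []
    for pid, d0 in zip(pids, index_dates):
        snaps = [
            regimen.snapshot_from_codes(
                pid, regimen.add_years(d0, k), code_sets[k].get(pid, empty)
            )
            for k in range(n_years + 1)
        ]
        label_rows.append(
            {"patient_id": pid,
             "regimen_label": regimen.classify_regimen(snaps[0]).label}
        )
        for k in range(1, n_years + 1):
            state, subtype = classify_change(snaps[k - 1], snaps[k])
            ev_rows.append(
                {"patient_id": pid, "interval_index": k,
                 "state": state, "subtype": subtype}
            )
        net_state, _ = classify_change(snaps[0], snaps[-1])
        net_rows.append({"patient_id": pid, "outcome": net_state})
    return (
        pd.DataFrame(ev_rows),
        pd.DataFrame(net_rows),
        pd.DataFrame(label_rows),
    )


def events_to_panel(events: pd.DataFrame) -> pd.DataFrame:
    """Wide panel (rows = patients, columns y1..y5) for the Markov model."""
    wide = events.pivot(index="patient_id", columns="interval_index",
                        values="state")
    wide.columns = [f"y{k}" for k in wide.columns]
    return wide


def share_table(labels: pd.Series) -> pd.DataFrame:
    """Counts and one-decimal percentage shares of a label column."""
    counts = labels.value_counts()
    n = int(counts.sum())
    return pd.DataFrame(
        {
            "label": counts.index,
            "count": counts.to_numpy(),
            "pct": [round_half_up(100.0 * c / n, 1) for c in counts.to_numpy()],
        }
    )
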