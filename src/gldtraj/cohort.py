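"""Prevalent-user cohort selection from the raw dispensing tables.

Selection rules, applied in a fixed declared order so the flow report is
reproducible:

1. an index date exists: first dispensing of any glucose-lowering drug
   (ATC ``A10``) inside the index window (boundaries inclusive);
2. age at index >= 35 years (age in completed years from the birth year,
   July-1 convention, since the database stores birth year only);
3. not a spot user: >= 2 A10 dispensings in the closed interval
   [index, index + 365 d] (the index dispensing counts as one);
4. continuous registration covering [index - 5 y, index + 5 y];
5. not insulin-only pre-index: among A10 dispensings in the five years
   before the index date, at least one is not an insulin (``A10A``).
   Patients with no pre-index A10 dispensings are retained
   (incident-like users);
6. optional "dummy"-patient screen via a configurable id predicate
   (off by default).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .change import age_band
from .config import CohortConfig
from .regimen import add_years, _as_date

logger = logging.getLogger(__name__)

STEP_ORDER = (
    "no_index_date",
    "age_below_minimum",
    "spot_user",
    "incomplete_registration",
    "insulin_only_preindex",
    "dummy_patient",
)


@dataclass(frozen=True)
class CohortMember:
    patient_id: str
    index_date: dt.date
    age_at_index: int
    sex: str
    age_band: str


def age_at(index_date: dt.date, birth_year: int) -> int:
    """Completed years at ``index_date`` with the July-1 birthday convention."""
    index_date = _as_date(index_date)
    age = index_date.year - birth_year
    if (index_date.month, index_date.day) < (7, 1):
        age -= 1
    return age


def find_index_date(patient, dispensings: pd.DataFrame,
                    config: CohortConfig | None = None):
    """Earliest A10 dispensing date inside the index window, else None."""
    config = config or CohortConfig()
    pid = patient["patient_id"] if isinstance(patient, (dict, pd.Series)) else patient
    sub = dispensings[dispensings["patient_id"] == pid]
    a10 = sub[sub["atc_code"].str.startswith("A10")]
    if a10.empty:
        return None
    dates = pd.to_datetime(a10["dispense_date"])
    lo = pd.Timestamp(config.index_window_start)
    hi = pd.Timestamp(config.index_window_end)
    in_win = dates[(dates >= lo) & (dates <= hi)]
    if in_win.empty:
        return None
    return in_win.min().date()


def select_cohort(
    patients: pd.DataFrame,
    dispensings: pd.DataFrame,
    config: CohortConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the selection rules; returns (members, exclusion flow table).

    ``members`` has one row per retained patient (patient_id, index_date,
    age_at_index, sex, age_band); the flow table records the count removed
    at each step, in order, plus the retained total.
    """
    config = config or CohortConfig()
    if patients.empty:
        logger.warning("empty patient table: empty cohort")
        flow = _flow_frame({s: 0 for s in STEP_ORDER}, 0, 0)
        return pd.DataFrame(
            columns=["patient_id", "index_date", "age_at_index", "sex", "age_band"]
        ), flow

    pat = patients.set_index("patient_id")
    n_input = len(pat)
    disp = dispensings.copy()
    disp["dispense_date"] = pd.to_datetime(disp["dispense_date"])
    a10 = disp[disp["atc_code"].str.startswith("A10")]

    lo = pd.Timestamp(config.index_window_start)
    hi = pd.Timestamp(config.index_window_end)
    in_win = a10[(a10["dispense_date"] >= lo) & (a10["dispense_date"] <= hi)]
    index_date = in_win.groupby("patient_id")["dispense_date"].min()

    tally: dict[str, int] = {}
    alive = pat.index

    has_index = alive.intersection(index_date.index)
    tally["no_index_date"] = len(alive) - len(has_index)
    alive = has_index

    idx = index_date.loc[alive]
    birth = pat.loc[alive, "birth_year"]
    shift = (idx.dt.month * 100 + idx.dt.day) < 701
    ages = idx.dt.year - birth - shift.astype(int)
    ok = ages >= config.min_age_at_index
    tally["age_below_minimum"] = int((~ok).sum())
    alive = alive[ok.to_numpy()]

    # spot users: < min_a10_dispensings A10 dispensings in [index, index+lookahead]
    a10_alive = a10[a10["patient_id"].isin(alive)]
    merged_idx = a10_alive["patient_id"].map(index_date)
    delta = (a10_alive["dispense_date"] - merged_idx).dt.days
    in_year = a10_alive[(delta >= 0) & (delta <= config.lookahead_days)]
    n_year = in_year.groupby("patient_id").size().reindex(alive, fill_value=0)
    ok = n_year >= config.min_a10_dispensings
    tally["spot_user"] = int((~ok).sum())
    alive = alive[ok.to_numpy()]

    # continuous registration over [index - pre, index + post]
    idx_dates = index_date.loc[alive].dt.date
    pre = idx_dates.map(lambda d: add_years(d, -config.required_pre_years))
    post = idx_dates.map(lambda d: add_years(d, config.required_post_years))
    reg_start = pd.to_datetime(pat.loc[alive, "registration_start"]).dt.date
    reg_end = pd.to_datetime(pat.loc[alive, "registration_end"]).dt.date
    ok = (reg_start.to_numpy() <= pre.to_numpy()) & (
        reg_end.to_numpy() >= post.to_numpy()
    )
    tally["incomplete_registration"] = int((~ok).sum())
    alive = alive[ok]

    # insulin-only pre-index exclusion
    a10_alive = a10[a10["patient_id"].isin(alive)]
    midx = a10_alive["patient_id"].map(index_date)
    pre_lo = a10_alive["patient_id"].map(
        index_date.dt.date.map(
            lambda d: pd.Timestamp(add_years(d, -config.required_pre_years))
        )
    )
    pre_mask = (a10_alive["dispense_date"] >= pre_lo) & (
        a10_alive["dispense_date"] < midx
    )
    pre_disp = a10_alive[pre_mask]
    grp = pre_disp.groupby("patient_id")["atc_code"]
    n_pre = grp.size().reindex(alive, fill_value=0)
    n_pre_ins = (
        pre_disp[pre_disp["atc_code"].str.startswith("A10A")]
        .groupby("patient_id").size().reindex(alive, fill_value=0)
    )
    insulin_only = (n_pre > 0) & (n_pre == n_pre_ins)
    tally["insulin_only_preindex"] = int(insulin_only.sum())
    alive = alive[~insulin_only.to_numpy()]

    if config.dummy_id_predicate is not None:
        is_dummy = np.array([config.dummy_id_predicate(p) for p in alive])
        tally["dummy_patient"] = int(is_dummy.sum())
        alive = alive[~is_dummy]
    else:
        tally["dummy_patient"] = 0

    idx_final = index_date.loc[alive]
    birth = pat.loc[alive, "birth_year"]
    shift = (idx_final.dt.month * 100 + idx_final.dt.day) < 701
    ages = (idx_final.dt.year - birth - shift.astype(int)).astype(int)
    members = pd.DataFrame(
        {
            "patient_id": alive,
            "index_date": idx_final.dt.date.to_numpy(),
            "age_at_index": ages.to_numpy(),
            "sex": pat.loc[alive, "sex"].to_numpy(),
        }
    )
    members["age_band"] = [age_band(a) for a in members["age_at_index"]]
    members = members.sort_values("patient_id").reset_index(drop=True)
    flow = _flow_frame(tally, n_input, len(members))
    return members, flow


def _flow_frame(tally: dict[str, int], n_input: int, n_retained: int) -> pd.DataFrame:
    rows = [{"step": "input_patients", "n_excluded": 0, "n_remaining": n_input}]
    remaining = n_input
    for step in STEP_ORDER:
        removed = tally.get(step, 0)
        remaining -= removed
        rows.append({"step": step, "n_excluded": removed, "n_remaining": remaining})
    rows.append(
        {"step": "retained", "n_excluded": 0, "n_remaining": n_retained}
    )
    return pd.DataFrame(rows)
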