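"""Medication snapshots at anniversary dates and the regimen taxonomy.

A patient's regimen at an assessment date is the set of drug subgroups
with at least one dispensing in the closed ±45-day window around that
date (the anniversary method).  Snapshots are classified into a
14-category regimen taxonomy (metformin monotherapy, SU + non-insulin
combination, insulin + SU combination, ...) used for the baseline table,
and carry the class flags the change classifier needs.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import pandas as pd

from . import atc

DEFAULT_WINDOW_DAYS = 45

# taxonomy labels, as printed
METFORMIN_MONO = "Metformin monotherapy"
NONINS_NONSU_COMB = "Non-insulin, non-SU combination"
DPP4_MONO = "DPP4 inhibitors monotherapy"
GLP1_MONO = "GLP-1 analogs monotherapy"
AGI_MONO = "Alpha glucosidase inhibitors monotherapy"
TZD_MONO = "Thiazolidinediones monotherapy"
SGLT2_MONO = "SGLT2 inhibitors monotherapy"
SU_NONINS_COMB = "SU + non-insulin combination"
INS_OTHER_COMB = "Insulin + other combination"
INS_SU_COMB = "Insulin + SU combination"
SU_MONO = "SU monotherapy"
INS_COMB = "Insulin combination"
INS_MONO = "Insulin monotherapy"
SU_COMB = "SU combination"
NO_GLD = "none"

_MONO_BY_SUBGROUP = {
    "A10BA": METFORMIN_MONO,
    "A10BH": DPP4_MONO,
    "A10BJ": GLP1_MONO,
    "A10BF": AGI_MONO,
    "A10BG": TZD_MONO,
    "A10BK": SGLT2_MONO,
}

HYPO_ASSOCIATED_LABELS = frozenset(
    {SU_NONINS_COMB, INS_OTHER_COMB, INS_SU_COMB, SU_MONO, INS_COMB, INS_MONO, SU_COMB}
)

ALL_LABELS = (
    METFORMIN_MONO,
    NONINS_NONSU_COMB,
    DPP4_MONO,
    GLP1_MONO,
    AGI_MONO,
    TZD_MONO,
    SGLT2_MONO,
    SU_NONINS_COMB,
    INS_OTHER_COMB,
    INS_SU_COMB,
    SU_MONO,
    INS_COMB,
    INS_MONO,
    SU_COMB,
)


@dataclass(frozen=True)
class RegimenSnapshot:
    """Active medication around one assessment date.

    ``active_atc5`` holds the glucose-lowering ATC-5 subgroups active in
    the window (combination products decomposed); ``su_codes`` keeps the
    distinct full sulfonylurea codes, needed only to tell "SU combination"
    (two SU products) from "SU monotherapy".
    """

    patient_id: str
    assessment_date: dt.date
    active_atc5: frozenset[str] = field(default_factory=frozenset)
    su_codes: frozenset[str] = field(default_factory=frozenset)

    @property
    def has_insulin(self) -> bool:
        return any(s.startswith("A10A") for s in self.active_atc5)

    @property
    def has_su(self) -> bool:
        return "A10BB" in self.active_atc5

    @property
    def other_subgroups(self) -> frozenset[str]:
        """Active non-insulin, non-SU glucose-lowering subgroups."""
        return frozenset(
            s for s in self.active_atc5
            if s.startswith("A10") and not s.startswith("A10A") and s != "A10BB"
        )

    @property
    def has_other(self) -> bool:
        return bool(self.other_subgroups)

    @property
    def n_gld_groups(self) -> int:
        return sum(1 for s in self.active_atc5 if s.startswith("A10"))

    @property
    def therapy_type(self) -> str:
        n = self.n_gld_groups
        if n == 0:
            return "none"
        return "monotherapy" if n == 1 else "combination"


@dataclass(frozen=True)
class RegimenLabel:
    label: str
    hypo_associated: bool


def snapshot_from_codes(
    patient_id: str, assessment_date: dt.date, codes
) -> RegimenSnapshot:
    """Build a snapshot from the full ATC codes dispensed in the window."""
    active: set[str] = set()
    su_codes: set[str] = set()
    for code in set(codes):
        subs = atc.subgroups(code)
        active.update(s for s in subs if s.startswith("A10"))
        # only GLD subgroups are kept; non-GLD drugs are irrelevant here
        if "A10BB" in subs:
            su_codes.add(code)
    return RegimenSnapshot(
        patient_id=patient_id,
        assessment_date=assessment_date,
        active_atc5=frozenset(active),
        su_codes=frozenset(su_codes),
    )


def snapshot(
    dispensings: pd.DataFrame,
    patient_id: str,
    assessment_date,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> RegimenSnapshot:
    """Glucose-lowering regimen active in ``assessment_date`` ± ``window_days``.

    A subgroup is active iff at least one dispensing with that subgroup
    falls in the closed interval [date − w, date + w].  Invariant to
    record order and duplicates, and monotone in ``window_days``.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    assessment_date = _as_date(assessment_date)
    sub = dispensings[dispensings["patient_id"] == patient_id]
    if sub.empty:
        warnings.warn(f"no dispensings for patient {patient_id!r}; empty snapshot")
        return RegimenSnapshot(patient_id, assessment_date)
    dates = pd.to_datetime(sub["dispense_date"]).dt.date
    lo = assessment_date - dt.timedelta(days=window_days)
    hi = assessment_date + dt.timedelta(days=window_days)
    in_window = sub.loc[[(lo <= d <= hi) for d in dates], "atc_code"]
    gld = [c for c in in_window if atc.is_gld(c)]
    return snapshot_from_codes(patient_id, assessment_date, gld)


def classify_regimen(s: RegimenSnapshot) -> RegimenLabel:
    """Deterministic taxonomy label; insulin labels first, then SU, then other."""
    ins, su, other = s.has_insulin, s.has_su, s.other_subgroups
    n_ins = sum(1 for g in s.active_atc5 if g.startswith("A10A"))
    if ins:
        if su:
            label = INS_SU_COMB
        elif other:
            label = INS_OTHER_COMB
        elif n_ins >= 2:
            label = INS_COMB
        else:
            label = INS_MONO
    elif su:
        if other:
            label = SU_NONINS_COMB
        elif len(s.su_codes) >= 2:
            label = SU_COMB
        else:
            label = SU_MONO
    elif other:
        if len(other) == 1:
            g = next(iter(other))
            label = _MONO_BY_SUBGROUP.get(g, NONINS_NONSU_COMB)
        else:
            label = NONINS_NONSU_COMB
    else:
        label = NO_GLD
    return RegimenLabel(label=label, hypo_associated=ins or su)


def anniversary_dates(index_date, n_years: int = 5) -> list[dt.date]:
    """Index date plus its calendar anniversaries for Years 1..n.

    Feb 29 maps to Feb 28 in non-leap years.
    """
    index_date = _as_date(index_date)
    out = [index_date]
    for k in range(1, n_years + 1):
        out.append(add_years(index_date, k))
    return out


def add_years(date: dt.date, k: int) -> dt.date:
    try:
        return date.replace(year=date.year + k)
    except ValueError:  # Feb 29 in a non-leap target year
        return date.replace(year=date.year + k, day=28)


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.Timestamp(d).date()
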