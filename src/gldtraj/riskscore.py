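"""Dispensing-based hypoglycemia risk score at the index date.

The score is a logistic-regression classifier on routinely available
dispensing features (age, sex, drug counts, insulin exposure and
duration, premixed insulin, antidepressant use), returning a probability
in [0, 1]; patients at or above the 0.6 cutoff are labelled high risk.
The published coefficient vector is not public, so the coefficients are
a configuration input; the shipped default is a synthetic vector
calibrated so that roughly a quarter of a typical primary-care T2D
cohort — essentially the insulin-treated patients — is high risk.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import atc
from .config import ConfigurationError
from .regimen import DEFAULT_WINDOW_DAYS, add_years

PREDICTORS = (
    "age_decades",
    "female",
    "total_drug_count",
    "gld_count",
    "su_count",
    "insulin_count",
    "premixed_insulin",
    "antidepressant",
    "insulin_duration_years",
)

# synthetic default; see docs/methods.md for the calibration rationale
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "intercept": -4.60,
    "age_decades": 0.10,
    "female": 0.10,
    "total_drug_count": 0.06,
    "gld_count": 0.15,
    "su_count": 0.50,
    "insulin_count": 2.20,
    "premixed_insulin": 0.50,
    "antidepressant": 0.30,
    "insulin_duration_years": 0.40,
}

DEFAULT_CUTOFF = 0.6


@dataclass(frozen=True)
class RiskProfile:
    patient_id: str
    age_at_index: int
    sex: str
    total_drug_count: int
    gld_count: int
    su_count: int
    insulin_count: int
    premixed_insulin_use: bool
    antidepressant_use: bool
    insulin_duration_years: float

    def vector(self) -> dict[str, float]:
        return {
            "age_decades": self.age_at_index / 10.0,
            "female": 1.0 if self.sex == "female" else 0.0,
            "total_drug_count": float(self.total_drug_count),
            "gld_count": float(self.gld_count),
            "su_count": float(self.su_count),
            "insulin_count": float(self.insulin_count),
            "premixed_insulin": 1.0 if self.premixed_insulin_use else 0.0,
            "antidepressant": 1.0 if self.antidepressant_use else 0.0,
            "insulin_duration_years": self.insulin_duration_years,
        }


@dataclass(frozen=True)
class RiskScore:
    score: float
    category: str  # "low" / "high"
    cutoff: float = DEFAULT_CUTOFF


def build_profile(member, dispensings: pd.DataFrame,
                  window_days: int = DEFAULT_WINDOW_DAYS) -> RiskProfile:
    """Extract the predictor vector for one cohort member at index.

    Drug counts are distinct ATC-5 subgroups dispensed in the ±45-day
    index window; insulin duration is the time from the first insulin
    dispensing within the five pre-index years to the index date.
    """
    pid = member["patient_id"] if isinstance(member, (dict, pd.Series)) else member.patient_id
    index_date = member["index_date"] if isinstance(member, (dict, pd.Series)) else member.index_date
    if isinstance(index_date, pd.Timestamp):
        index_date = index_date.date()
    sub = dispensings[dispensings["patient_id"] == pid]
    dates = pd.to_datetime(sub["dispense_date"]).dt.date
    lo = index_date - dt.timedelta(days=window_days)
    hi = index_date + dt.timedelta(days=window_days)
    in_win = sub.loc[[(lo <= d <= hi) for d in dates], "atc_code"]
    subgroups: set[str] = set()
    for code in set(in_win):
        subgroups.update(atc.subgroups(code))
    gld = {s for s in subgroups if s.startswith("A10")}
    ins = {s for s in gld if s.startswith("A10A")}
    su = {s for s in gld if s.startswith("A10BB")}

    pre_lo = add_years(index_date, -5)
    pre_ins_dates = [
        d for d, c in zip(dates, sub["atc_code"])
        if c.startswith("A10A") and pre_lo <= d <= index_date
    ]
    duration = 0.0
    if pre_ins_dates:
        duration = min(5.0, (index_date - min(pre_ins_dates)).days / 365.25)

    sex = member["sex"] if isinstance(member, (dict, pd.Series)) else member.sex
    age = member["age_at_index"] if isinstance(member, (dict, pd.Series)) else member.age_at_index
    return RiskProfile(
        patient_id=pid,
        age_at_index=int(age),
        sex=sex,
        total_drug_count=len(subgroups),
        gld_count=len(gld),
        su_count=len(su),
        insulin_count=len(ins),
        premixed_insulin_use=any(s.startswith("A10AD") for s in ins),
        antidepressant_use=any(c.startswith("N06A") for c in in_win),
        insulin_duration_years=duration,
    )


def score(profile: RiskProfile, coefficients: dict[str, float] | None = None,
          cutoff: float = DEFAULT_CUTOFF) -> RiskScore:
    """Inverse-logit score; category 'high' iff score >= cutoff."""
    coef = coefficients if coefficients is not None else DEFAULT_COEFFICIENTS
    missing = ({"intercept", *PREDICTORS}) - set(coef)
    if missing:
        raise ConfigurationError(
            f"missing risk coefficients: {sorted(missing)}"
        )
    x = profile.vector()
    lp = coef["intercept"] + sum(coef[k] * x[k] for k in PREDICTORS)
    s = 1.0 / (1.0 + np.exp(-lp))
    return RiskScore(score=float(s),
                     category="high" if s >= cutoff else "low",
                     cutoff=cutoff)


def build_profiles(members: pd.DataFrame, dispensings: pd.DataFrame,
                   window_days: int = DEFAULT_WINDOW_DAYS) -> pd.DataFrame:
    """Vectorised profile extraction for a whole cohort."""
    disp = dispensings.copy()
    disp["dispense_date"] = pd.to_datetime(disp["dispense_date"])
    idx_map = members.set_index("patient_id")["index_date"].map(pd.Timestamp)
    disp = disp[disp["patient_id"].isin(idx_map.index)]
    idx = disp["patient_id"].map(idx_map)
    delta = (disp["dispense_date"] - idx).dt.days

    win = disp[np.abs(delta) <= window_days]
    # decomposed subgroups per record
    win_sub = win.assign(
        subgroup=[atc.subgroups(c) for c in win["atc_code"]]
    ).explode("subgroup")
    per = win_sub.groupby("patient_id")["subgroup"]
    total = per.nunique()
    gld = win_sub[win_sub["subgroup"].str.startswith("A10")].groupby(
        "patient_id")["subgroup"].nunique()
    ins_sub = win_sub[win_sub["subgroup"].str.startswith("A10A")]
    ins = ins_sub.groupby("patient_id")["subgroup"].nunique()
    su = win_sub[win_sub["subgroup"].str.startswith("A10BB")].groupby(
        "patient_id")["subgroup"].nunique()
    premix = ins_sub[ins_sub["subgroup"].str.startswith("A10AD")].groupby(
        "patient_id").size()
    antidep = win[win["atc_code"].str.startswith("N06A")].groupby(
        "patient_id").size()

    pre_lo = disp["patient_id"].map(
        idx_map.map(lambda t: pd.Timestamp(add_years(t.date(), -5)))
    )
    pre_ins = disp[
        disp["atc_code"].str.startswith("A10A")
        & (disp["dispense_date"] >= pre_lo)
        & (disp["dispense_date"] <= idx)
    ]
    first_ins = pre_ins.groupby("patient_id")["dispense_date"].min()
    dur = ((idx_map.loc[first_ins.index] - first_ins).dt.days / 365.25).clip(
        upper=5.0
    )

    out = members[["patient_id", "age_at_index", "sex"]].copy()
    pid = out["patient_id"]
    out["total_drug_count"] = pid.map(total).fillna(0).astype(int)
    out["gld_count"] = pid.map(gld).fillna(0).astype(int)
    out["su_count"] = pid.map(su).fillna(0).astype(int)
    out["insulin_count"] = pid.map(ins).fillna(0).astype(int)
    out["premixed_insulin"] = pid.map(premix).fillna(0).astype(int) > 0
    out["antidepressant"] = pid.map(antidep).fillna(0).astype(int) > 0
    out["insulin_duration_years"] = pid.map(dur).fillna(0.0)
    return out


def score_table(profiles: pd.DataFrame,
                coefficients: dict[str, float] | None = None,
                cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Scores and categories for a profile table."""
    coef = coefficients if coefficients is not None else DEFAULT_COEFFICIENTS
    missing = ({"intercept", *PREDICTORS}) - set(coef)
    if missing:
        raise ConfigurationError(f"missing risk coefficients: {sorted(missing)}")
    lp = (
        coef["intercept"]
        + coef["age_decades"] * profiles["age_at_index"] / 10.0
        + coef["female"] * (profiles["sex"] == "female")
        + coef["total_drug_count"] * profiles["total_drug_count"]
        + coef["gld_count"] * profiles["gld_count"]
        + coef["su_count"] * profiles["su_count"]
        + coef["insulin_count"] * profiles["insulin_count"]
        + coef["premixed_insulin"] * profiles["premixed_insulin"]
        + coef["antidepressant"] * profiles["antidepressant"]
        + coef["insulin_duration_years"] * profiles["insulin_duration_years"]
    )
    s = 1.0 / (1.0 + np.exp(-lp.astype(float)))
    return pd.DataFrame(
        {
            "patient_id": profiles["patient_id"],
            "score": s,
            "category": np.where(s >= cutoff, "high", "low"),
        }
    )


def load_coefficients(path) -> dict[str, float]:
    """Read a two-column (predictor, weight) delimited coefficients file."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    return dict(zip(df[cols[0]], df[cols[1]].astype(float)))


def write_coefficients(coefficients: dict[str, float], path) -> None:
    pd.DataFrame(
        {"predictor": list(coefficients), "weight": list(coefficients.values())}
    ).to_csv(path, index=False)
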