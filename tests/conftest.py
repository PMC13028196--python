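import datetime as dt

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gldtraj import change, cohort, riskscore, synthetic
from gldtraj.config import SimulationConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_dispensings(rows):
    """rows: iterable of (patient_id, atc_code, iso_date)."""
    return pd.DataFrame(
        [
            {
                "patient_id": pid,
                "atc_code": code,
                "dispense_date": pd.Timestamp(date),
                "n_days_supplied": 60,
            }
            for pid, code, date in rows
        ]
    )


def make_member(pid="P1", index_date="2016-09-01", age=60, sex="male"):
    return pd.Series(
        {
            "patient_id": pid,
            "index_date": dt.date.fromisoformat(index_date),
            "age_at_index": age,
            "sex": sex,
            "age_band": change.age_band(age),
        }
    )


@pytest.fixture(scope="session")
def large_run():
    """One large simulated cohort shared by the statistical checks.

    Short refill intervals make ±45-day window misses negligible, so the
    realised states reflect the latent process almost exactly.
    """
    cfg = SimulationConfig(
        n_patients=27500,
        seed=20260922,
        refill_interval_days=(30.0, 5.0),
        frac_short_registration=0.04,
        frac_spot_users=0.02,
        frac_insulin_only_preindex=0.02,
    )
    patients, dispensings = synthetic.generate_population(cfg)
    members, flow = cohort.select_cohort(patients, dispensings)
    events, net, labels = change.cohort_events(members, dispensings)
    truth = synthetic.latent_truth(cfg)
    profiles = riskscore.build_profiles(members, dispensings)
    scores = riskscore.score_table(profiles)
    return {
        "config": cfg,
        "patients": patients,
        "dispensings": dispensings,
        "members": members,
        "flow": flow,
        "events": events,
        "net": net,
        "labels": labels,
        "truth": truth,
        "profiles": profiles,
        "scores": scores,
    }


@pytest.fixture(scope="session")
def small_population():
    cfg = SimulationConfig(n_patients=800, seed=99)
    patients, dispensings = synthetic.generate_population(cfg)
    return cfg, patients, dispensings
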