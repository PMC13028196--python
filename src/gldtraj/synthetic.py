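"""Synthetic community-pharmacy dispensing database generator.

Emulates the longitudinal structure the trajectory analysis assumes: a
patient table (birth year, sex, registration interval) and a dispensing
table (patient, ATC code, date), where each non-edge-case patient carries
a latent annual treatment path.  A patient starts from a baseline
glucose-lowering regimen drawn from the observed regimen taxonomy, and
each follow-up year an intended state (no change / intensification /
de-intensification) is drawn from configurable row-conditional rates,
modified by covariate odds multipliers, and realised as a concrete
regimen edit (add / discontinue / switch a drug class) when the current
regimen permits it.  Dispensings are emitted per drug as a renewal
process with truncated-normal refill intervals, so a drug active at an
assessment date has a dispensing inside the ±45-day window with high
probability.

Edge cases are injected at configured fractions: spot users (a single
glucose-lowering dispensing), insulin-only pre-index (type-1-like)
patients, and patients with under ten years of registration.

The generator is deterministic: one master seed, per-patient substreams
spawned from it, so outputs are byte-identical across runs and
independent of iteration order.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from . import regimen as rg
from .config import DEFAULT_CHANGE_TARGETS, SimulationConfig

_EPOCH = dt.date(1970, 1, 1)


def _d2i(d: dt.date) -> int:
    return (d - _EPOCH).days


def _i2d(i: int) -> dt.date:
    return _EPOCH + dt.timedelta(days=int(i))


# concrete drug products behind each baseline regimen category
REGIMEN_CODES: dict[str, tuple[str, ...]] = {
    rg.METFORMIN_MONO: ("A10BA02",),
    rg.NONINS_NONSU_COMB: ("A10BA02", "A10BH01"),
    rg.DPP4_MONO: ("A10BH01",),
    rg.GLP1_MONO: ("A10BJ02",),
    rg.AGI_MONO: ("A10BF01",),
    rg.TZD_MONO: ("A10BG03",),
    rg.SGLT2_MONO: ("A10BK01",),
    rg.SU_NONINS_COMB: ("A10BA02", "A10BB09"),
    rg.INS_OTHER_COMB: ("A10AE04", "A10BA02"),
    rg.INS_SU_COMB: ("A10AE04", "A10BB09"),
    rg.SU_MONO: ("A10BB09",),
    rg.INS_COMB: ("A10AE04", "A10AB05"),
    rg.INS_MONO: ("A10AE04",),
    rg.SU_COMB: ("A10BB01", "A10BB09"),
}

_SU_CODE = "A10BB09"
_BASAL_INSULIN = "A10AE04"
_PREMIX_INSULIN = "A10AD05"
_OTHER_POOL = ("A10BH01", "A10BK01", "A10BJ02", "A10BA02")

FILLER_CODES = (
    "C07AB02", "C09AA02", "C10AA01", "A02BC02",
    "B01AC06", "N02BE01", "C03CA01", "R03AC02",
)
ANTIDEPRESSANT_CODE = "N06AB06"


def _is_ins(c: str) -> bool:
    return c.startswith("A10A")


def _is_su(c: str) -> bool:
    return c.startswith("A10BB")


def _is_other(c: str) -> bool:
    return c.startswith("A10") and not _is_ins(c) and not _is_su(c)


# ---------------------------------------------------------------------------
# intended-state machinery

def _modifier(row: dict[str, float], ins_active: bool, female: bool,
              age: float, ref_age: float) -> float:
    m = 1.0
    if ins_active:
        m *= row.get("insulin_active", 1.0)
    if female:
        m *= row.get("female", 1.0)
    per_dec = row.get("age_per_decade", 1.0)
    if per_dec != 1.0:
        m *= per_dec ** ((age - ref_age) / 10.0)
    return m


def _odds_scale(p, m):
    """Apply an odds multiplier to a probability (vectorised)."""
    return m * p / (1.0 - p + m * p)


def _regimen_probs(config: SimulationConfig) -> dict[str, float]:
    counts = config.initial_regimen_counts
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


def _label_traits(label: str) -> tuple[bool, bool]:
    """(insulin_active, hypo_active) for a baseline regimen label."""
    codes = REGIMEN_CODES[label]
    ins = any(_is_ins(c) for c in codes)
    hypo = ins or any(_is_su(c) for c in codes)
    return ins, hypo


def calibrated_change_rates(
    config: SimulationConfig,
    targets: list[dict[str, dict[str, float]]] | None = None,
) -> list[dict[str, dict[str, float]]]:
    """Resolve per-interval intended-state draw probabilities.

    The NC-source rows are calibrated so that, after covariate odds
    modifiers and regimen-feasibility fallback, the realised frequency of
    each destination matches the row target under the configured baseline
    regimen / age / sex mix.  Rows for the IN and DI source states are
    taken as-is (their destination moves are almost always feasible).
    """
    targets = targets if targets is not None else DEFAULT_CHANGE_TARGETS
    probs = _regimen_probs(config)
    mean_age, sd_age = config.age_distribution
    ref_age = mean_age

    # age grid on the >=35 cohort support
    ages = np.linspace(35.0, mean_age + 4 * sd_age, 96)
    age_w = stats.norm.pdf(ages, mean_age, sd_age)
    age_w /= age_w.sum()

    labels = list(probs)
    lab_w = np.array([probs[l] for l in labels])
    ins_act = np.array([_label_traits(l)[0] for l in labels])
    hypo = np.array([_label_traits(l)[1] for l in labels])
    # intensification is infeasible only when both hypo classes are present
    in_elig = np.array([l != rg.INS_SU_COMB for l in labels])

    def realized(p: float, dest: str) -> float:
        row = config.rate_modifiers.get("IN" if dest == "IN" else "DI", {})
        elig = in_elig if dest == "IN" else hypo
        acc = 0.0
        for female, sex_w in ((False, 1 - config.frac_female),
                              (True, config.frac_female)):
            # labels x ages modifier matrix
            base = np.where(ins_act, row.get("insulin_active", 1.0), 1.0)
            if female:
                base = base * row.get("female", 1.0)
            per_dec = row.get("age_per_decade", 1.0)
            age_f = per_dec ** ((ages - ref_age) / 10.0)
            m = np.outer(base, age_f)
            pr = _odds_scale(p, m)
            acc += sex_w * float((lab_w * elig) @ pr @ age_w)
        return acc

    out: list[dict[str, dict[str, float]]] = []
    for piece in targets:
        resolved: dict[str, dict[str, float]] = {}
        for src, rates in piece.items():
            if src == "NC":
                resolved[src] = {
                    dest: brentq(lambda p: realized(p, dest) - t, 1e-10, 0.6,
                                 xtol=1e-12)
                    for dest, t in rates.items()
                }
            else:
                resolved[src] = dict(rates)
        out.append(resolved)
    return out


def resolve_change_rates(config: SimulationConfig):
    if config.annual_change_rates is not None:
        return config.annual_change_rates
    return calibrated_change_rates(config)


# ---------------------------------------------------------------------------
# refill emission

def _refill_times(rng: np.random.Generator, start: int, end: int,
                  mean: float, sd: float, floor: float) -> np.ndarray:
    """Renewal-process dispensing days in [start, end], first at start."""
    if end < start:
        return np.empty(0, dtype=np.int64)
    span = end - start
    n = int(span / mean * 1.4) + 6
    while True:
        gaps = np.maximum(rng.normal(mean, sd, size=n), floor)
        days = start + np.concatenate(([0.0], np.cumsum(gaps)))
        if days[-1] > end:
            break
        n *= 2
    return days[days <= end].astype(np.int64)


# ---------------------------------------------------------------------------
# per-patient simulation

_KIND_REGULAR = "regular"
_KIND_SPOT = "spot"
_KIND_INS_ONLY = "insulin_only"
_KIND_SHORT_REG = "short_registration"


def _in_actions(cur: set[str]) -> list[tuple[str, float]]:
    has_ins = any(_is_ins(c) for c in cur)
    has_su = any(_is_su(c) for c in cur)
    has_other = any(_is_other(c) for c in cur)
    acts: list[tuple[str, float]] = []
    if has_su and not has_ins:
        acts.append(("add_ins", 0.75))
        acts.append(("switch_su_to_ins", 0.15))
        if has_other:
            acts.append(("switch_other_to_ins", 0.10))
    elif not has_su:
        acts.append(("add_su", 0.80))
        if not has_ins:
            acts.append(("add_ins", 0.12))
        if has_other:
            acts.append(("switch_other_to_su", 0.04))
            if not has_ins:
                acts.append(("switch_other_to_ins", 0.04))
    return acts


def _di_actions(cur: set[str]) -> list[tuple[str, float]]:
    has_ins = any(_is_ins(c) for c in cur)
    has_su = any(_is_su(c) for c in cur)
    acts: list[tuple[str, float]] = []
    if has_ins and has_su:
        acts = [("disc_su", 0.75), ("disc_ins", 0.25)]
    elif has_ins:
        acts = [("disc_ins", 0.85), ("switch_ins_to_nonsu", 0.11),
                ("switch_ins_to_su", 0.04)]
    elif has_su:
        acts = [("disc_su", 0.87), ("switch_su_to_nonsu", 0.13)]
    return acts


def _pick(rng: np.random.Generator, acts: list[tuple[str, float]]) -> str:
    w = np.array([a[1] for a in acts])
    w = w / w.sum()
    return acts[int(rng.choice(len(acts), p=w))]


def _pick_action(rng, acts):
    w = np.array([a[1] for a in acts])
    return acts[int(rng.choice(len(acts), p=w / w.sum()))][0]


class _PatientSim:
    """Mutable per-patient state during simulation."""

    __slots__ = ("episodes", "active")

    def __init__(self):
        self.episodes: list[list] = []  # [code, start, end_or_None]
        self.active: dict[str, int] = {}  # code -> episode idx

    def start(self, code: str, day: int) -> None:
        self.episodes.append([code, day, None])
        self.active[code] = len(self.episodes) - 1

    def stop(self, code: str, day: int) -> None:
        idx = self.active.pop(code)
        self.episodes[idx][2] = day

    def stop_class(self, pred, day: int) -> None:
        for code in [c for c in self.active if pred(c)]:
            self.stop(code, day)

    def codes(self) -> set[str]:
        return set(self.active)


def _apply_action(sim: _PatientSim, action: str, day: int,
                  rng: np.random.Generator, premix_frac: float) -> None:
    def new_insulin() -> str:
        return _PREMIX_INSULIN if rng.random() < premix_frac else _BASAL_INSULIN

    def add_other() -> None:
        for cand in _OTHER_POOL:
            if cand not in sim.active:
                sim.start(cand, day)
                return

    if action == "add_su":
        sim.start(_SU_CODE, day)
    elif action == "add_ins":
        sim.start(new_insulin(), day)
    elif action == "switch_su_to_ins":
        sim.stop_class(_is_su, day)
        sim.start(new_insulin(), day)
    elif action == "switch_other_to_su":
        others = sorted(c for c in sim.active if _is_other(c))
        sim.stop(others[int(rng.integers(len(others)))], day)
        sim.start(_SU_CODE, day)
    elif action == "switch_other_to_ins":
        others = sorted(c for c in sim.active if _is_other(c))
        sim.stop(others[int(rng.integers(len(others)))], day)
        sim.start(new_insulin(), day)
    elif action == "disc_su":
        sim.stop_class(_is_su, day)
    elif action == "disc_ins":
        sim.stop_class(_is_ins, day)
    elif action == "switch_ins_to_su":
        sim.stop_class(_is_ins, day)
        sim.start(_SU_CODE, day)
    elif action == "switch_ins_to_nonsu":
        sim.stop_class(_is_ins, day)
        add_other()
    elif action == "switch_su_to_nonsu":
        sim.stop_class(_is_su, day)
        add_other()
    else:  # pragma: no cover
        raise AssertionError(action)


def _simulate_patient(pid, rng, cfg: SimulationConfig, rates, consts):
    """Returns (patient_row, [(code, day_array)...], states_or_None)."""
    ws, we = consts["ws"], consts["we"]
    reg_start, reg_end = consts["reg_start"], consts["reg_end"]
    mean, sd = cfg.refill_interval_days
    floor = cfg.refill_floor_days

    u = rng.random()
    if u < cfg.frac_spot_users:
        kind = _KIND_SPOT
    elif u < cfg.frac_spot_users + cfg.frac_insulin_only_preindex:
        kind = _KIND_INS_ONLY
    elif u < (cfg.frac_spot_users + cfg.frac_insulin_only_preindex
              + cfg.frac_short_registration):
        kind = _KIND_SHORT_REG
    else:
        kind = _KIND_REGULAR

    female = rng.random() < cfg.frac_female
    age = int(np.clip(np.round(rng.normal(*cfg.age_distribution)), 6, 110))
    birth_year = consts["ref_year"] - age

    r_start, r_end = reg_start, reg_end
    if kind == _KIND_SHORT_REG:
        if rng.random() < 0.5:
            r_start = reg_start + int(rng.integers(550, 1800))
        else:
            r_end = reg_end - int(rng.integers(600, 1800))

    row = {
        "patient_id": pid,
        "birth_year": birth_year,
        "sex": "female" if female else "male",
        "registration_start": _i2d(r_start),
        "registration_end": _i2d(r_end),
    }

    out: list[tuple[str, np.ndarray]] = []

    def fillers(anchor: int) -> None:
        n_f = min(int(rng.poisson(cfg.filler_drug_mean)), len(FILLER_CODES))
        chosen = rng.choice(len(FILLER_CODES), size=n_f, replace=False)
        for i in sorted(chosen):
            t1 = int(np.clip(anchor + rng.integers(-40, 41), r_start, r_end))
            t2 = int(np.clip(t1 + rng.integers(30, 71), r_start, r_end))
            out.append((FILLER_CODES[i], np.array([t1, t2], dtype=np.int64)))
        if rng.random() < cfg.frac_antidepressant:
            t1 = int(np.clip(anchor + rng.integers(-40, 41), r_start, r_end))
            t2 = int(np.clip(t1 + rng.integers(30, 71), r_start, r_end))
            out.append((ANTIDEPRESSANT_CODE, np.array([t1, t2], dtype=np.int64)))

    if kind == _KIND_SPOT:
        day = ws + int(rng.integers(0, 331))
        out.append(("A10BA02", np.array([day], dtype=np.int64)))
        fillers(day)
        return row, out, None

    # baseline regimen
    if kind == _KIND_INS_ONLY:
        label = rg.INS_MONO
    else:
        label = consts["labels"][
            int(rng.choice(len(consts["labels"]), p=consts["label_p"]))
        ]
    codes = list(REGIMEN_CODES[label])
    if any(_is_ins(c) for c in codes) and rng.random() < cfg.frac_premixed_insulin:
        codes = [_PREMIX_INSULIN if c == _BASAL_INSULIN else c for c in codes]

    sim = _PatientSim()
    times: dict[int, np.ndarray] = {}  # episode idx -> dispensing days

    horizon_full = r_end
    for code in codes:
        start = r_start + int(rng.integers(0, 46))
        sim.start(code, start)
        times[sim.active[code]] = _refill_times(
            rng, start, horizon_full, mean, sd, floor
        )

    # index date: first glucose-lowering dispensing on/after the window start
    t0 = None
    for idx in list(sim.active.values()):
        ts = times[idx]
        after = ts[ts >= ws]
        if len(after) and (t0 is None or after[0] < t0):
            t0 = int(after[0])
    if t0 is None or t0 > we:
        # no dispensing inside the index window (early de-registration)
        for idx, ts in times.items():
            out.append((sim.episodes[idx][0], ts))
        fillers(min(r_start + 200, r_end))
        return row, out, None

    # prior oral therapy for insulin-monotherapy-like baselines, so that
    # regular patients are not insulin-only over the pre-index years
    if kind != _KIND_INS_ONLY and label in (rg.INS_MONO, rg.INS_COMB):
        hist_end = t0 - int(rng.integers(750, 1401))
        hist_start = r_start + int(rng.integers(0, 46))
        if hist_end - hist_start > 90:
            ts = _refill_times(rng, hist_start, hist_end, mean, sd, floor)
            out.append(("A10BA02", ts))

    # annual latent path
    t0_date = _i2d(t0)
    ann = [t0] + [_d2i(rg.add_years(t0_date, k)) for k in range(1, 6)]
    mods_in = cfg.rate_modifiers.get("IN", {})
    mods_di = cfg.rate_modifiers.get("DI", {})
    ref_age = cfg.age_distribution[0]
    state = "NC"
    states: list[str] = []
    for k in range(1, 6):
        piece = rates[k - 1]
        rates_row = piece.get(state, piece.get("NC", {}))
        ins_active = any(_is_ins(c) for c in sim.active)
        p_in = _odds_scale(
            rates_row.get("IN", 0.0),
            _modifier(mods_in, ins_active, female, age, ref_age),
        )
        p_di = _odds_scale(
            rates_row.get("DI", 0.0),
            _modifier(mods_di, ins_active, female, age, ref_age),
        )
        tot = p_in + p_di
        if tot > 0.9:
            p_in, p_di = 0.9 * p_in / tot, 0.9 * p_di / tot
        u = rng.random()
        intended = "IN" if u < p_in else ("DI" if u < p_in + p_di else "NC")
        realized = "NC"
        if intended == "IN":
            acts = _in_actions(sim.codes())
            if acts:
                day = ann[k - 1] + int(rng.integers(60, 301))
                action = _pick_action(rng, acts)
                _before = set(sim.active)
                _apply_action(sim, action, day, rng, cfg.frac_premixed_insulin)
                for code in set(sim.active) - _before:
                    times[sim.active[code]] = _refill_times(
                        rng, day, horizon_full, mean, sd, floor
                    )
                realized = "IN"
        elif intended == "DI":
            acts = _di_actions(sim.codes())
            if acts:
                day = ann[k - 1] + int(rng.integers(60, 301))
                action = _pick_action(rng, acts)
                _before = set(sim.active)
                _apply_action(sim, action, day, rng, cfg.frac_premixed_insulin)
                for code in set(sim.active) - _before:
                    times[sim.active[code]] = _refill_times(
                        rng, day, horizon_full, mean, sd, floor
                    )
                realized = "DI"
        states.append(realized)
        state = realized

    horizon = min(r_end, ann[5] + 100)
    for idx, ep in enumerate(sim.episodes):
        code, start, end = ep
        ts = times.get(idx)
        if ts is None:
            continue
        hi = horizon if end is None else min(end - 1, horizon)
        out.append((code, ts[(ts >= start) & (ts <= hi)]))

    fillers(t0)
    return row, out, states


def _constants(cfg: SimulationConfig) -> dict:
    probs = _regimen_probs(cfg)
    labels = list(probs)
    return {
        "ws": _d2i(cfg.index_window_start),
        "we": _d2i(cfg.index_window_end),
        "reg_start": _d2i(cfg.start_date),
        "reg_end": _d2i(cfg.end_date),
        "ref_year": cfg.index_window_start.year,
        "labels": labels,
        "label_p": np.array([probs[l] for l in labels]),
    }


def _run(cfg: SimulationConfig):
    rates = resolve_change_rates(cfg)
    consts = _constants(cfg)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_patients)
    patient_rows = []
    disp_pid: list[str] = []
    disp_code: list[str] = []
    disp_days: list[np.ndarray] = []
    truth_rows = []
    for i in range(cfg.n_patients):
        pid = f"P{i:06d}"
        rng = np.random.default_rng(children[i])
        row, eps, states = _simulate_patient(pid, rng, cfg, rates, consts)
        patient_rows.append(row)
        for code, days in eps:
            if len(days):
                disp_pid.extend([pid] * len(days))
                disp_code.extend([code] * len(days))
                disp_days.append(days)
        if states is not None:
            for k, s in enumerate(states, start=1):
                truth_rows.append((pid, k, s))
    patients = pd.DataFrame(patient_rows)
    patients["registration_start"] = pd.to_datetime(patients["registration_start"])
    patients["registration_end"] = pd.to_datetime(patients["registration_end"])
    days_all = (
        np.concatenate(disp_days) if disp_days else np.empty(0, dtype=np.int64)
    )
    dispensings = pd.DataFrame(
        {
            "patient_id": pd.array(disp_pid, dtype=str),
            "atc_code": pd.array(disp_code, dtype=str),
            "dispense_date": pd.to_datetime(days_all, unit="D"),
        }
    )
    dispensings["n_days_supplied"] = np.where(
        dispensings["atc_code"].str.startswith("A10"), 60, 30
    )
    dispensings = dispensings.sort_values(
        ["patient_id", "dispense_date", "atc_code"], kind="mergesort"
    ).reset_index(drop=True)
    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "interval_index", "state"]
    )
    return patients, dispensings, truth


def generate_population(config: SimulationConfig):
    """Simulate the database: returns ``(patients, dispensings)`` tables."""
    patients, dispensings, _ = _run(config)
    return patients, dispensings


def latent_truth(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Generative per-patient-year states, for classifier-recovery checks.

    ``seed``, if given, must equal ``config.seed`` (the truth is only
    defined for the exact stream that generated the tables).
    """
    if seed is not None and seed != config.seed:
        raise ValueError(
            f"seed {seed} does not match config.seed {config.seed}"
        )
    _, _, truth = _run(config)
    return truth


def write_tables(patients: pd.DataFrame, dispensings: pd.DataFrame,
                 patients_path, dispensings_path) -> None:
    """Write the two delimited tables with ISO-8601 dates."""
    p = patients.copy()
    for col in ("registration_start", "registration_end"):
        p[col] = pd.to_datetime(p[col]).dt.strftime("%Y-%m-%d")
    d = dispensings.copy()
    d["dispense_date"] = pd.to_datetime(d["dispense_date"]).dt.strftime("%Y-%m-%d")
    p.to_csv(patients_path, index=False)
    d.to_csv(dispensings_path, index=False)


# ---------------------------------------------------------------------------
# analytic expectations under the generator's covariate law

def expected_high_risk_fraction(config: SimulationConfig, coefficients=None,
                                cutoff: float = 0.6) -> float:
    """Expected share of high-risk patients among retained cohort members,
    computed by integrating the score over the generator's covariate
    distribution (regimen mix x premix x antidepressant x sex x filler
    count x truncated age), independent of any simulation run."""
    from . import riskscore

    coef = coefficients if coefficients is not None else (
        config.risk_coefficients or riskscore.DEFAULT_COEFFICIENTS
    )
    probs = _regimen_probs(config)
    mean_age, sd_age = config.age_distribution
    ages = np.linspace(35.0, mean_age + 4 * sd_age, 161)
    age_w = stats.norm.pdf(ages, mean_age, sd_age)
    age_w /= age_w.sum()

    n_max = len(FILLER_CODES)
    ks = np.arange(0, n_max + 1)
    pk = stats.poisson.pmf(ks, config.filler_drug_mean)
    pk[-1] += 1.0 - pk.sum()  # counts above the pool size collapse to it

    total = 0.0
    for label, p_lab in probs.items():
        base_codes = REGIMEN_CODES[label]
        has_ins = any(_is_ins(c) for c in base_codes)
        premix_opts = (
            [(False, 1 - config.frac_premixed_insulin),
             (True, config.frac_premixed_insulin)]
            if has_ins else [(False, 1.0)]
        )
        subgroups = {c[:5] for c in base_codes}
        gld = len(subgroups)
        su = int(any(_is_su(c) for c in base_codes))
        ins = sum(1 for s in subgroups if s.startswith("A10A"))
        dur = 5.0 if has_ins else 0.0
        for premix, p_pm in premix_opts:
            for antidep, p_ad in (
                (False, 1 - config.frac_antidepressant),
                (True, config.frac_antidepressant),
            ):
                for female, p_sex in (
                    (False, 1 - config.frac_female),
                    (True, config.frac_female),
                ):
                    for k, p_k in zip(ks, pk):
                        lp = (
                            coef["intercept"]
                            + coef["age_decades"] * ages / 10.0
                            + coef["female"] * float(female)
                            + coef["total_drug_count"]
                            * (gld + k + int(antidep))
                            + coef["gld_count"] * gld
                            + coef["su_count"] * su
                            + coef["insulin_count"] * ins
                            + coef["premixed_insulin"] * float(premix)
                            + coef["antidepressant"] * float(antidep)
                            + coef["insulin_duration_years"] * dur
                        )
                        score = 1.0 / (1.0 + np.exp(-lp))
                        p_high = float(age_w @ (score >= cutoff))
                        total += p_lab * p_pm * p_ad * p_sex * p_k * p_high
    return total
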