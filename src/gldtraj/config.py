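"""Configuration objects for the simulation, cohort selection and pipeline.

All randomness in the package flows from the seeds held here; no stage
seeds itself from the wall clock.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, fields
from typing import Callable

import yaml

from . import regimen as _regimen


class ConfigurationError(ValueError):
    """Raised for an invalid configuration value, naming the field."""


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


# Baseline regimen distribution the generator draws from: the observed
# category counts of a Dutch T2D dispensing cohort (n = 25,057).
DEFAULT_INITIAL_REGIMEN_COUNTS: dict[str, int] = {
    _regimen.METFORMIN_MONO: 10315,
    _regimen.NONINS_NONSU_COMB: 437,
    _regimen.DPP4_MONO: 47,
    _regimen.GLP1_MONO: 25,
    _regimen.AGI_MONO: 17,
    _regimen.TZD_MONO: 10,
    _regimen.SGLT2_MONO: 4,
    _regimen.SU_NONINS_COMB: 6623,
    _regimen.INS_OTHER_COMB: 3886,
    _regimen.INS_SU_COMB: 1652,
    _regimen.SU_MONO: 1075,
    _regimen.INS_COMB: 545,
    _regimen.INS_MONO: 408,
    _regimen.SU_COMB: 13,
}

# Row-conditional targets for the intended annual state, one entry per
# follow-up interval.  The Year-1 row targets the marginal state shares;
# rows for later intervals target the frequency of the next state given
# the current one.  Values mirror the annual transition structure of the
# study cohort this generator emulates.
DEFAULT_CHANGE_TARGETS: list[dict[str, dict[str, float]]] = [
    {"NC": {"IN": 1923 / 25057, "DI": 1188 / 25057}},
    {
        "NC": {"IN": 1480 / 21946, "DI": 778 / 21946},
        "IN": {"IN": 101 / 1923, "DI": 341 / 1923},
        "DI": {"IN": 324 / 1188, "DI": 31 / 1188},
    },
    {
        "NC": {"IN": 1356 / 22002, "DI": 786 / 22002},
        "IN": {"IN": 88 / 1905, "DI": 384 / 1905},
        "DI": {"IN": 309 / 1150, "DI": 30 / 1150},
    },
    {
        "NC": {"IN": 1247 / 22104, "DI": 854 / 22104},
        "IN": {"IN": 70 / 1753, "DI": 361 / 1753},
        "DI": {"IN": 310 / 1200, "DI": 30 / 1200},
    },
    {
        "NC": {"IN": 1345 / 22185, "DI": 1195 / 22185},
        "IN": {"IN": 64 / 1627, "DI": 372 / 1627},
        "DI": {"IN": 320 / 1245, "DI": 51 / 1245},
    },
]

# Odds multipliers applied to a patient-year's intended-state probability.
# Directions mirror the associations reported for this population: being
# on insulin (the dominant driver of a high estimated hypoglycemia risk)
# strongly lowers further intensification; female sex slightly raises
# de-intensification; age lowers intensification per decade.  No explicit
# insulin multiplier is needed for de-intensification: its positive
# association with insulin use emerges mechanically, because only
# patients on a hypoglycemia-associated drug can de-intensify.
DEFAULT_RATE_MODIFIERS: dict[str, dict[str, float]] = {
    "IN": {"insulin_active": 0.18, "female": 0.94, "age_per_decade": 0.80},
    "DI": {"female": 1.12, "age_per_decade": 0.97},
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dispensing-database generator."""

    n_patients: int = 1000
    seed: int = 2016
    start_date: dt.date = dt.date(2011, 1, 1)
    end_date: dt.date = dt.date(2022, 12, 31)
    index_window_start: dt.date = dt.date(2016, 7, 1)
    index_window_end: dt.date = dt.date(2017, 6, 30)
    # None -> calibrated from DEFAULT_CHANGE_TARGETS (see synthetic module)
    annual_change_rates: list[dict[str, dict[str, float]]] | None = None
    rate_modifiers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RATE_MODIFIERS.items()}
    )
    refill_interval_days: tuple[float, float] = (60.0, 15.0)  # mean, sd
    refill_floor_days: float = 14.0
    frac_spot_users: float = 0.02
    frac_insulin_only_preindex: float = 0.02
    frac_short_registration: float = 0.49
    age_distribution: tuple[float, float] = (66.19, 11.11)  # at 2016-07-01
    frac_female: float = 0.482
    frac_premixed_insulin: float = 0.15
    frac_antidepressant: float = 0.20
    filler_drug_mean: float = 3.0
    initial_regimen_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_INITIAL_REGIMEN_COUNTS)
    )
    risk_coefficients: dict[str, float] | None = None  # None -> module default

    def __post_init__(self) -> None:
        for f in ("start_date", "end_date", "index_window_start", "index_window_end"):
            setattr(self, f, _as_date(getattr(self, f)))
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_patients, int) or self.n_patients <= 0:
            raise ConfigurationError("n_patients must be a positive integer")
        if self.start_date >= self.end_date:
            raise ConfigurationError("start_date must precede end_date")
        if self.index_window_start >= self.index_window_end:
            raise ConfigurationError(
                "index_window_start must precede index_window_end"
            )
        mean, sd = self.refill_interval_days
        if mean <= 0 or sd < 0:
            raise ConfigurationError(
                "refill_interval_days mean must be > 0 and sd >= 0"
            )
        if self.refill_floor_days <= 0:
            raise ConfigurationError("refill_floor_days must be > 0")
        for f in (
            "frac_spot_users",
            "frac_insulin_only_preindex",
            "frac_short_registration",
            "frac_female",
            "frac_premixed_insulin",
            "frac_antidepressant",
        ):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{f} must be in [0, 1]")
        edge = (
            self.frac_spot_users
            + self.frac_insulin_only_preindex
            + self.frac_short_registration
        )
        if edge > 1.0:
            raise ConfigurationError(
                "frac_spot_users + frac_insulin_only_preindex + "
                "frac_short_registration must not exceed 1"
            )
        if self.filler_drug_mean < 0:
            raise ConfigurationError("filler_drug_mean must be >= 0")
        if self.age_distribution[1] <= 0:
            raise ConfigurationError("age_distribution sd must be > 0")
        if self.annual_change_rates is not None:
            for piece in self.annual_change_rates:
                for src, row in piece.items():
                    for dest, p in row.items():
                        if p < 0:
                            raise ConfigurationError(
                                f"annual_change_rates[{src}->{dest}] must be >= 0"
                            )
        unknown = set(self.initial_regimen_counts) - set(
            DEFAULT_INITIAL_REGIMEN_COUNTS
        )
        if unknown:
            raise ConfigurationError(
                f"initial_regimen_counts has unknown regimen labels: {unknown}"
            )


@dataclass
class CohortConfig:
    """Selection rules for the prevalent-user cohort."""

    index_window_start: dt.date = dt.date(2016, 7, 1)
    index_window_end: dt.date = dt.date(2017, 6, 30)
    min_age_at_index: int = 35
    min_a10_dispensings: int = 2
    lookahead_days: int = 365
    required_pre_years: int = 5
    required_post_years: int = 5
    # hook for screening out database test ("dummy") patients; off by default
    dummy_id_predicate: Callable[[str], bool] | None = None

    def __post_init__(self) -> None:
        self.index_window_start = _as_date(self.index_window_start)
        self.index_window_end = _as_date(self.index_window_end)
        if self.index_window_start >= self.index_window_end:
            raise ConfigurationError(
                "index_window_start must precede index_window_end"
            )
        for f in (
            "min_age_at_index",
            "min_a10_dispensings",
            "lookahead_days",
            "required_pre_years",
            "required_post_years",
        ):
            if getattr(self, f) <= 0:
                raise ConfigurationError(f"{f} must be positive")


@dataclass
class MarkovConfig:
    """Estimation settings for the piecewise-constant multi-state model."""

    bootstrap_draws: int = 500
    ci_method: str = "bootstrap"  # or "delta"
    seed: int = 0
    gtol: float = 1e-6
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.bootstrap_draws <= 0:
            raise ConfigurationError("bootstrap_draws must be positive")
        if self.ci_method not in ("bootstrap", "delta"):
            raise ConfigurationError("ci_method must be 'bootstrap' or 'delta'")


@dataclass
class PipelineConfig:
    """End-to-end run configuration (simulate or load, then analyse)."""

    simulation: SimulationConfig | None = None
    patients_path: str | None = None
    dispensings_path: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    markov: MarkovConfig = field(default_factory=MarkovConfig)
    window_days: int = 45
    risk_coefficients_path: str | None = None
    risk_cutoff: float = 0.6
    outdir: str = "out"

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_paths = self.patients_path is not None or self.dispensings_path is not None
        if has_sim and has_paths:
            raise ConfigurationError(
                "exactly one of (simulation block, input paths) may be set"
            )
        if has_paths and (self.patients_path is None or self.dispensings_path is None):
            raise ConfigurationError(
                "both patients_path and dispensings_path are required"
            )
        if self.window_days <= 0:
            raise ConfigurationError("window_days must be positive")
        if not 0.0 <= self.risk_cutoff <= 1.0:
            raise ConfigurationError("risk_cutoff must be in [0, 1]")


def _dataclass_from_mapping(cls, mapping, name):
    if mapping is None:
        return None
    if not isinstance(mapping, dict):
        raise ConfigurationError(f"{name} block must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigurationError(f"unknown {name} fields: {sorted(unknown)}")
    coerced = dict(mapping)
    if "refill_interval_days" in coerced and coerced["refill_interval_days"] is not None:
        coerced["refill_interval_days"] = tuple(coerced["refill_interval_days"])
    if "age_distribution" in coerced and coerced["age_distribution"] is not None:
        coerced["age_distribution"] = tuple(coerced["age_distribution"])
    return cls(**coerced)


def load_pipeline_config(path) -> PipelineConfig:
    """Read a YAML pipeline configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = _dataclass_from_mapping(SimulationConfig, raw.get("simulation"), "simulation")
    cohort = (
        _dataclass_from_mapping(CohortConfig, raw.get("cohort"), "cohort")
        or CohortConfig()
    )
    markov = (
        _dataclass_from_mapping(MarkovConfig, raw.get("markov"), "markov")
        or MarkovConfig()
    )
    inputs = raw.get("inputs") or {}
    return PipelineConfig(
        simulation=sim,
        patients_path=inputs.get("patients"),
        dispensings_path=inputs.get("dispensings"),
        cohort=cohort,
        markov=markov,
        window_days=int(raw.get("window_days", 45)),
        risk_coefficients_path=raw.get("risk_coefficients"),
        risk_cutoff=float(raw.get("risk_cutoff", 0.6)),
        outdir=str(raw.get("outdir", "out")),
    )
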