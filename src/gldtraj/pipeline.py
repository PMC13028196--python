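"""End-to-end orchestration: simulate → cohort → classify → tabulate →
fit-msm → score → fit-regression.

Each stage reads its upstream artifacts from the output directory and
writes its own CSVs plus manifest lines (file, rows, checksum) to a
deterministic run log.  All randomness flows from configuration seeds,
so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import change, cohort, inference, markov, riskscore, synthetic
from .config import PipelineConfig

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "cohort", "classify", "tabulate",
    "fit-msm", "score", "fit-regression",
)


class PipelineError(RuntimeError):
    pass


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _log(out: Path, lines: list[str]) -> None:
    with open(out / "run.log", "a") as fh:
        for line in lines:
            fh.write(line + "\n")


def _write(out: Path, name: str, df: pd.DataFrame) -> str:
    path = out / name
    df.to_csv(path, index=False)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
    return f"manifest {name} rows={len(df)} sha256={digest}"


def _require(out: Path, name: str, needed_by: str, produced_by: str) -> Path:
    path = out / name
    if not path.exists():
        raise PipelineError(
            f"{needed_by!r} needs {name}; run the {produced_by!r} "
            "subcommand first"
        )
    return path


def stage_simulate(config: PipelineConfig) -> None:
    if config.simulation is None:
        raise PipelineError(
            "no simulation block configured; provide input tables instead"
        )
    out = _outdir(config)
    patients, dispensings = synthetic.generate_population(config.simulation)
    synthetic.write_tables(
        patients, dispensings, out / "patients.csv", out / "dispensings.csv"
    )
    lines = [f"stage simulate seed={config.simulation.seed} "
             f"n_patients={config.simulation.n_patients}"]
    for name, df in (("patients.csv", patients), ("dispensings.csv", dispensings)):
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()[:16]
        lines.append(f"manifest {name} rows={len(df)} sha256={digest}")
    _log(out, lines)


def _load_tables(config: PipelineConfig, out: Path):
    if config.patients_path is not None:
        ppath, dpath = Path(config.patients_path), Path(config.dispensings_path)
        if not ppath.exists() or not dpath.exists():
            raise PipelineError("configured input tables do not exist")
    else:
        ppath = _require(out, "patients.csv", "cohort", "simulate")
        dpath = _require(out, "dispensings.csv", "cohort", "simulate")
    patients = pd.read_csv(ppath)
    dispensings = pd.read_csv(dpath)
    return patients, dispensings


def stage_cohort(config: PipelineConfig) -> None:
    out = _outdir(config)
    patients, dispensings = _load_tables(config, out)
    members, flow = cohort.select_cohort(patients, dispensings, config.cohort)
    lines = [f"stage cohort retained={len(members)}"]
    lines.append(_write(out, "cohort.csv", members))
    lines.append(_write(out, "flow_report.csv", flow))
    _log(out, lines)


def _load_members(out: Path, needed_by: str) -> pd.DataFrame:
    path = _require(out, "cohort.csv", needed_by, "cohort")
    members = pd.read_csv(path)
    members["index_date"] = pd.to_datetime(members["index_date"]).dt.date
    return members


def stage_classify(config: PipelineConfig) -> None:
    out = _outdir(config)
    members = _load_members(out, "classify")
    _, dispensings = _load_tables(config, out)
    events, net, labels = change.cohort_events(
        members, dispensings, config.window_days
    )
    lines = ["stage classify"]
    lines.append(_write(out, "events.csv", events))
    lines.append(_write(out, "net_outcomes.csv", net))
    lines.append(_write(out, "index_regimens.csv", labels))
    _log(out, lines)


def stage_tabulate(config: PipelineConfig) -> None:
    out = _outdir(config)
    events = pd.read_csv(_require(out, "events.csv", "tabulate", "classify"))
    net = pd.read_csv(_require(out, "net_outcomes.csv", "tabulate", "classify"))
    labels = pd.read_csv(
        _require(out, "index_regimens.csv", "tabulate", "classify")
    )
    members = _load_members(out, "tabulate")
    tables = change.transition_tables(events)
    lines = ["stage tabulate"]
    lines.append(
        _write(out, "transition_tables.csv", change.transition_tables_frame(tables))
    )
    lines.append(_write(out, "subtypes.csv", change.pooled_subtypes(events)))
    lines.append(
        _write(out, "stratified_rates.csv", change.stratified_rates(events, members))
    )
    lines.append(
        _write(out, "net_outcome_shares.csv", change.share_table(net["outcome"]))
    )
    lines.append(
        _write(out, "baseline_regimens.csv",
               change.share_table(labels["regimen_label"]))
    )
    _log(out, lines)


def stage_fit_msm(config: PipelineConfig, plot: bool = False) -> markov.MarkovFit:
    out = _outdir(config)
    events = pd.read_csv(_require(out, "events.csv", "fit-msm", "classify"))
    panel = change.events_to_panel(events)
    fit = markov.fit(panel, config.markov)
    lines = [f"stage fit-msm converged={fit.converged}"]
    lines.append(_write(out, "transition_probabilities.csv", fit.frame()))
    lines.append(
        _write(out, "markov_gof.csv", markov.goodness_of_fit(panel, fit))
    )
    lines.append(_write(out, "markov_report.csv", fit.report()))
    if plot:
        markov.plot_transition_network(fit, out / "transition_network.png")
        lines.append("manifest transition_network.png rows=0 sha256=plot")
    _log(out, lines)
    return fit


def stage_score(config: PipelineConfig) -> None:
    out = _outdir(config)
    members = _load_members(out, "score")
    _, dispensings = _load_tables(config, out)
    if config.risk_coefficients_path:
        coef = riskscore.load_coefficients(config.risk_coefficients_path)
    elif config.simulation is not None and config.simulation.risk_coefficients:
        coef = config.simulation.risk_coefficients
    else:
        coef = riskscore.DEFAULT_COEFFICIENTS
    profiles = riskscore.build_profiles(members, dispensings, config.window_days)
    scores = riskscore.score_table(profiles, coef, config.risk_cutoff)
    lines = ["stage score"]
    lines.append(_write(out, "risk_profiles.csv", profiles))
    lines.append(_write(out, "risk_scores.csv", scores))
    _log(out, lines)


def stage_fit_regression(config: PipelineConfig) -> pd.DataFrame:
    out = _outdir(config)
    members = _load_members(out, "fit-regression")
    net = pd.read_csv(
        _require(out, "net_outcomes.csv", "fit-regression", "classify")
    )
    scores = pd.read_csv(
        _require(out, "risk_scores.csv", "fit-regression", "score")
    )
    design = inference.build_design(members, net, scores)
    try:
        table = inference.fit_models(design)
        lines = ["stage fit-regression"]
    except ValueError as exc:
        # degenerate cohorts (e.g. every outcome NC) have nothing to model
        logger.warning("regression skipped: %s", exc)
        table = pd.DataFrame(
            columns=["model", "outcome", "factor", "level", "odds_ratio",
                     "ci_low", "ci_high", "p_value", "significant"]
        )
        lines = [f"stage fit-regression skipped: {exc}"]
    lines.append(_write(out, "odds_ratios.csv", table))
    _log(out, lines)
    return table


def run(subcommand: str, config: PipelineConfig, plot: bool = False) -> None:
    """Run one pipeline stage (or 'all')."""
    stages = {
        "simulate": stage_simulate,
        "cohort": stage_cohort,
        "classify": stage_classify,
        "tabulate": stage_tabulate,
        "fit-msm": stage_fit_msm,
        "score": stage_score,
        "fit-regression": stage_fit_regression,
    }
    if subcommand == "all":
        out = _outdir(config)
        (out / "run.log").write_text("")  # fresh deterministic log
        _log(out, [f"config {config_summary(config)}"])
        if config.simulation is not None:
            stage_simulate(config)
        stage_cohort(config)
        stage_classify(config)
        stage_tabulate(config)
        stage_fit_msm(config, plot=plot)
        stage_score(config)
        stage_fit_regression(config)
        return
    if subcommand not in stages:
        raise PipelineError(
            f"unknown subcommand {subcommand!r}; choose from "
            f"{('all',) + STAGES}"
        )
    if subcommand == "fit-msm":
        stages[subcommand](config, plot=plot)
    else:
        stages[subcommand](config)


def config_summary(config: PipelineConfig) -> str:
    d = dataclasses.asdict(config)
    d.pop("outdir", None)  # location, not analysis configuration
    if d.get("simulation") and d["simulation"].get("annual_change_rates"):
        d["simulation"]["annual_change_rates"] = "<explicit>"
    if d.get("cohort"):
        d["cohort"].pop("dummy_id_predicate", None)
    return repr(d)
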