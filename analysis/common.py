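"""Shared configuration for the numbered analysis drivers.

The pipeline works in ``scratch/pipeline`` (large intermediate tables);
each driver publishes its small summary tables to ``results/``.  The
default database size keeps a single step under a minute while leaving
several thousand cohort members for stable rates.
"""

import shutil
from pathlib import Path

from gldtraj.config import (
    CohortConfig,
    MarkovConfig,
    PipelineConfig,
    SimulationConfig,
)

ROOT = Path(__file__).resolve().parent.parent
OUTDIR = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def pipeline_config(n_patients: int = 12000, seed: int = 2016) -> PipelineConfig:
    return PipelineConfig(
        simulation=SimulationConfig(n_patients=n_patients, seed=seed),
        cohort=CohortConfig(),
        markov=MarkovConfig(bootstrap_draws=500, seed=seed + 1),
        outdir=str(OUTDIR),
    )


def publish(*names: str) -> None:
    """Copy small summary tables from the workspace into results/."""
    RESULTS.mkdir(parents=True, exist_ok=True)
    for name in names:
        shutil.copy2(OUTDIR / name, RESULTS / name)
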