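#!/usr/bin/env python
"""Classify annual treatment changes and the net five-year outcome.

Each patient-interval becomes NC (no change), IN (intensification) or
DI (de-intensification) of hypoglycemia-associated medication, from the
±45-day anniversary snapshots.
"""

import pandas as pd

from common import OUTDIR, pipeline_config
from gldtraj import pipeline

cfg = pipeline_config()
pipeline.run("classify", cfg)

events = pd.read_csv(OUTDIR / "events.csv")
net = pd.read_csv(OUTDIR / "net_outcomes.csv")
print("per-interval state frequencies (%):")
freq = (events.groupby("interval_index")["state"]
        .value_counts(normalize=True).unstack() * 100).round(1)
print(freq.to_string())
print("\nnet 5-year outcome (%):")
print((net["outcome"].value_counts(normalize=True) * 100).round(1).to_string())
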