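#!/usr/bin/env python
"""Tabulate transition matrices, pooled change subtypes, stratified
crude rates and the baseline regimen mix."""

import pandas as pd

from common import OUTDIR, pipeline_config, publish
from gldtraj import pipeline

cfg = pipeline_config()
pipeline.run("tabulate", cfg)

subtypes = pd.read_csv(OUTDIR / "subtypes.csv")
baseline = pd.read_csv(OUTDIR / "baseline_regimens.csv")
print("top treatment-change subtypes per category:")
print(subtypes.groupby("category").head(3).to_string(index=False))
print("\nbaseline regimen mix (top 5):")
print(baseline.head(5).to_string(index=False))

publish('transition_tables.csv', 'subtypes.csv', 'stratified_rates.csv', 'net_outcome_shares.csv', 'baseline_regimens.csv')
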