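#!/usr/bin/env python
"""Simulate the synthetic community-pharmacy dispensing database.

Writes patients.csv and dispensings.csv under results/pipeline and
reports the table sizes and the edge-case mix.
"""

import pandas as pd

from common import OUTDIR, pipeline_config
from gldtraj import pipeline

cfg = pipeline_config()
pipeline.run("simulate", cfg)

patients = pd.read_csv(OUTDIR / "patients.csv")
dispensings = pd.read_csv(OUTDIR / "dispensings.csv")
print(f"simulated {len(patients)} patients, {len(dispensings)} dispensings")
print(f"date range {dispensings['dispense_date'].min()} .. "
      f"{dispensings['dispense_date'].max()}")
a10 = dispensings["atc_code"].str.startswith("A10").mean()
print(f"{100 * a10:.1f}% of dispensings are glucose-lowering (A10)")
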