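#!/usr/bin/env python
"""Score hypoglycemia risk at index and fit the multinomial outcome
models (Model 1: risk + sex + age; Model 2: risk only)."""

import pandas as pd

from common import OUTDIR, pipeline_config, publish
from gldtraj import pipeline

cfg = pipeline_config()
pipeline.run("score", cfg)
pipeline.run("fit-regression", cfg)

scores = pd.read_csv(OUTDIR / "risk_scores.csv")
print(f"high-risk share: {100 * (scores['category'] == 'high').mean():.1f}%")
ors = pd.read_csv(OUTDIR / "odds_ratios.csv")
print("\nodds ratios (NC reference):")
cols = ["model", "outcome", "factor", "level", "odds_ratio",
        "ci_low", "ci_high", "significant"]
print(ors[cols].round(3).to_string(index=False))

publish('odds_ratios.csv')
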