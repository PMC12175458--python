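#!/usr/bin/env python
"""Correlate discriminant metabolites with bioactivity and write the report.

Pearson correlation between group-mean intensities of the significantly
different features (one-way ANOVA, p < 0.05) and each activity readout,
followed by the prioritization bundle (heat maps + merged annotation CSV).
"""

import pandas as pd

from actinomet.pipeline import PipelineConfig, stage_correlate, stage_report

cfg = PipelineConfig(outdir="results/run", seed=1)
stage_correlate(cfg)
written = stage_report(cfg)

r = pd.read_csv("results/run/correlation_r.csv", index_col=0)
print(f"Correlation matrix: {r.shape[0]} significant features x "
      f"{r.shape[1]} activity readouts")
strongest = r.abs().max(axis=1).sort_values(ascending=False).head(10)
print("\nStrongest feature-activity correlations (|r| max per feature):")
for fid, val in strongest.items():
    col = r.loc[fid].abs().idxmax()
    print(f"  {fid:>6}  r = {r.loc[fid, col]:+.3f}  vs {col}")

print("\nReport bundle:")
for key, path in written.items():
    print(f"  {key}: {path}")
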