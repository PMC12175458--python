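#!/usr/bin/env python
"""Clean the feature tables: blank removal, medium subtraction, mode merge.

Features louder than 1e4 in any solvent blank are discarded; the rest must
beat the ISP-2 medium by at least 20x. The surviving positive- and
negative-mode features are stacked into one matrix for modelling.
"""

import pandas as pd

from actinomet.pipeline import PipelineConfig, stage_preprocess

cfg = PipelineConfig(outdir="results/run", seed=1)
merged_path = stage_preprocess(cfg)

report = pd.read_csv("results/run/filter_report.csv", index_col=0)
print("Per-mode feature counts through the cleanup rules:")
print(report.to_string())
print(f"\nMerged table: {merged_path}")
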