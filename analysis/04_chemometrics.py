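#!/usr/bin/env python
"""Multivariate modelling of the cleaned profiles.

Fits PCA (with the 95% Hotelling ellipse), multi-group PLS-DA with VIP
scores, OPLS-DA with its S-plot, and a random-forest top-15 ranking; prints
the fit statistics and which samples fall outside the confidence ellipse.
"""

from pathlib import Path

import pandas as pd

from actinomet.pipeline import PipelineConfig, stage_model

cfg = PipelineConfig(outdir="results/run", seed=1)
paths = stage_model(cfg)

print(Path(paths["fit_report"]).read_text())

scores = pd.read_csv(paths["pca_scores"], index_col=0)
outliers = scores[scores["outlier"]]
print("Samples outside the 95% Hotelling ellipse:")
print(outliers[["label", "t1", "t2", "hotelling_t2"]].to_string())

vip = pd.read_csv(paths["vip"], index_col=0)["VIP"]
print(f"\nFeatures with VIP > 1: {(vip > 1).sum()} of {len(vip)}")
print("Top-15 random-forest features written to", paths["rf"])
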