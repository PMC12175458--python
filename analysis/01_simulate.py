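#!/usr/bin/env python
"""Generate the synthetic screening experiment all later steps analyse.

Writes the two ionization-mode feature tables, the bioactivity table, the
dereplication library (planted compounds + mass decoys) and the ground
truth under results/run/.
"""

from actinomet.pipeline import PipelineConfig, stage_simulate

cfg = PipelineConfig(outdir="results/run", seed=1)
paths = stage_simulate(cfg)

print("Simulated experiment written:")
for key, path in paths.items():
    print(f"  {key:>13}: {path}")
print(
    "\n8 isolate groups x 3 replicates + blanks, media and pooled QCs,"
    "\ntwo ionization modes, planted marker clusters and library matches."
)
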