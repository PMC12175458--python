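#!/usr/bin/env python
"""Bioactivity analysis on the bundled screening tables.

Applies the >= 12 mm positivity rule to the inhibition-zone matrix of the
eight prioritized isolates, then compares each isolate's MCF-7 IC50 with
the matched normal-cell (HSF) IC50 by an unpaired t-test on simulated
triplicates drawn from the published mean +- SD.
"""

import numpy as np

from actinomet import bioassoc
from actinomet.datasets import load_cytotoxicity, load_demo_bioactivity

bt = load_demo_bioactivity()
calls = bioassoc.classify_zones(bt, cutoff=12.0)
counts = bioassoc.activity_counts(calls)
print("Active isolates per test organism (zone >= 12 mm):")
print(counts.to_string())

print("\nMCF-7 vs HSF IC50 (unpaired t-test on triplicates from mean +- SD):")
cyto = load_cytotoxicity().set_index(["group", "cell_line"])
rng = np.random.default_rng(1)
for group in bt.groups:
    try:
        m1, s1 = cyto.loc[(group, "MCF-7")]
        m2, s2 = cyto.loc[(group, "HSF")]
    except KeyError:
        continue
    if np.isnan(m1) or np.isnan(m2):
        print(f"  isolate {group:>2}: IC50 not reached on one side (NA)")
        continue
    a = rng.normal(m1, s1, 3)
    b = rng.normal(m2, s2, 3)
    t, p = bioassoc.compare_ic50(a, b)
    flag = "*" if p < 0.05 else " "
    print(f"  isolate {group:>2}: MCF-7 {m1:6.2f} vs HSF {m2:6.2f} ug/mL, "
          f"p = {p:.4f}{flag}")
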