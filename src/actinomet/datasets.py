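"""Bundled reference tables for the eight prioritized marine actinomycetes.

The package ships three small CSVs used throughout the documentation, the
analysis drivers and the tests:

* ``inhibition_zones.csv`` — agar-diffusion zones (mm) of the eight
  bioactive isolates (seven *Streptomyces*, one *Brevibacterium*) against
  reference and multidrug-resistant strains; ``NA`` = no inhibition.
* ``cytotoxicity_ic50.csv`` — IC50 mean ± SD (µg/mL, SRB assay, triplicate)
  against MCF-7, HCT-116 and normal HSF cells, plus the 5-FU drug standard.
* ``compound_library.csv`` — natural products with molecular formulas that
  serve as a miniature dereplication library; the same compounds seed the
  synthetic generator's planted annotations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .tabio import BioactivityTable, CompoundLibrary, read_bioactivity, read_compound_library

__all__ = [
    "load_inhibition_zones",
    "load_cytotoxicity",
    "load_demo_bioactivity",
    "load_reference_compounds",
]


def _data_path(name: str):
    return resources.files("actinomet").joinpath("data", name)


def load_inhibition_zones() -> BioactivityTable:
    """Inhibition-zone matrix of the eight prioritized isolates."""
    with resources.as_file(_data_path("inhibition_zones.csv")) as path:
        return read_bioactivity(path)


def load_cytotoxicity() -> pd.DataFrame:
    """Tidy IC50 summary (group, cell_line, ic50_mean, ic50_sd); includes 5-FU."""
    with resources.as_file(_data_path("cytotoxicity_ic50.csv")) as path:
        frame = pd.read_csv(path, dtype={"group": str})
    return frame


def load_demo_bioactivity() -> BioactivityTable:
    """Zones plus MCF-7/HSF/HCT-116 mean IC50s for the eight isolates."""
    zones = load_inhibition_zones()
    cyto = load_cytotoxicity()
    ic50 = (
        cyto[cyto["group"] != "5-FU"]
        .pivot(index="group", columns="cell_line", values="ic50_mean")
        .reindex(zones.groups)
    )
    ic50.columns.name = None
    return BioactivityTable(zones=zones.zones, ic50=ic50)


def load_reference_compounds() -> CompoundLibrary:
    """The miniature natural-product library used for dereplication demos."""
    with resources.as_file(_data_path("compound_library.csv")) as path:
        return read_compound_library(path)
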