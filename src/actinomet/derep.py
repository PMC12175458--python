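"""Exact-mass dereplication of LC-MS features against a compound library.

Each detected ion is tentatively annotated as a known natural product by
comparing its measured m/z with the theoretical adduct m/z of every library
compound, inside a symmetric ppm window (default 5 ppm). Positive-mode
features are matched as [M+H]+ and negative-mode features as [M-H]-;
[M+Na]+ can be enabled for positive mode. Only singly charged ions are
considered. Features with no compound inside the window are reported as
"no hits" — from a discovery standpoint those are the interesting ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .formulas import (  # noqa: F401  (re-exported: the module's public surface)
    BUILTIN_ADDUCTS,
    DEFAULT_ADDUCTS,
    M_MINUS_H,
    M_PLUS_H,
    M_PLUS_NA,
    PROTON_MASS,
    Adduct,
    adduct_mz,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
)
from .tabio import CompoundLibrary, FeatureTable

__all__ = [
    "DereplicationHit",
    "annotate",
    "hits_frame",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "Adduct",
]


@dataclass(frozen=True)
class DereplicationHit:
    """One (feature, compound, adduct) match inside the ppm tolerance."""

    feature_id: str
    mz_observed: float
    compound: str
    formula: str
    adduct: str
    theoretical_mz: float
    ppm: float


def _feature_mode(ft: FeatureTable, feature_id: str) -> str:
    if ft.mode in ("positive", "negative"):
        return ft.mode
    fid = str(feature_id)
    if fid.startswith("P_"):
        return "positive"
    if fid.startswith("N_"):
        return "negative"
    raise ConfigurationError(
        f"cannot infer ionization mode of feature {feature_id!r} in a merged table"
    )


def annotate(
    ft: FeatureTable,
    lib: CompoundLibrary,
    tolerance: float = 5.0,
    adducts: dict[str, tuple[Adduct, ...]] | None = None,
    include_sodium: bool = False,
) -> list[DereplicationHit]:
    """Match every feature against every (compound, adduct) pair.

    Parameters
    ----------
    tolerance:
        Symmetric ppm window; a hit requires ``|ppm_error| <= tolerance``.
        ``tolerance=0`` keeps only exact m/z equality.
    adducts:
        Mapping mode -> adducts; defaults to [M+H]+ / [M-H]-, plus [M+Na]+
        for positive mode when ``include_sodium`` is set.

    Returns hits grouped by feature (table order), each feature's hits sorted
    by \\|ppm\\| with ties broken by library order, then compound name.
    """
    if len(lib) == 0:
        raise ConfigurationError("compound library is empty")
    if tolerance < 0:
        raise ConfigurationError("tolerance must be >= 0")
    if adducts is None:
        adducts = {
            "positive": (M_PLUS_H, M_PLUS_NA) if include_sodium else (M_PLUS_H,),
            "negative": (M_MINUS_H,),
        }
    # theoretical m/z per mode: rows follow library order
    theo: dict[str, list[tuple[float, int, Adduct]]] = {}
    for mode, adds in adducts.items():
        rows = []
        for i, rec in enumerate(lib):
            for add in adds:
                rows.append((adduct_mz(rec.neutral_mass, add), i, add))
        theo[mode] = rows

    hits: list[DereplicationHit] = []
    for fid in ft.feature_ids:
        mode = _feature_mode(ft, fid)
        observed = float(ft.mz.loc[fid])
        cands = []
        for tmz, i, add in theo.get(mode, ()):
            err = ppm_error(observed, tmz)
            if abs(err) <= tolerance:
                cands.append((abs(err), i, lib[i].name, tmz, add, err))
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        for _, i, name, tmz, add, err in cands:
            hits.append(
                DereplicationHit(
                    feature_id=str(fid),
                    mz_observed=observed,
                    compound=name,
                    formula=lib[i].formula,
                    adduct=add.name,
                    theoretical_mz=tmz,
                    ppm=err,
                )
            )
    return hits


def hits_frame(hits: list[DereplicationHit], ft: FeatureTable | None = None) -> pd.DataFrame:
    """Tabulate hits; with ``ft`` given, unmatched features appear as "no hits"."""
    rows = [
        {
            "feature_id": h.feature_id,
            "mz": h.mz_observed,
            "adduct": h.adduct,
            "compound": h.compound,
            "formula": h.formula,
            "theoretical_mz": h.theoretical_mz,
            "ppm": h.ppm,
        }
        for h in hits
    ]
    frame = pd.DataFrame(
        rows,
        columns=["feature_id", "mz", "adduct", "compound", "formula",
                 "theoretical_mz", "ppm"],
    )
    if ft is not None:
        matched = set(frame["feature_id"])
        missing = [
            {
                "feature_id": str(fid),
                "mz": float(ft.mz.loc[fid]),
                "adduct": "",
                "compound": "no hits",
                "formula": "",
                "theoretical_mz": np.nan,
                "ppm": np.nan,
            }
            for fid in ft.feature_ids
            if str(fid) not in matched
        ]
        if missing and len(frame):
            frame = pd.concat(
                [frame, pd.DataFrame(missing, columns=frame.columns)],
                ignore_index=True,
            )
        elif missing:
            frame = pd.DataFrame(missing, columns=frame.columns)
    return frame
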