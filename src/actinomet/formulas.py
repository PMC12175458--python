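"""Molecular-formula arithmetic: parsing, monoisotopic masses, adduct m/z.

Exact-mass dereplication hinges on three tiny, exact operations: turning a
Hill-notation formula into element counts, summing the most-abundant-isotope
(monoisotopic) masses, and shifting the neutral mass by an ionizing adduct.
Atomic masses come from the NIST table bundled with pyteomics, so carbon is
exactly 12 and, e.g., C24H32N6O4S2 sums to 532.1926 Da ([M+H]+ 533.1999).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from pyteomics import mass as _ptmass

from .exceptions import FormulaError

__all__ = [
    "PROTON_MASS",
    "Adduct",
    "M_PLUS_H",
    "M_MINUS_H",
    "M_PLUS_NA",
    "BUILTIN_ADDUCTS",
    "DEFAULT_ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
]

#: Mass of a proton in Da, the shift of [M+H]+ / [M-H]- ions.
PROTON_MASS = 1.007276

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Adduct:
    """An ionizing adduct: m/z = (neutral + mass_delta) / |charge|."""

    name: str
    mass_delta: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise FormulaError("adduct charge must be non-zero")


M_PLUS_H = Adduct("[M+H]+", +PROTON_MASS, +1)
M_MINUS_H = Adduct("[M-H]-", -PROTON_MASS, -1)
# Na+ = monoisotopic Na minus one electron mass.
M_PLUS_NA = Adduct("[M+Na]+", +22.989218, +1)

BUILTIN_ADDUCTS = {a.name: a for a in (M_PLUS_H, M_MINUS_H, M_PLUS_NA)}

#: Default adduct set per ionization mode; only protonation/deprotonation,
#: matching the annotations this workflow actually reports.
DEFAULT_ADDUCTS = {"positive": (M_PLUS_H,), "negative": (M_MINUS_H,)}


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula into element counts.

    Supports plain element/count tokens (``C24H32N6O4S2``); repeated element
    symbols accumulate. Parentheses and isotope labels are not supported.

    Raises
    ------
    FormulaError
        On empty input, unknown element symbols, explicit zero counts, or
        stray characters.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty molecular formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.end() == pos:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        symbol, digits = m.groups()
        if symbol not in _ptmass.nist_mass:
            raise FormulaError(f"unknown element {symbol!r} in formula {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return counts


def monoisotopic_mass(counts: dict[str, int]) -> float:
    """Monoisotopic neutral mass in Da: sum of most-abundant-isotope masses."""
    if not counts:
        raise FormulaError("element counts are empty")
    total = 0.0
    for symbol, n in counts.items():
        if symbol not in _ptmass.nist_mass:
            raise FormulaError(f"unknown element {symbol!r}")
        if n < 1:
            raise FormulaError(f"non-positive count for element {symbol!r}")
        total += n * _ptmass.nist_mass[symbol][0][0]
    return total


def adduct_mz(neutral_mass: float, adduct: Adduct) -> float:
    """Theoretical m/z of ``adduct`` formed from a neutral monoisotopic mass."""
    if neutral_mass <= 0:
        raise FormulaError("neutral mass must be positive")
    return (neutral_mass + adduct.mass_delta) / abs(adduct.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million.

    Computed against the theoretical mass (the common convention):
    ``(observed - theoretical) / theoretical * 1e6``.
    """
    if theoretical <= 0:
        raise FormulaError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6
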