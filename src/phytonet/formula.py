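"""Molecular-formula arithmetic for small-molecule mass spectrometry.

Monoisotopic masses are the sums of the most-abundant-isotope masses of the
constituent atoms; the protonated ion [M+H]+ observed in positive-mode ESI
adds one proton (not one hydrogen atom — the cation is short one electron).
Mass accuracy is expressed in parts per million (ppm) relative to the
theoretical m/z.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Mapping

__all__ = [
    "FormulaError",
    "ISOTOPE_MASS",
    "PROTON_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "ppm_error",
]


class FormulaError(ValueError):
    """Raised for malformed molecular formulas or unsupported elements."""


#: Most-abundant-isotope masses in Da (CODATA/IUPAC, 7 significant decimals).
#: Extensible: callers may pass a custom table to :func:`monoisotopic_mass`.
ISOTOPE_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
    "P": 30.9737615,
}

#: Mass of the proton in Da, added for the [M+H]+ adduct.
PROTON_MASS: float = 1.00727646

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula_text: str) -> dict[str, int]:
    """Parse a molecular formula string into an element -> count map.

    Accepts plain Hill-style formulas (``"C15H10O7"``), underscore-decorated
    dialects (``"C_15_H_10_O_7_"``), embedded whitespace, and dot-separated
    multi-part formulas for adducts/solvates (``"C14H20O7.NH3"``), whose
    parts are summed.  A missing count means 1.

    Raises
    ------
    FormulaError
        If the string is empty, contains an unsupported element symbol, or
        has characters that are not part of any element token.
    """
    cleaned = re.sub(r"[\s_]+", "", formula_text or "")
    if not cleaned:
        raise FormulaError("empty molecular formula")
    counts: Counter[str] = Counter()
    for part in cleaned.split("."):
        if not part:
            raise FormulaError(f"empty formula component in {formula_text!r}")
        pos = 0
        for match in _TOKEN.finditer(part):
            if match.start() != pos:
                raise FormulaError(
                    f"unparseable fragment {part[pos:match.start()]!r} in {formula_text!r}"
                )
            symbol, digits = match.groups()
            if symbol not in ISOTOPE_MASS:
                raise FormulaError(f"unsupported element symbol {symbol!r} in {formula_text!r}")
            n = int(digits) if digits else 1
            if n < 1:
                raise FormulaError(f"non-positive count for {symbol!r} in {formula_text!r}")
            counts[symbol] += n
            pos = match.end()
        if pos != len(part):
            raise FormulaError(f"unparseable fragment {part[pos:]!r} in {formula_text!r}")
    return dict(counts)


def monoisotopic_mass(
    composition: Mapping[str, int],
    mass_table: Mapping[str, float] = ISOTOPE_MASS,
) -> float:
    """Monoisotopic mass in Da of an element->count composition.

    The empty composition has mass 0.  Unknown elements raise
    :class:`FormulaError`.
    """
    total = 0.0
    for symbol, count in composition.items():
        try:
            total += count * mass_table[symbol]
        except KeyError:
            raise FormulaError(f"no isotope mass for element {symbol!r}") from None
    return total


def protonated_mz(monoisotopic: float) -> float:
    """Theoretical m/z of the [M+H]+ ion for a neutral monoisotopic mass."""
    if monoisotopic <= 0:
        raise ValueError(f"monoisotopic mass must be positive, got {monoisotopic}")
    return monoisotopic + PROTON_MASS


def ppm_error(measured_mz: float, theoretical_mz: float) -> float:
    """Relative mass deviation (measured - theoretical)/theoretical * 1e6."""
    if theoretical_mz <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical_mz}")
    if measured_mz <= 0:
        raise ValueError(f"measured m/z must be positive, got {measured_mz}")
    return (measured_mz - theoretical_mz) / theoretical_mz * 1e6
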