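"""Molecular-formula arithmetic for negative-mode small-molecule MS.

Monoisotopic masses restricted to the CHNOS elements occurring in the
phenolic compound library; [M-H]- is the only adduct the pipeline needs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ATOMIC_MASS",
    "PROTON_MASS",
    "ChemicalFormula",
    "parse_formula",
    "monoisotopic_mz",
    "ppm_error",
]

#: Monoisotopic atomic masses (Da), CODATA/IUPAC values to >=6 decimals.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

#: Mass of a proton (Da); subtracted for the deprotonated [M-H]- ion.
PROTON_MASS = 1.007276

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


@dataclass(frozen=True)
class ChemicalFormula:
    """Element composition of a neutral molecule.

    ``element_counts`` maps element symbols to non-negative integer counts;
    the total atom count must be positive.
    """

    element_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.element_counts or sum(self.element_counts.values()) <= 0:
            raise FormulaError("formula must contain at least one atom")
        for el, n in self.element_counts.items():
            if el not in ATOMIC_MASS:
                raise FormulaError(f"element {el!r} has no monoisotopic mass entry")
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}")

    def hill(self) -> str:
        """Canonical Hill-order string: C, H, then other elements alphabetically."""
        counts = self.element_counts
        order = [e for e in ("C", "H") if counts.get(e)]
        order += sorted(e for e in counts if e not in ("C", "H") and counts[e])
        return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order)

    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return sum(ATOMIC_MASS[e] * n for e, n in self.element_counts.items())

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ChemicalFormula:
    """Parse an element-count formula string such as ``"C16H18O9"``.

    Tolerant of any element ordering; an omitted count means 1. Raises
    :class:`FormulaError` on unknown symbols or non-formula characters.
    """
    if not text or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", text):
        raise FormulaError(f"malformed formula string: {text!r}")
    counts: dict[str, int] = {}
    for el, num in _TOKEN.findall(text):
        if not el:
            continue
        if el not in ATOMIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    return ChemicalFormula(counts)


def monoisotopic_mz(formula: ChemicalFormula | str, mode: str = "[M-H]-") -> float:
    """Theoretical m/z of the deprotonated ion.

    Only the ``"[M-H]-"`` adduct is supported: neutral monoisotopic mass
    minus one proton (1.007276 Da).
    """
    if mode != "[M-H]-":
        raise ValueError(f"unsupported adduct mode {mode!r}; only '[M-H]-' is implemented")
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return formula.monoisotopic_mass() - PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical
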