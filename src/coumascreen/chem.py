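"""Elemental-formula parsing, monoisotopic-mass and adduct arithmetic.

All mass bookkeeping in the package goes through this module: formulas are
parsed into element-count maps, masses are sums of most-abundant-isotope
masses, and positive-mode adduct m/z values are derived from neutral masses.
Matching against observed m/z uses :class:`MassTolerance`, which supports
relative (ppm), absolute (Da) and wider-of-both windows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, Mapping

__all__ = [
    "ElementalComposition",
    "NeutralLoss",
    "MassTolerance",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "within_tolerance",
    "ppm_error",
    "display_round",
    "PROTON_MASS",
    "ISOTOPE_MASSES",
]

# Monoisotopic (most-abundant-isotope) masses, Da. Carbon-12 is exact by
# definition. Extensible via register_element for elements outside CHNOS.
ISOTOPE_MASSES: Dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

#: Mass of the proton, Da. This is the H-atom mass minus the electron mass:
#: protonation adds H+ (no electron), so [M+H]+ = M + 1.0072765.
PROTON_MASS = 1.0072765

# Hill ordering: C first, H second, then the rest alphabetically.
_HILL_ORDER = {"C": 0, "H": 1}


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid molecular formulas."""


def register_element(symbol: str, monoisotopic: float) -> None:
    """Extend the isotope table with an element outside the default CHNOS set."""
    if not re.fullmatch(r"[A-Z][a-z]?", symbol):
        raise FormulaError(f"invalid element symbol: {symbol!r}")
    ISOTOPE_MASSES[symbol] = float(monoisotopic)


@dataclass(frozen=True)
class ElementalComposition:
    """An element -> count map; the unit of all mass arithmetic.

    Counts are non-negative integers; zero counts are dropped on
    construction so that equality and hashing behave set-like.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for el, n in self.counts.items():
            if n < 0:
                raise FormulaError(f"negative count for element {el}: {n}")
            if int(n) != n:
                raise FormulaError(f"non-integer count for element {el}: {n}")
            if n > 0:
                cleaned[el] = int(n)
        object.__setattr__(self, "counts", dict(cleaned))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            new = merged.get(el, 0) - n
            if new < 0:
                raise FormulaError(
                    f"subtraction yields negative count for {el}: "
                    f"{merged.get(el, 0)} - {n}"
                )
            merged[el] = new
        return ElementalComposition(merged)

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition({el: n * k for el, n in self.counts.items()})

    def hill_formula(self) -> str:
        """Canonical Hill-notation string (C, H, then alphabetical)."""
        parts = []
        for el in sorted(self.counts, key=lambda e: (_HILL_ORDER.get(e, 2), e)):
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> ElementalComposition:
    """Parse a Hill-style molecular formula such as ``C10H8O4``.

    Implicit counts of 1 are accepted (``CO2`` -> {C:1, O:2}).  Unknown
    element symbols and empty strings raise :class:`FormulaError`.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula")
    formula = formula.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if m is None or m.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        el, digits = m.groups()
        if el not in ISOTOPE_MASSES:
            raise FormulaError(f"unknown element symbol {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    comp = ElementalComposition(counts)
    if not comp:
        raise FormulaError(f"formula {formula!r} has no atoms")
    return comp


def monoisotopic_mass(comp: ElementalComposition | Mapping[str, int]) -> float:
    """Monoisotopic mass in Da of a composition (sum of isotope masses)."""
    counts = comp.counts if isinstance(comp, ElementalComposition) else comp
    if not counts or not any(n > 0 for n in counts.values()):
        raise FormulaError("empty composition has no mass")
    total = 0.0
    for el, n in counts.items():
        if el not in ISOTOPE_MASSES:
            raise FormulaError(f"no isotope mass for element {el!r}")
        total += ISOTOPE_MASSES[el] * n
    return total


# Positive-mode adducts only; the workflow analyses protonated species.
_ADDUCT_SHIFTS = {
    "[M+H]+": PROTON_MASS,
    "[M+Na]+": 22.9892213,  # Na mass 22.98976928 minus electron
    "[M+NH4]+": 18.0338254,
}


def adduct_mz(neutral_mass: float, adduct: str = "[M+H]+") -> float:
    """m/z of a singly charged adduct of a neutral monoisotopic mass."""
    if adduct not in _ADDUCT_SHIFTS:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(_ADDUCT_SHIFTS)}"
        )
    if neutral_mass < 0:
        raise ValueError("neutral mass must be non-negative")
    return neutral_mass + _ADDUCT_SHIFTS[adduct]


def display_round(value: float, ndigits: int = 2) -> float:
    """Round half-up to `ndigits` decimals, matching printed report precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class NeutralLoss:
    """A neutral moiety departing during fragmentation (e.g. CH3, CO, CO2)."""

    label: str
    composition: ElementalComposition
    mass: float

    def __post_init__(self) -> None:
        expected = monoisotopic_mass(self.composition)
        if abs(expected - self.mass) > 1e-6:
            raise ValueError(
                f"loss {self.label}: stated mass {self.mass} differs from "
                f"composition mass {expected:.6f} by more than 1e-6 Da"
            )

    @classmethod
    def from_formula(cls, label: str, formula: str) -> "NeutralLoss":
        comp = parse_formula(formula)
        return cls(label=label, composition=comp, mass=monoisotopic_mass(comp))


@dataclass(frozen=True)
class MassTolerance:
    """A mass-matching window: relative (ppm), absolute (Da) or the wider of both.

    Parameters
    ----------
    ppm
        Relative tolerance in parts-per-million of the reference m/z.
    dalton
        Absolute tolerance in Da.
    mode
        ``"relative"`` uses the ppm bound, ``"absolute"`` the Da bound,
        ``"wider"`` whichever is larger at the m/z in question.
    """

    ppm: float = 0.0
    dalton: float = 0.0
    mode: str = "relative"

    def __post_init__(self) -> None:
        if self.mode not in ("relative", "absolute", "wider"):
            raise ValueError(f"unknown tolerance mode {self.mode!r}")
        if self.mode in ("relative", "wider") and self.ppm <= 0 and self.mode == "relative":
            raise ValueError("relative tolerance requires ppm > 0")
        if self.mode == "absolute" and self.dalton <= 0:
            raise ValueError("absolute tolerance requires dalton > 0")
        if self.mode == "wider" and self.ppm <= 0 and self.dalton <= 0:
            raise ValueError("wider-of tolerance requires ppm > 0 or dalton > 0")

    def window(self, mz: float) -> float:
        """Effective half-window in Da at a given m/z; strictly positive."""
        if mz <= 0:
            raise ValueError("m/z must be positive")
        rel = self.ppm * 1e-6 * mz
        if self.mode == "relative":
            return rel
        if self.mode == "absolute":
            return self.dalton
        return max(rel, self.dalton)


#: Precursor-level default: 10 ppm, the tolerance used for MS1/MS2 matching.
PRECURSOR_TOLERANCE = MassTolerance(ppm=10.0)

#: Fragment-level default: the wider of 20 ppm and 0.01 Da, reflecting the
#: 2-decimal precision at which fragment ions are reported.
FRAGMENT_TOLERANCE = MassTolerance(ppm=20.0, dalton=0.01, mode="wider")


def within_tolerance(observed: float, theoretical: float, tol: MassTolerance) -> bool:
    """True iff two m/z values agree within the tolerance window.

    Symmetric in its two m/z arguments: the window is evaluated at the mean
    of the two values, so swapping arguments cannot flip the outcome.
    """
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    mid = 0.5 * (observed + theoretical)
    return abs(observed - theoretical) <= tol.window(mid)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative error of `observed` vs `theoretical`, in ppm."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6
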