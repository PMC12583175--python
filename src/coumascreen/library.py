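"""In-house compound library: construction, merging, deduplication, lookup.

The library merges taxon-specific literature compounds with high-confidence
public spectral-library matches (admitted above a similarity score cut-off),
recomputes every [M+H]+ m/z from the molecular formula, and answers
precursor-window queries.

The packaged starter library carries the coumarins, cinnamic acids and
flavonoids of *Chimonanthus* chemistry that the pipeline's worked examples
use. The bicoumarin formulas (chimsalicifoliusins, biisofraxidins) were
inferred from their reported protonated masses rather than taken from a
structure database.
"""

from __future__ import annotations

import csv
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

from .chem import (
    ElementalComposition,
    FormulaError,
    MassTolerance,
    PRECURSOR_TOLERANCE,
    adduct_mz,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    within_tolerance,
)

__all__ = [
    "LibraryCompound",
    "Library",
    "build_library",
    "match_precursor",
    "load_library",
    "starter_library",
    "canonical_name",
]

COMPOUND_CLASSES = {
    "coumarin",
    "cinnamic_acid",
    "flavonoid",
    "alkaloid",
    "fatty_acid",
    "benzene_derivative",
    "terpenoid",
    "other",
}

_PUNCT = re.compile(r"[\s\-'\",.()\[\]]+")


def canonical_name(name: str) -> str:
    """Dedup key: case-folded with punctuation and whitespace stripped."""
    return _PUNCT.sub("", name.casefold())


@dataclass(frozen=True)
class LibraryCompound:
    """A reference metabolite: name, formula, [M+H]+ m/z and class labels."""

    name: str
    formula: ElementalComposition
    neutral_mass: float
    mh_mz: float
    compound_class: str = "other"
    subclass: Optional[str] = None
    source: str = "literature"
    score: Optional[float] = None

    def __post_init__(self) -> None:
        expected = adduct_mz(self.neutral_mass, "[M+H]+")
        if abs(expected - self.mh_mz) > 1e-4:
            raise ValueError(
                f"{self.name}: mh_mz {self.mh_mz} inconsistent with neutral "
                f"mass (expected {expected:.4f})"
            )
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(
                f"{self.name}: unknown compound class {self.compound_class!r}"
            )

    @classmethod
    def from_formula(
        cls,
        name: str,
        formula: str | ElementalComposition,
        compound_class: str = "other",
        subclass: Optional[str] = None,
        source: str = "literature",
        score: Optional[float] = None,
    ) -> "LibraryCompound":
        comp = parse_formula(formula) if isinstance(formula, str) else formula
        mass = monoisotopic_mass(comp)
        return cls(
            name=name,
            formula=comp,
            neutral_mass=mass,
            mh_mz=adduct_mz(mass, "[M+H]+"),
            compound_class=compound_class,
            subclass=subclass,
            source=source,
            score=score,
        )


@dataclass
class Library:
    """A deduplicated compound collection with an m/z-sorted lookup index."""

    compounds: List[LibraryCompound] = field(default_factory=list)

    def __post_init__(self) -> None:
        order = sorted(range(len(self.compounds)), key=lambda i: self.compounds[i].mh_mz)
        self._sorted = [self.compounds[i] for i in order]
        self._sorted_mz = [c.mh_mz for c in self._sorted]
        seen = {}
        for c in self.compounds:
            key = canonical_name(c.name)
            if key in seen:
                raise ValueError(f"duplicate compound name after canonicalization: {c.name!r}")
            seen[key] = c

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    def get(self, name: str) -> Optional[LibraryCompound]:
        key = canonical_name(name)
        for c in self.compounds:
            if canonical_name(c.name) == key:
                return c
        return None

    def by_class(self, compound_class: str) -> List[LibraryCompound]:
        return [c for c in self.compounds if c.compound_class == compound_class]

    def window(self, lo_mz: float, hi_mz: float) -> List[LibraryCompound]:
        """Compounds with [M+H]+ m/z in [lo_mz, hi_mz]."""
        i = bisect_left(self._sorted_mz, lo_mz)
        j = bisect_right(self._sorted_mz, hi_mz)
        return self._sorted[i:j]


def build_library(
    literature_entries: Iterable[Mapping],
    public_entries: Iterable[Mapping] = (),
    min_public_score: float = 0.9,
) -> Tuple[Library, List[str]]:
    """Merge literature and public-match entries into a deduplicated library.

    Entries are mappings with keys ``name``, ``formula``, ``class`` and
    optionally ``subclass``; public entries additionally carry ``score``
    and are admitted only when score > `min_public_score`. The [M+H]+ m/z
    is always recomputed from the formula. Duplicates (same canonical name)
    are merged with ``source="both"``. Entries whose formula fails to parse
    are rejected and reported, not fatal.

    Returns the library and the list of rejection messages.
    """
    rejects: List[str] = []
    merged: dict[str, LibraryCompound] = {}

    def _admit(entry: Mapping, source: str) -> None:
        name = str(entry["name"]).strip()
        try:
            compound = LibraryCompound.from_formula(
                name=name,
                formula=str(entry["formula"]),
                compound_class=str(entry.get("class", "other")),
                subclass=entry.get("subclass") or None,
                source=source,
                score=entry.get("score"),
            )
        except (FormulaError, ValueError) as exc:
            rejects.append(f"{name}: {exc}")
            return
        key = canonical_name(name)
        if key in merged:
            prior = merged[key]
            if prior.source != source:
                merged[key] = LibraryCompound.from_formula(
                    name=prior.name,
                    formula=prior.formula,
                    compound_class=prior.compound_class,
                    subclass=prior.subclass,
                    source="both",
                    score=prior.score if prior.score is not None else compound.score,
                )
        else:
            merged[key] = compound

    for entry in literature_entries:
        _admit(entry, str(entry.get("source", "literature")) or "literature")
    for entry in public_entries:
        score = entry.get("score")
        if score is None or float(score) <= min_public_score:
            continue
        _admit(dict(entry, score=float(score)), "public_match")

    return Library(compounds=list(merged.values())), rejects


def match_precursor(
    lib: Library,
    precursor_mz: float,
    tol: MassTolerance = PRECURSOR_TOLERANCE,
) -> List[LibraryCompound]:
    """All library entries whose [M+H]+ m/z matches the precursor within `tol`.

    Sorted by absolute ppm deviation, ascending; multiple isomers can be
    returned and are left for manual review downstream.
    """
    if precursor_mz <= 0:
        raise ValueError("precursor m/z must be positive")
    halfwidth = tol.window(precursor_mz) * 1.5  # generous pre-window; exact check below
    hits = [
        c
        for c in lib.window(precursor_mz - halfwidth, precursor_mz + halfwidth)
        if within_tolerance(precursor_mz, c.mh_mz, tol)
    ]
    hits.sort(key=lambda c: (abs(ppm_error(precursor_mz, c.mh_mz)), c.name))
    return hits


_LIB_COLUMNS = ("name", "formula", "class", "subclass", "source", "score")


def load_library(path: str | Path, min_public_score: float = 0.9) -> Library:
    """Load a library from delimited text (columns: name, formula, class,
    subclass, source, score) and merge/dedup it through :func:`build_library`."""
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.readline()
        delimiter = "\t" if sample.count("\t") > sample.count(",") else ","
        fh.seek(0)
        rows = list(csv.DictReader(fh, delimiter=delimiter))
    literature, public = [], []
    for row in rows:
        entry = {k: (row.get(k) or None) for k in _LIB_COLUMNS}
        entry["name"] = row["name"]
        entry["formula"] = row["formula"]
        entry["class"] = row.get("class") or "other"
        if entry.get("score"):
            entry["score"] = float(entry["score"])
        if (row.get("source") or "literature") == "public_match":
            public.append(entry)
        else:
            literature.append(entry)
    lib, rejects = build_library(literature, public, min_public_score=min_public_score)
    if rejects:
        raise ValueError(f"library {path.name}: unparseable entries: {rejects}")
    return lib


def save_library(lib: Library, path: str | Path) -> None:
    """Write a library in the same delimited schema `load_library` reads."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LIB_COLUMNS)
        for c in sorted(lib.compounds, key=lambda c: c.name):
            writer.writerow(
                [
                    c.name,
                    c.formula.hill_formula(),
                    c.compound_class,
                    c.subclass or "",
                    c.source,
                    "" if c.score is None else c.score,
                ]
            )


def starter_library() -> Library:
    """The packaged starter library of coumarins, cinnamic acids and flavonoids."""
    ref = resources.files("coumascreen.data").joinpath("starter_library.csv")
    with resources.as_file(ref) as path:
        return load_library(path)
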