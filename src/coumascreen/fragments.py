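"""Neutral-loss ladders, diagnostic-ion scoring and class/linkage calls.

Positive-mode coumarins fragment by sequential small neutral losses from
[M+H]+ — CH3 (radical), CHO, CO, CO2, C2H2 — producing characteristic
fragment-ion ladders; cinnamic acids lose H2O and CO, with an additional
15 Da CH3 loss when methoxylated. This module generates those ladders
in silico, detects neutral losses in observed spectra (precursor-to-peak
and peak-to-peak), scores spectra against diagnostic-ion sets, calls
compound classes from loss patterns, and discriminates C-O- from
C-C-linked coumarin dimers by which fragmentation regime dominates.

The engine tracks m/z only, not electron parity: radical losses such as
CH3* yield odd-electron fragments, but annotation works purely on mass
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .chem import (
    FRAGMENT_TOLERANCE,
    MassTolerance,
    NeutralLoss,
    display_round,
    within_tolerance,
)
from .spectra import Spectrum

__all__ = [
    "LossCatalog",
    "FragmentLadder",
    "ClassRule",
    "LossEvidence",
    "default_loss_catalog",
    "default_class_rules",
    "generate_ladder",
    "detect_neutral_losses",
    "diagnostic_ion_score",
    "classify_class",
    "classify_dimer_linkage",
]

#: Default catalog: label -> formula of the departing neutral.
_DEFAULT_LOSSES = {
    "CH3": "CH3",
    "CHO": "CHO",
    "CO": "CO",
    "CO2": "CO2",
    "C2H2": "C2H2",
    "H2O": "H2O",
    "CH2": "CH2",
}

#: Optional extra hydrogen-loss step. Some published coumarin fragment
#: annotations sit ~1.008 Da below the mass implied by their loss labels
#: (an unannotated H loss); enabling "H" in a ladder reproduces them.
HYDROGEN_LOSS = NeutralLoss.from_formula("H", "H")


@dataclass(frozen=True)
class LossCatalog:
    """A set of named neutral losses with unique labels."""

    losses: Tuple[NeutralLoss, ...]

    def __post_init__(self) -> None:
        labels = [l.label for l in self.losses]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate loss labels in catalog")

    def __iter__(self):
        return iter(self.losses)

    def __contains__(self, label: str) -> bool:
        return any(l.label == label for l in self.losses)

    def __getitem__(self, label: str) -> NeutralLoss:
        for l in self.losses:
            if l.label == label:
                return l
        raise KeyError(f"loss {label!r} not in catalog")

    def labels(self) -> List[str]:
        return [l.label for l in self.losses]

    def mass(self, label: str) -> float:
        return self[label].mass

    @classmethod
    def from_formulas(cls, entries: Dict[str, str]) -> "LossCatalog":
        return cls(tuple(NeutralLoss.from_formula(lbl, f) for lbl, f in entries.items()))

    @classmethod
    def from_file(cls, path: str | Path) -> "LossCatalog":
        """Read a catalog override: one ``label formula`` pair per line."""
        entries: Dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            label, formula = line.split()
            entries[label] = formula
        return cls.from_formulas(entries)

    def with_hydrogen(self) -> "LossCatalog":
        """Catalog extended with the optional single-H loss step."""
        if "H" in self:
            return self
        return LossCatalog(self.losses + (HYDROGEN_LOSS,))


def default_loss_catalog() -> LossCatalog:
    return LossCatalog.from_formulas(_DEFAULT_LOSSES)


@dataclass(frozen=True)
class FragmentLadder:
    """m/z rungs produced by cumulative neutral losses from a start ion."""

    start_mz: float
    steps: Tuple[str, ...]
    rungs: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.rungs):
            raise ValueError("steps and rungs must have equal length")
        prev = self.start_mz
        for mz in self.rungs:
            if mz >= prev:
                raise ValueError("ladder rungs must be strictly decreasing")
            prev = mz

    def display_rungs(self, ndigits: int = 2) -> Tuple[float, ...]:
        """Rungs rounded half-up to report precision."""
        return tuple(display_round(r, ndigits) for r in self.rungs)


def generate_ladder(
    start_mz: float,
    steps: Sequence[str],
    catalog: Optional[LossCatalog] = None,
) -> FragmentLadder:
    """Apply neutral losses sequentially from `start_mz`.

    Rung ``i`` is ``start_mz`` minus the cumulative mass of ``steps[:i+1]``.
    Raises at the first step whose cumulative loss would exceed the start m/z.
    """
    catalog = catalog or default_loss_catalog()
    rungs: List[float] = []
    current = start_mz
    for i, label in enumerate(steps):
        loss = catalog[label]
        current -= loss.mass
        if current <= 0:
            raise ValueError(
                f"cumulative loss exceeds start m/z at step {i} ({label})"
            )
        rungs.append(current)
    return FragmentLadder(start_mz=start_mz, steps=tuple(steps), rungs=tuple(rungs))


@dataclass(frozen=True)
class LossEvidence:
    """One detected neutral loss: the higher and lower m/z of the pair."""

    label: str
    from_mz: float
    to_mz: float
    from_precursor: bool


def detect_neutral_losses(
    spec: Spectrum,
    catalog: Optional[LossCatalog] = None,
    tol: MassTolerance = FRAGMENT_TOLERANCE,
) -> Dict[str, List[LossEvidence]]:
    """Detect catalog losses between the precursor and peaks, and between peaks.

    A loss L is detected iff some ordered pair (higher m/z -> lower m/z),
    drawn from the precursor and the peak list, differs by mass(L) within
    `tol`. Returns every detection with its supporting pair.
    """
    catalog = catalog or default_loss_catalog()
    if not spec.peaks:
        return {}
    points = [(spec.precursor_mz, True)] + [(mz, False) for mz, _ in spec.peaks]
    found: Dict[str, List[LossEvidence]] = {}
    for loss in catalog:
        for hi_mz, is_prec in points:
            target = hi_mz - loss.mass
            if target <= 0:
                continue
            for lo_mz, _ in spec.peaks:
                if lo_mz >= hi_mz:
                    break
                # the lower peak must sit where the higher ion minus the
                # loss mass predicts; window evaluated at fragment scale
                if within_tolerance(lo_mz, target, tol):
                    found.setdefault(loss.label, []).append(
                        LossEvidence(loss.label, hi_mz, lo_mz, is_prec)
                    )
    return found


def diagnostic_ion_score(
    spec: Spectrum,
    diagnostic_mzs: Iterable[float],
    tol: MassTolerance = FRAGMENT_TOLERANCE,
) -> float:
    """Fraction of a diagnostic-ion set present in the spectrum.

    Each diagnostic m/z counts as present when some peak lies within `tol`
    of it. Raises on an empty diagnostic set.
    """
    diagnostics = list(diagnostic_mzs)
    if not diagnostics:
        raise ValueError("diagnostic set must be non-empty")
    if not spec.peaks:
        return 0.0
    hit = 0
    for d in diagnostics:
        if any(within_tolerance(mz, d, tol) for mz, _ in spec.peaks):
            hit += 1
    return hit / len(diagnostics)


@dataclass(frozen=True)
class ClassRule:
    """A compound-class call: required losses plus optional soft evidence.

    ``diagnostic_losses`` must all be detected for the class to be called;
    soft features (e.g. the [M+H-H2O]+ > [M+H-CO]+ intensity ordering of
    cinnamic acids) only adjust rank order among called classes.
    """

    class_name: str
    diagnostic_losses: FrozenSet[str]
    soft_features: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.diagnostic_losses:
            raise ValueError(f"rule {self.class_name}: empty diagnostic loss set")


#: Soft-feature registry: name -> predicate(spec, detected, catalog, tol).
def _water_over_co(spec, detected, catalog, tol) -> bool:
    """[M+H-H2O]+ more intense than [M+H-CO]+ (cinnamic-acid signature)."""

    def precursor_loss_intensity(label: str) -> Optional[float]:
        target = spec.precursor_mz - catalog.mass(label)
        candidates = [
            inten for mz, inten in spec.peaks if within_tolerance(mz, target, tol)
        ]
        return max(candidates) if candidates else None

    ih2o = precursor_loss_intensity("H2O")
    ico = precursor_loss_intensity("CO")
    return ih2o is not None and ico is not None and ih2o > ico


SOFT_FEATURES = {"water_loss_dominates_co": _water_over_co}


def default_class_rules() -> List[ClassRule]:
    """Screening rules for the two classes with established loss signatures."""
    return [
        ClassRule(
            class_name="coumarin",
            diagnostic_losses=frozenset({"CH3", "CO"}),
        ),
        ClassRule(
            class_name="cinnamic_acid",
            diagnostic_losses=frozenset({"H2O", "CO"}),
            soft_features=("water_loss_dominates_co",),
        ),
    ]


def classify_class(
    spec: Spectrum,
    rules: Optional[Sequence[ClassRule]] = None,
    catalog: Optional[LossCatalog] = None,
    tol: MassTolerance = FRAGMENT_TOLERANCE,
) -> List[Tuple[str, Dict]]:
    """Rank compound-class calls for a spectrum.

    A class is called iff all its diagnostic losses are detected; classes
    sharing losses can be called simultaneously (class overlap is real:
    CH3/CO/CO2 losses recur across coumarins, flavonoids and cinnamic
    acids). Soft features adjust rank order only. Returns
    ``[(class_name, evidence_dict), ...]`` best first.
    """
    rules = list(rules) if rules is not None else default_class_rules()
    if not rules:
        raise ValueError("at least one class rule required")
    catalog = catalog or default_loss_catalog()
    detected = detect_neutral_losses(spec, catalog, tol)
    calls: List[Tuple[str, Dict]] = []
    for rule in rules:
        if not rule.diagnostic_losses <= set(detected):
            continue
        soft_hits = [
            name
            for name in rule.soft_features
            if SOFT_FEATURES[name](spec, detected, catalog, tol)
        ]
        evidence = {
            "losses": {lbl: detected[lbl] for lbl in rule.diagnostic_losses},
            "soft_features": soft_hits,
        }
        calls.append((rule.class_name, evidence))
    calls.sort(
        key=lambda c: (
            -len(c[1]["soft_features"]),
            -len(c[1]["losses"]),
            c[0],
        )
    )
    return calls


# Coumarin-monomer loss sequences used to build the "looks like a single
# coumarin" reference ladders for dimer-linkage calls and for synthetic
# spectra: parallel channels starting with methyl radical loss or direct
# CO/H2O expulsion from the lactone.
MONOMER_LOSS_SEQUENCES: Tuple[Tuple[str, ...], ...] = (
    ("CH3", "CHO", "CO2", "CO"),
    ("CH3", "CO2", "C2H2", "CO"),
    ("H2O", "CO", "C2H2", "CO"),
    ("CO", "C2H2", "CO2"),
)

#: The descending small-loss regime of C-O-linked dimers: continuous
#: CH3 / CH2 / CO2 losses walking down from the precursor.
DIMER_SMALL_LOSS_STEPS: Tuple[str, ...] = ("CH3", "CH2", "CO2")

# Loss sequences expected per compound class, used both to build
# per-candidate diagnostic-ion sets and to synthesize reference spectra.
# Cinnamic acids lose water and CO from the carboxyl; methoxylated members
# (ferulic, sinapinic) additionally lose a 15 Da methyl radical.
CLASS_LOSS_SEQUENCES: Dict[str, Tuple[Tuple[str, ...], ...]] = {
    "coumarin": MONOMER_LOSS_SEQUENCES,
    "cinnamic_acid": (
        ("H2O", "CO"),
        ("CO", "C2H2"),
        ("H2O", "CO", "CO"),
    ),
    "flavonoid": (
        ("H2O", "CO"),
        ("CO", "C2H2"),
        ("H2O", "CO2"),
    ),
}

#: Extra channels for methoxylated members of any class.
METHOXYLATED_SEQUENCES: Tuple[Tuple[str, ...], ...] = (
    ("CH3",),
    ("CH3", "H2O", "CO"),
)


def compound_loss_sequences(
    compound_class: str, methoxylated: bool = False
) -> Tuple[Tuple[str, ...], ...]:
    """Loss sequences a compound of this class is expected to show."""
    base = CLASS_LOSS_SEQUENCES.get(compound_class, (("H2O",), ("CO",)))
    if methoxylated:
        base = base + METHOXYLATED_SEQUENCES
    return base


def candidate_diagnostic_set(
    mh_mz: float,
    compound_class: str,
    catalog: Optional[LossCatalog] = None,
    methoxylated: bool = False,
) -> Tuple[float, ...]:
    """Distinct theoretical fragment m/z values for a candidate compound.

    The diagnostic set is the union of the rungs of every class-expected
    loss ladder generated from the candidate's own [M+H]+; duplicates
    arising from commuting loss orders are collapsed.
    """
    catalog = catalog or default_loss_catalog()
    rungs: Set[float] = set()
    for seq in compound_loss_sequences(compound_class, methoxylated):
        try:
            ladder = generate_ladder(mh_mz, seq, catalog)
        except ValueError:
            continue
        rungs.update(ladder.rungs)
    deduped: List[float] = []
    for r in sorted(rungs):
        if not deduped or r - deduped[-1] > 1e-6:
            deduped.append(r)
    return tuple(deduped)


def _matched_intensity(spec: Spectrum, targets: Iterable[float], tol: MassTolerance) -> float:
    total = 0.0
    for mz, inten in spec.peaks:
        if any(within_tolerance(mz, t, tol) for t in targets):
            total += inten
    return total


def classify_dimer_linkage(
    spec: Spectrum,
    monomer_mh_mzs: Sequence[float],
    catalog: Optional[LossCatalog] = None,
    tol: MassTolerance = FRAGMENT_TOLERANCE,
    min_precursor_mz: float = 300.0,
    dominance: float = 0.5,
) -> Tuple[str, Dict]:
    """Call a coumarin dimer's linkage from its fragmentation regime.

    ``CO_linked``: the spectrum is dominated by a continuous descending
    ladder of small losses (CH3, CH2, CO2) from the precursor — an ether
    bridge survives while peripheral groups strip off. ``CC_linked``: the
    dominant fragments reproduce a single-coumarin ladder anchored at a
    monomer [M+H]+ — the C-C bond resists cleavage so the spectrum looks
    like one coumarin unit. ``undetermined`` otherwise. "Dominated" means
    the pattern's peaks carry more than `dominance` of total intensity.
    """
    catalog = catalog or default_loss_catalog()
    if spec.precursor_mz < min_precursor_mz:
        return "undetermined", {"reason": f"precursor below dimer gate {min_precursor_mz}"}
    total = sum(inten for _, inten in spec.peaks)
    if total <= 0:
        return "undetermined", {"reason": "no fragment intensity"}

    # C-O regime: every cumulative combination of small-loss steps from the
    # precursor, in any order, up to the full step set.
    co_targets: Set[float] = set()
    cumulative = [0.0]
    for label in DIMER_SMALL_LOSS_STEPS:
        cumulative = cumulative + [c + catalog.mass(label) for c in cumulative]
    for c in cumulative:
        if c > 0 and spec.precursor_mz - c > 0:
            co_targets.add(spec.precursor_mz - c)
    co_fraction = _matched_intensity(spec, co_targets, tol) / total

    # C-C regime: monomer-like ladders anchored at each candidate monomer
    # [M+H]+ (the monomer ion itself plus its standard loss rungs).
    cc_targets: Set[float] = set()
    for mh in monomer_mh_mzs:
        if mh <= 0 or mh >= spec.precursor_mz:
            continue
        cc_targets.add(mh)
        for seq in MONOMER_LOSS_SEQUENCES:
            try:
                cc_targets.update(generate_ladder(mh, seq, catalog).rungs)
            except ValueError:
                continue
    cc_fraction = _matched_intensity(spec, cc_targets, tol) / total if cc_targets else 0.0

    evidence = {"co_fraction": co_fraction, "cc_fraction": cc_fraction}
    if co_fraction > dominance and co_fraction >= cc_fraction:
        return "CO_linked", evidence
    if cc_fraction > dominance:
        return "CC_linked", evidence
    return "undetermined", evidence
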