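"""Automatic diagnostic-ion screening of MS2 nodes.

Per node the pipeline (1) matches the precursor against the in-house
library at 10 ppm, (2) calls compound classes from detected neutral
losses, (3) scores the spectrum against each candidate's theoretical
fragment ladder and confirms candidates only when more than the
characteristic-ion threshold (default: strictly over 60%) of the ladder
is present, (4) for unmatched precursors infers structural modifications
(hexosylation, methylation, ...) relative to library bases, and
(5) assigns an annotation tier. Nodes matching two or more isomers are
flagged for manual review rather than auto-resolved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .chem import (
    ElementalComposition,
    FRAGMENT_TOLERANCE,
    MassTolerance,
    PRECURSOR_TOLERANCE,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
)
from .fragments import (
    ClassRule,
    LossCatalog,
    candidate_diagnostic_set,
    classify_class,
    default_class_rules,
    default_loss_catalog,
    detect_neutral_losses,
    diagnostic_ion_score,
)
from .library import Library, LibraryCompound, match_precursor
from .spectra import Spectrum

__all__ = [
    "ModificationCatalog",
    "ModificationCall",
    "AnnotationResult",
    "ScreeningConfig",
    "default_modification_catalog",
    "infer_modification",
    "screen_spectrum",
    "screen_corpus",
    "ScreeningSummary",
]

TIERS = ("library_confirmed", "class_plus_modification", "class_only", "unassigned")

# Default structural-unit modifications: mass shifts that connect an
# observed precursor to a library base compound.
_DEFAULT_MODIFICATIONS = {
    "hexosylation": "C6H10O5",     # +162.05282
    "methylation": "CH2",          # +14.01565
    "hydroxylation": "O",          # +15.99491
    "methoxylation": "CH2O",       # +30.01057
    "acetylation": "C2H2O",        # +42.01057
}


@dataclass(frozen=True)
class Modification:
    label: str
    composition: ElementalComposition
    mass: float

    def __post_init__(self) -> None:
        if abs(monoisotopic_mass(self.composition) - self.mass) > 1e-6:
            raise ValueError(f"modification {self.label}: mass/composition mismatch")


@dataclass(frozen=True)
class ModificationCatalog:
    entries: Tuple[Modification, ...]

    def __post_init__(self) -> None:
        labels = [m.label for m in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate modification labels")

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_formulas(cls, entries: Dict[str, str]) -> "ModificationCatalog":
        mods = []
        for label, formula in entries.items():
            comp = parse_formula(formula)
            mods.append(Modification(label, comp, monoisotopic_mass(comp)))
        return cls(tuple(mods))


def default_modification_catalog() -> ModificationCatalog:
    return ModificationCatalog.from_formulas(_DEFAULT_MODIFICATIONS)


@dataclass(frozen=True)
class ModificationCall:
    """One inferred modification combination relative to a base compound."""

    labels: Tuple[str, ...]
    delta_mass: float
    ppm: float


@dataclass
class ScreeningConfig:
    """Tunable thresholds of the screening pipeline."""

    precursor_tol: MassTolerance = field(default_factory=lambda: PRECURSOR_TOLERANCE)
    fragment_tol: MassTolerance = field(default_factory=lambda: FRAGMENT_TOLERANCE)
    score_threshold: float = 0.6          # candidates need score strictly above
    min_diagnostic_set_size: int = 3
    modification_max_steps: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.score_threshold <= 1):
            raise ValueError("score_threshold must be in (0, 1]")
        if self.min_diagnostic_set_size < 1:
            raise ValueError("min_diagnostic_set_size must be >= 1")
        if self.modification_max_steps < 1:
            raise ValueError("modification_max_steps must be >= 1")


@dataclass
class AnnotationResult:
    """Per-node screening outcome."""

    node_id: str
    precursor_mz: float
    class_calls: List[str] = field(default_factory=list)
    diagnostic_score: Optional[float] = None
    losses_detected: List[str] = field(default_factory=list)
    library_matches: List[Tuple[str, float]] = field(default_factory=list)
    modification_call: Optional[Tuple[str, Tuple[str, ...]]] = None
    tier: str = "unassigned"

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier == "library_confirmed" and not self.library_matches:
            raise ValueError("library_confirmed requires library matches")

    @property
    def needs_manual_review(self) -> bool:
        """Two or more isomeric library matches demand manual confirmation."""
        return len(self.library_matches) >= 2

    @property
    def best_match(self) -> Optional[str]:
        return self.library_matches[0][0] if self.library_matches else None


def _is_methoxylated(compound: LibraryCompound) -> bool:
    return "methoxy" in (compound.subclass or "").casefold()


def infer_modification(
    precursor_mz: float,
    base: LibraryCompound,
    mods: Optional[ModificationCatalog] = None,
    cfg: Optional[ScreeningConfig] = None,
) -> List[ModificationCall]:
    """Modification combinations bridging a base compound to a precursor.

    Enumerates single entries and combinations (with repetition) up to
    ``cfg.modification_max_steps`` whose summed mass matches
    ``precursor_mz - base.mh_mz`` within the precursor tolerance; sorted by
    absolute ppm deviation.
    """
    mods = mods or default_modification_catalog()
    cfg = cfg or ScreeningConfig()
    delta = precursor_mz - base.mh_mz
    if delta <= 0:
        return []
    window = cfg.precursor_tol.window(precursor_mz)
    calls: List[ModificationCall] = []
    entries = sorted(mods, key=lambda m: m.label)
    for k in range(1, cfg.modification_max_steps + 1):
        for combo in itertools.combinations_with_replacement(entries, k):
            total = sum(m.mass for m in combo)
            if abs(delta - total) <= window:
                calls.append(
                    ModificationCall(
                        labels=tuple(m.label for m in combo),
                        delta_mass=total,
                        ppm=ppm_error(base.mh_mz + total, precursor_mz),
                    )
                )
    calls.sort(key=lambda c: (abs(c.ppm), c.labels))
    return calls


def _score_candidate(
    spec: Spectrum,
    compound: LibraryCompound,
    catalog: LossCatalog,
    cfg: ScreeningConfig,
) -> Optional[float]:
    """Diagnostic score of a spectrum against one candidate's ladder set.

    Returns None when the candidate's diagnostic set is smaller than the
    configured minimum (too little theory to confirm against).
    """
    diagnostics = candidate_diagnostic_set(
        compound.mh_mz,
        compound.compound_class,
        catalog,
        methoxylated=_is_methoxylated(compound),
    )
    if len(diagnostics) < cfg.min_diagnostic_set_size:
        return None
    return diagnostic_ion_score(spec, diagnostics, cfg.fragment_tol)


# A pluggable structural-unit resolver may propose (name, formula) candidates
# for nodes the library cannot explain; the shipped pipeline never performs
# network calls, so the default is None (disabled).
Resolver = Callable[[float, Sequence[str]], List[Tuple[str, str]]]


def screen_spectrum(
    spec: Spectrum,
    lib: Library,
    rules: Optional[Sequence[ClassRule]] = None,
    catalog: Optional[LossCatalog] = None,
    mods: Optional[ModificationCatalog] = None,
    cfg: Optional[ScreeningConfig] = None,
    resolver: Optional[Resolver] = None,
) -> AnnotationResult:
    """Screen one MS2 node; never raises on a valid spectrum."""
    catalog = catalog or default_loss_catalog()
    mods = mods or default_modification_catalog()
    cfg = cfg or ScreeningConfig()
    rules = list(rules) if rules is not None else default_class_rules()

    result = AnnotationResult(node_id=spec.node_id, precursor_mz=spec.precursor_mz)
    if spec.flagged_empty:
        return result

    detected = detect_neutral_losses(spec, catalog, cfg.fragment_tol)
    result.losses_detected = sorted(detected)
    class_calls = classify_class(spec, rules, catalog, cfg.fragment_tol)
    result.class_calls = [name for name, _ in class_calls]

    # (1)+(3): precursor match then per-candidate diagnostic confirmation
    precursor_hits = match_precursor(lib, spec.precursor_mz, cfg.precursor_tol)
    scored: List[Tuple[LibraryCompound, float, float]] = []
    best_score: Optional[float] = None
    for compound in precursor_hits:
        score = _score_candidate(spec, compound, catalog, cfg)
        if score is None:
            continue
        if best_score is None or score > best_score:
            best_score = score
        if score > cfg.score_threshold:
            scored.append(
                (compound, score, ppm_error(spec.precursor_mz, compound.mh_mz))
            )
    result.diagnostic_score = best_score

    if scored:
        scored.sort(key=lambda t: (-t[1], abs(t[2]), t[0].name))
        result.library_matches = [(c.name, dppm) for c, _, dppm in scored]
        result.diagnostic_score = scored[0][1]
        result.tier = "library_confirmed"
        confirmed_classes = {c.compound_class for c, _, _ in scored}
        for cls_name in sorted(confirmed_classes):
            if cls_name not in result.class_calls:
                result.class_calls.append(cls_name)
        return result

    # (5): no confirmed direct hit -> structural-unit (modification) inference
    best_mod: Optional[Tuple[float, float, LibraryCompound, ModificationCall]] = None
    for base in lib:
        if base.mh_mz >= spec.precursor_mz:
            continue
        calls = infer_modification(spec.precursor_mz, base, mods, cfg)
        if not calls:
            continue
        score = _score_candidate(spec, base, catalog, cfg)
        if score is None or score <= cfg.score_threshold:
            continue
        key = (-score, abs(calls[0].ppm))
        if best_mod is None or key < (-best_mod[0], best_mod[1]):
            best_mod = (score, abs(calls[0].ppm), base, calls[0])

    if best_mod is not None:
        score, _, base, call = best_mod
        result.modification_call = (base.name, call.labels)
        result.diagnostic_score = score
        result.tier = "class_plus_modification"
        if base.compound_class not in result.class_calls:
            result.class_calls.append(base.compound_class)
        return result

    if resolver is not None and not result.class_calls:
        # external structural-unit lookup hook (disabled by default)
        _ = resolver(spec.precursor_mz, result.losses_detected)

    result.tier = "class_only" if result.class_calls else "unassigned"
    return result


@dataclass
class ScreeningSummary:
    """Corpus-level tallies of a screening run."""

    n_nodes: int
    tier_counts: Dict[str, int]
    class_counts: Dict[str, int]
    fraction_annotated: float


def screen_corpus(
    spectra: Sequence[Spectrum],
    lib: Library,
    rules: Optional[Sequence[ClassRule]] = None,
    catalog: Optional[LossCatalog] = None,
    mods: Optional[ModificationCatalog] = None,
    cfg: Optional[ScreeningConfig] = None,
) -> Tuple[List[AnnotationResult], ScreeningSummary]:
    """Screen every node and summarize tiers and classes.

    Results are per-node and order-independent: permuting the corpus
    permutes the result list identically.
    """
    if not spectra:
        raise ValueError("empty corpus")
    results = [
        screen_spectrum(s, lib, rules=rules, catalog=catalog, mods=mods, cfg=cfg)
        for s in spectra
    ]
    tier_counts = {t: 0 for t in TIERS}
    class_counts: Dict[str, int] = {}
    for r in results:
        tier_counts[r.tier] += 1
        for c in r.class_calls:
            class_counts[c] = class_counts.get(c, 0) + 1
    n = len(results)
    annotated = n - tier_counts["unassigned"]
    summary = ScreeningSummary(
        n_nodes=n,
        tier_counts=tier_counts,
        class_counts=dict(sorted(class_counts.items())),
        fraction_annotated=annotated / n,
    )
    return results, summary
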