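"""The coumarin branch of the phenylpropanoid pathway, as a static graph.

Phenylalanine/tyrosine feed cinnamic acids (PAL, TAL, C4H, C3H, OMT),
which cyclize to simple coumarins (umbelliferone, esculetin, scopoletin)
via hydroxylation and lactonization (C2'H, F6'H, COSY) and are further
decorated to scopolin (2GT), fraxetin (S8H) and isofraxidin (OMT). The
graph is packaged data; coverage reporting intersects a screening run's
annotated compound names with the pathway's node names.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .library import canonical_name

__all__ = [
    "PathwayGraph",
    "CoverageReport",
    "load_pathway",
    "default_pathway",
    "pathway_coverage",
    "ENZYME_LABELS",
    "SYNONYMS",
]

ENZYME_LABELS = {
    "PAL", "TAL", "C3H", "C4H", "OMT", "2GT",
    "3CL", "4CL", "F6'H", "C2'H", "COSY", "S8H",
}

#: Alternate names mapped to the pathway's canonical node names.
SYNONYMS = {
    "isofraxin": "isofraxidin",
    "scoparone": "6,7-dimethoxycoumarin",
    "aesculetin": "esculetin",
    "2,4-dihydroxycinnamic acid": "2,4-dihydroxy-cinnamic acid",
}


@dataclass
class PathwayGraph:
    """A directed acyclic graph of pathway intermediates.

    Edges carry the catalyzing enzyme label (or None for steps the figure
    leaves unlabeled) and an ``authenticated`` flag; unauthenticated steps
    are proposed, not enzymatically verified.
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("pathway graph must be acyclic")
        for u, v, data in self.graph.edges(data=True):
            enzyme = data.get("enzyme")
            if enzyme is not None and enzyme not in ENZYME_LABELS:
                raise ValueError(f"unknown enzyme label {enzyme!r} on edge {u} -> {v}")

    @property
    def nodes(self) -> List[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> List[Tuple[str, str, Optional[str], bool]]:
        return sorted(
            (u, v, d.get("enzyme"), bool(d.get("authenticated", False)))
            for u, v, d in self.graph.edges(data=True)
        )

    def resolve(self, name: str) -> Optional[str]:
        """Map an arbitrary compound name to a pathway node, or None."""
        canon = canonical_name(SYNONYMS.get(name.strip().casefold(), name))
        for node in self.graph.nodes:
            if canonical_name(node) == canon:
                return node
        return None


def load_pathway(path: str | Path) -> PathwayGraph:
    """Load a pathway from delimited text: from, to, enzyme, authenticated."""
    graph = nx.DiGraph()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            enzyme = (row.get("enzyme") or "").strip() or None
            graph.add_edge(
                row["from"].strip(),
                row["to"].strip(),
                enzyme=enzyme,
                authenticated=(row.get("authenticated", "").strip().lower() == "true"),
            )
    return PathwayGraph(graph)


def default_pathway() -> PathwayGraph:
    """The packaged coumarin-biosynthesis pathway graph."""
    ref = resources.files("coumascreen.data").joinpath("pathway.tsv")
    with resources.as_file(ref) as path:
        return load_pathway(path)


@dataclass
class CoverageReport:
    """Which pathway intermediates a screening run has annotated."""

    covered: List[str]
    uncovered: List[str]
    covered_edges: List[Tuple[str, str, Optional[str], bool]]

    @property
    def n_covered(self) -> int:
        return len(self.covered)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["node\tcovered"]
        for node in self.covered:
            lines.append(f"{node}\ttrue")
        for node in self.uncovered:
            lines.append(f"{node}\tfalse")
        Path(path).write_text("\n".join(lines) + "\n")


def _annotation_names(annotations: Iterable) -> Set[str]:
    """Compound names asserted by annotations (results or plain names)."""
    names: Set[str] = set()
    for ann in annotations:
        if isinstance(ann, str):
            names.add(ann)
            continue
        for name, _ in getattr(ann, "library_matches", ()):
            names.add(name)
        mod = getattr(ann, "modification_call", None)
        if mod is not None:
            names.add(mod[0])
    return names


def pathway_coverage(annotations: Iterable, graph: Optional[PathwayGraph] = None) -> CoverageReport:
    """Report pathway nodes covered by a screening run.

    `annotations` may be AnnotationResult objects (their library matches and
    modification bases count) or plain compound-name strings. Name matching
    is case-insensitive with synonym resolution. Coverage is monotone:
    adding annotations never removes covered nodes.
    """
    graph = graph or default_pathway()
    covered: Set[str] = set()
    for name in _annotation_names(annotations):
        node = graph.resolve(name)
        if node is not None:
            covered.add(node)
    uncovered = [n for n in graph.nodes if n not in covered]
    covered_edges = [
        (u, v, enz, auth)
        for u, v, enz, auth in graph.edges
        if u in covered and v in covered
    ]
    return CoverageReport(
        covered=sorted(covered),
        uncovered=sorted(uncovered),
        covered_edges=covered_edges,
    )
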