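"""Molecular networking: modified-cosine similarity and family assignment.

Spectra become nodes; pairs whose modified-cosine similarity exceeds a
threshold (default: strictly above 0.6 with at least 5 matched peaks) are
connected, and connected components form molecular families of putatively
related structures. Peak matching allows fragment pairs offset by the
precursor mass difference, so analogs differing by one modification still
align; the one-to-one pairing is solved as a maximum-weight assignment,
with a documented greedy approximation available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .chem import FRAGMENT_TOLERANCE, MassTolerance
from .spectra import Spectrum

__all__ = [
    "NetworkEdge",
    "MolecularFamily",
    "modified_cosine",
    "build_network",
    "propagate_class",
    "write_graphml",
    "write_edge_list",
]


@dataclass(frozen=True)
class NetworkEdge:
    """An above-threshold spectral similarity between two nodes."""

    node_a: str
    node_b: str
    cosine: float
    matched_peaks: int

    def __post_init__(self) -> None:
        if not self.node_a < self.node_b:
            raise ValueError("edge endpoints must be in canonical order (a < b)")
        if not (0.0 <= self.cosine <= 1.0):
            raise ValueError(f"cosine {self.cosine} outside [0, 1]")


@dataclass
class MolecularFamily:
    """A connected component of the thresholded similarity graph."""

    family_id: int
    members: List[str]
    class_support: Dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def _candidate_pairs(
    a: Spectrum,
    b: Spectrum,
    tol: MassTolerance,
    precursor_shift: bool,
) -> List[Tuple[int, int]]:
    """Index pairs matchable directly or offset by the precursor difference."""
    shift = a.precursor_mz - b.precursor_mz
    mza, mzb = a.mz, b.mz
    pairs = []
    for i, ma in enumerate(mza):
        for j, mb in enumerate(mzb):
            direct = abs(ma - mb) <= tol.window(0.5 * (ma + mb))
            shifted = precursor_shift and abs(ma - mb - shift) <= tol.window(
                0.5 * (ma + mb)
            )
            if direct or shifted:
                pairs.append((i, j))
    return pairs


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    tol: MassTolerance = FRAGMENT_TOLERANCE,
    precursor_shift: bool = True,
    greedy: bool = False,
) -> Tuple[float, int]:
    """Modified-cosine similarity and matched-peak count of two spectra.

    Intensities are square-root weighted. Candidate peak pairs match either
    directly or offset by the precursor m/z difference; the one-to-one
    pairing maximizing the summed products of weights is found by
    maximum-weight assignment (or greedily when ``greedy=True``, a faster
    approximation). The score is the matched weight product sum divided by
    the product of the spectra's weight norms, hence in [0, 1] and
    symmetric.
    """
    if not a.peaks or not b.peaks:
        raise ValueError("modified cosine requires non-empty peak lists")
    wa = np.sqrt(a.intensities)
    wb = np.sqrt(b.intensities)
    norm = np.linalg.norm(wa) * np.linalg.norm(wb)
    if norm == 0:
        return 0.0, 0
    pairs = _candidate_pairs(a, b, tol, precursor_shift)
    if not pairs:
        return 0.0, 0

    if greedy:
        scored = sorted(pairs, key=lambda ij: -(wa[ij[0]] * wb[ij[1]]))
        used_a, used_b = set(), set()
        total, matched = 0.0, 0
        for i, j in scored:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            total += wa[i] * wb[j]
            matched += 1
    else:
        ia = sorted({i for i, _ in pairs})
        jb = sorted({j for _, j in pairs})
        amap = {i: k for k, i in enumerate(ia)}
        bmap = {j: k for k, j in enumerate(jb)}
        weight = np.zeros((len(ia), len(jb)))
        allowed = np.zeros((len(ia), len(jb)), dtype=bool)
        for i, j in pairs:
            weight[amap[i], bmap[j]] = wa[i] * wb[j]
            allowed[amap[i], bmap[j]] = True
        rows, cols = linear_sum_assignment(weight, maximize=True)
        total, matched = 0.0, 0
        for r, c in zip(rows, cols):
            if allowed[r, c] and weight[r, c] > 0:
                total += weight[r, c]
                matched += 1
            elif allowed[r, c]:
                # zero-intensity peaks can legitimately pair; they count as
                # matched but add no weight
                matched += 1
    cosine = min(1.0, total / norm)
    return float(cosine), int(matched)


def build_network(
    spectra: Sequence[Spectrum],
    min_cosine: float = 0.6,
    min_matched: int = 5,
    tol: MassTolerance = FRAGMENT_TOLERANCE,
    precursor_shift: bool = True,
    max_neighbors: Optional[int] = None,
) -> Tuple[List[NetworkEdge], List[MolecularFamily]]:
    """Score all spectrum pairs and build the thresholded family graph.

    Edges require cosine strictly above `min_cosine` and at least
    `min_matched` matched peaks. With `max_neighbors`, an edge survives only
    if it ranks within the top-K by cosine for both endpoints. Families are
    the connected components; spectra without edges form singleton families.
    """
    if not spectra:
        raise ValueError("at least one spectrum required")
    ids = [s.node_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate node ids in corpus")

    edges: List[NetworkEdge] = []
    for x in range(len(spectra)):
        for y in range(x + 1, len(spectra)):
            a, b = spectra[x], spectra[y]
            if not a.peaks or not b.peaks:
                continue
            cos, matched = modified_cosine(a, b, tol, precursor_shift)
            if cos > min_cosine and matched >= min_matched:
                lo, hi = sorted((a.node_id, b.node_id))
                edges.append(NetworkEdge(lo, hi, cos, matched))

    if max_neighbors is not None:
        by_node: Dict[str, List[NetworkEdge]] = {}
        for e in edges:
            by_node.setdefault(e.node_a, []).append(e)
            by_node.setdefault(e.node_b, []).append(e)
        keep = set()
        for node, node_edges in by_node.items():
            node_edges.sort(key=lambda e: -e.cosine)
            for e in node_edges[:max_neighbors]:
                keep.add((e.node_a, e.node_b))
        # survive only if top-K for BOTH endpoints
        counts: Dict[Tuple[str, str], int] = {}
        for node, node_edges in by_node.items():
            node_edges.sort(key=lambda e: -e.cosine)
            for e in node_edges[:max_neighbors]:
                counts[(e.node_a, e.node_b)] = counts.get((e.node_a, e.node_b), 0) + 1
        edges = [e for e in edges if counts.get((e.node_a, e.node_b), 0) == 2]

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    graph.add_edges_from((e.node_a, e.node_b) for e in edges)
    families = []
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for fid, comp in enumerate(components):
        families.append(MolecularFamily(family_id=fid, members=sorted(comp)))
    return edges, families


def propagate_class(
    families: Sequence[MolecularFamily],
    annotations: Mapping[str, Sequence[str]],
) -> List[MolecularFamily]:
    """Attach class labels with member support counts to each family.

    `annotations` maps node id to the class calls of that node (possibly
    empty). A family carries every class present among its annotated
    members; mixed families keep all their labels.
    """
    out = []
    for fam in families:
        support: Dict[str, int] = {}
        for node in fam.members:
            for cls in annotations.get(node, ()):
                support[cls] = support.get(cls, 0) + 1
        out.append(
            MolecularFamily(
                family_id=fam.family_id,
                members=list(fam.members),
                class_support=dict(sorted(support.items())),
            )
        )
    return out


def write_graphml(
    edges: Sequence[NetworkEdge],
    spectra: Sequence[Spectrum],
    path: str | Path,
    annotations: Optional[Mapping[str, Mapping]] = None,
) -> None:
    """Export the network as GraphML with node and edge attributes."""
    graph = nx.Graph()
    for s in spectra:
        attrs = {"precursor_mz": float(s.precursor_mz)}
        if annotations and s.node_id in annotations:
            ann = annotations[s.node_id]
            attrs["class_call"] = str(ann.get("class_call", ""))
            attrs["tier"] = str(ann.get("tier", ""))
        graph.add_node(s.node_id, **attrs)
    for e in edges:
        graph.add_edge(e.node_a, e.node_b, cosine=e.cosine, matched_peaks=e.matched_peaks)
    nx.write_graphml(graph, str(path))


def write_edge_list(edges: Sequence[NetworkEdge], path: str | Path) -> None:
    """Write edges as TSV: node_a, node_b, cosine, matched_peaks."""
    lines = ["node_a\tnode_b\tcosine\tmatched_peaks"]
    for e in sorted(edges, key=lambda e: (e.node_a, e.node_b)):
        lines.append(f"{e.node_a}\t{e.node_b}\t{e.cosine:.6f}\t{e.matched_peaks}")
    Path(path).write_text("\n".join(lines) + "\n")
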