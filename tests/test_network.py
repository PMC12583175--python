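"""Modified cosine, thresholded graph construction and class propagation."""

import itertools

import numpy as np
import pytest

from coumascreen.chem import MassTolerance
from coumascreen.network import (
    MolecularFamily,
    build_network,
    modified_cosine,
    propagate_class,
    write_edge_list,
    write_graphml,
)
from coumascreen.simulate import SpectrumRecipe, synth_spectrum
from coumascreen.spectra import Spectrum

TOL = MassTolerance(ppm=20, dalton=0.01, mode="wider")


def _spec(node_id, precursor, mzs, intens):
    return Spectrum(node_id, precursor, peaks=tuple(zip(mzs, intens)))


def brute_force_cosine(a, b, tol, precursor_shift=True):
    """Exhaustive best one-to-one assignment over candidate peak pairs."""
    wa, wb = np.sqrt(a.intensities), np.sqrt(b.intensities)
    shift = a.precursor_mz - b.precursor_mz
    pairs = []
    for i, ma in enumerate(a.mz):
        for j, mb in enumerate(b.mz):
            window = tol.window(0.5 * (ma + mb))
            if abs(ma - mb) <= window or (
                precursor_shift and abs(ma - mb - shift) <= window
            ):
                pairs.append((i, j))
    best = 0.0

    def search(k, used_a, used_b, acc):
        nonlocal best
        best = max(best, acc)
        for idx in range(k, len(pairs)):
            i, j = pairs[idx]
            if i in used_a or j in used_b:
                continue
            search(idx + 1, used_a | {i}, used_b | {j}, acc + wa[i] * wb[j])

    search(0, frozenset(), frozenset(), 0.0)
    norm = np.linalg.norm(wa) * np.linalg.norm(wb)
    return best / norm if norm else 0.0


def test_identical_spectra_self_similarity():
    s = _spec("a", 300.0, [100.0, 150.0, 200.0], [10.0, 20.0, 30.0])
    cos, matched = modified_cosine(s, s, TOL)
    assert cos == pytest.approx(1.0)
    assert matched == 3


def test_disjoint_spectra_zero():
    a = _spec("a", 300.0, [100.0, 150.0], [10.0, 10.0])
    b = _spec("b", 300.0, [120.0, 170.0], [10.0, 10.0])
    assert modified_cosine(a, b, TOL) == (0.0, 0)


def test_empty_peak_list_rejected():
    a = _spec("a", 300.0, [100.0], [1.0])
    with pytest.raises(ValueError):
        modified_cosine(a, Spectrum("b", 300.0, peaks=()), TOL)


def test_precursor_shift_matches_modified_analog():
    # analog shifted by +14 Da on precursor and one fragment
    a = _spec("a", 300.0, [120.0, 150.0, 200.0], [10.0, 20.0, 30.0])
    b = _spec("b", 314.0, [120.0, 150.0, 214.0], [10.0, 20.0, 30.0])
    cos_shift, matched_shift = modified_cosine(a, b, TOL, precursor_shift=True)
    cos_direct, _ = modified_cosine(a, b, TOL, precursor_shift=False)
    assert matched_shift == 3
    assert cos_shift == pytest.approx(1.0)
    assert cos_direct < cos_shift


def test_symmetry_and_range_random():
    rng = np.random.default_rng(17)
    for _ in range(50):
        na, nb = int(rng.integers(1, 10)), int(rng.integers(1, 10))
        a = _spec("a", float(rng.uniform(250, 350)), rng.uniform(50, 300, na).tolist(),
                  rng.uniform(1, 100, na).tolist())
        b = _spec("b", float(rng.uniform(250, 350)), rng.uniform(50, 300, nb).tolist(),
                  rng.uniform(1, 100, nb).tolist())
        tol = MassTolerance(dalton=float(rng.uniform(0.01, 2.0)), mode="absolute")
        cab, mab = modified_cosine(a, b, tol)
        cba, mba = modified_cosine(b, a, tol)
        assert cab == pytest.approx(cba, abs=1e-12)
        assert mab == mba
        assert 0.0 <= cab <= 1.0


def test_assignment_matches_exhaustive_oracle():
    rng = np.random.default_rng(23)
    for _ in range(200):
        na, nb = int(rng.integers(1, 9)), int(rng.integers(1, 9))
        a = _spec("a", float(rng.uniform(250, 350)), rng.uniform(50, 300, na).tolist(),
                  rng.uniform(1, 100, na).tolist())
        b = _spec("b", float(rng.uniform(250, 350)), rng.uniform(50, 300, nb).tolist(),
                  rng.uniform(1, 100, nb).tolist())
        tol = MassTolerance(dalton=float(rng.uniform(0.1, 3.0)), mode="absolute")
        cos, _ = modified_cosine(a, b, tol)
        assert cos == pytest.approx(brute_force_cosine(a, b, tol), abs=1e-9)


def test_greedy_is_a_lower_bound():
    rng = np.random.default_rng(29)
    for _ in range(50):
        n = int(rng.integers(2, 10))
        a = _spec("a", 320.0, rng.uniform(50, 300, n).tolist(), rng.uniform(1, 100, n).tolist())
        b = _spec("b", 330.0, rng.uniform(50, 300, n).tolist(), rng.uniform(1, 100, n).tolist())
        tol = MassTolerance(dalton=2.0, mode="absolute")
        optimal, _ = modified_cosine(a, b, tol)
        greedy, _ = modified_cosine(a, b, tol, greedy=True)
        assert greedy <= optimal + 1e-12


def test_two_copies_form_one_family():
    s = _spec("a", 300.0, [100.0, 120.0, 140.0, 160.0, 180.0], [10.0] * 5)
    edges, families = build_network([s, s.with_id("b")])
    assert len(edges) == 1
    assert edges[0].cosine == pytest.approx(1.0)
    assert [f.members for f in families] == [["a", "b"]]


def test_shared_ladder_coumarins_connect(lib):
    # scopoletin and isofraxidin spectra share their ladder structure up to
    # the precursor shift, so FBMN links them
    a, _ = synth_spectrum(SpectrumRecipe(compound=lib.get("scopoletin")))
    b, _ = synth_spectrum(SpectrumRecipe(compound=lib.get("isofraxidin")))
    cos, matched = modified_cosine(a, b, TOL, precursor_shift=True)
    assert cos > 0.6 and matched >= 5
    edges, families = build_network([a, b])
    assert len(edges) == 1
    assert families[0].size == 2


def test_all_dissimilar_corpus_gives_singletons():
    rng = np.random.default_rng(31)
    spectra = [
        _spec(f"n{i}", 250.0 + 30 * i, sorted(rng.uniform(50, 200, 5).tolist()),
              rng.uniform(1, 100, 5).tolist())
        for i in range(4)
    ]
    edges, families = build_network(spectra, min_cosine=0.99, min_matched=5)
    assert edges == []
    assert all(f.size == 1 for f in families)
    assert len(families) == 4


def test_threshold_monotonicity():
    rng = np.random.default_rng(37)
    base = sorted(rng.uniform(50, 280, 12).tolist())
    spectra = []
    for i in range(5):
        mzs = [m + rng.normal(0, 0.002) for m in base[: 12 - i]]
        spectra.append(_spec(f"n{i}", 300.0 + i, mzs, rng.uniform(10, 100, len(mzs)).tolist()))
    edges_low, _ = build_network(spectra, min_cosine=0.3, min_matched=3)
    edges_high, _ = build_network(spectra, min_cosine=0.6, min_matched=5)
    keys_low = {(e.node_a, e.node_b) for e in edges_low}
    keys_high = {(e.node_a, e.node_b) for e in edges_high}
    assert keys_high <= keys_low


def test_families_partition_nodes_and_edges_internal():
    rng = np.random.default_rng(41)
    base = sorted(rng.uniform(50, 280, 10).tolist())
    spectra = [
        _spec(f"n{i}", 300.0, [m + rng.normal(0, 0.001) for m in base],
              rng.uniform(10, 100, 10).tolist())
        for i in range(4)
    ] + [_spec("iso", 500.0, [400.0, 450.0], [5.0, 5.0])]
    edges, families = build_network(spectra, min_cosine=0.5)
    members = sorted(m for f in families for m in f.members)
    assert members == sorted(s.node_id for s in spectra)  # partition
    fam_of = {m: f.family_id for f in families for m in f.members}
    for e in edges:
        assert fam_of[e.node_a] == fam_of[e.node_b]


def test_propagate_class_mixed_family():
    fams = [MolecularFamily(0, ["a", "b", "c"]), MolecularFamily(1, ["d"])]
    annotations = {
        "a": ["coumarin"],
        "b": ["coumarin"],
        "c": ["cinnamic_acid"],
        "d": [],
    }
    out = propagate_class(fams, annotations)
    assert out[0].class_support == {"cinnamic_acid": 1, "coumarin": 2}
    assert out[1].class_support == {}


def test_propagate_class_partial_annotation():
    fams = [MolecularFamily(0, ["a", "b"])]
    out = propagate_class(fams, {"a": ["coumarin"], "b": []})
    assert out[0].class_support == {"coumarin": 1}


def test_exports(tmp_path):
    s1 = _spec("a", 300.0, [100.0, 120.0, 140.0, 160.0, 180.0], [10.0] * 5)
    s2 = s1.with_id("b")
    edges, _ = build_network([s1, s2])
    write_edge_list(edges, tmp_path / "edges.tsv")
    lines = (tmp_path / "edges.tsv").read_text().splitlines()
    assert lines[0].split("\t") == ["node_a", "node_b", "cosine", "matched_peaks"]
    assert len(lines) == 2
    write_graphml(edges, [s1, s2], tmp_path / "net.graphml")
    import networkx as nx

    g = nx.read_graphml(tmp_path / "net.graphml")
    assert g.number_of_nodes() == 2 and g.number_of_edges() == 1


def test_matchms_cross_check(lib):
    # independent reference implementation on well-separated peaks where
    # greedy and optimal assignment coincide
    matchms = pytest.importorskip("matchms")
    import matchms.similarity as mms

    a, _ = synth_spectrum(SpectrumRecipe(compound=lib.get("scopoletin")))
    b, _ = synth_spectrum(SpectrumRecipe(compound=lib.get("isofraxidin")))
    ma = matchms.Spectrum(
        mz=a.mz, intensities=a.intensities, metadata={"precursor_mz": a.precursor_mz}
    )
    mb = matchms.Spectrum(
        mz=b.mz, intensities=b.intensities, metadata={"precursor_mz": b.precursor_mz}
    )
    ref = mms.ModifiedCosine(tolerance=0.01).pair(ma, mb)
    cos, matched = modified_cosine(a, b, MassTolerance(dalton=0.01, mode="absolute"))
    assert cos == pytest.approx(float(ref["score"]), abs=0.02)
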