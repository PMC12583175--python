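"""PCA, PLS-DA/VIP, volcano analysis and the joint selection rule."""

import numpy as np
import pytest

from coumascreen.simulate import TableRecipe, synth_feature_table
from coumascreen.spectra import FeatureTable
from coumascreen.stats import (
    collapse_adducts,
    pca,
    plsda_vip,
    select_differential,
    volcano,
)


def _table(areas, groups=None, ids=None):
    areas = np.asarray(areas, dtype=float)
    nf, ns = areas.shape
    samples = [f"s{i}" for i in range(ns)]
    if groups is None:
        groups = {s: ("a" if i < ns // 2 else "b") for i, s in enumerate(samples)}
    return FeatureTable(
        feature_ids=ids or [f"F{i}" for i in range(nf)],
        feature_mz=[0.0] * nf,
        feature_rt=[0.0] * nf,
        samples=samples,
        groups=groups,
        areas=areas,
    )


def test_pca_two_samples_single_component():
    table = _table(np.array([[1.0, 2.0], [3.0, 5.0], [2.0, 2.5]]))
    model = pca(table, scaling="none")
    assert model.explained[0] == pytest.approx(1.0)


def test_pca_reconstruction_complete():
    rng = np.random.default_rng(2)
    table = _table(rng.uniform(1, 100, size=(20, 10)))
    model = pca(table, scaling="unit_variance")
    X = (table.areas.T - table.areas.T.mean(axis=0)) / table.areas.T.std(axis=0, ddof=1)
    recon = model.scores @ model.loadings.T
    assert np.max(np.abs(recon - X)) < 1e-8


def test_pca_no_variance_error():
    table = _table(np.full((3, 4), 7.0))
    with pytest.raises(ValueError, match="no variance"):
        pca(table)


def test_pca_separates_planted_clusters():
    rec = TableRecipe(
        n_features=50,
        groups={"a": 4, "b": 4},
        planted_effects=[(i, "a", 6.0) for i in range(10)],
        noise_cv=0.1,
        seed=4,
    )
    table, _ = synth_feature_table(rec)
    model = pca(table, n_components=2)
    pc1 = model.scores[:, 0]
    ga = [pc1[i] for i in table.samples_in_group("a")]
    gb = [pc1[i] for i in table.samples_in_group("b")]
    gap = abs(np.mean(ga) - np.mean(gb))
    spread = max(np.std(ga), np.std(gb))
    assert gap > 3 * spread


def test_pca_translation_invariance():
    rng = np.random.default_rng(6)
    areas = rng.uniform(10, 100, size=(8, 6))
    m1 = pca(_table(areas), scaling="none")
    m2 = pca(_table(areas + 50.0), scaling="none")
    assert np.allclose(np.abs(m1.scores), np.abs(m2.scores), atol=1e-8)


def test_vip_mean_square_identity():
    rng = np.random.default_rng(8)
    for trial in range(5):
        nf = int(rng.integers(5, 60))
        table = _table(rng.uniform(1, 100, size=(nf, 8)))
        _, vip = plsda_vip(table, n_components=2)
        assert np.mean(np.array(list(vip.values())) ** 2) == pytest.approx(1.0, abs=1e-9)


def test_single_informative_feature_has_max_vip():
    rec = TableRecipe(
        n_features=40,
        groups={"a": 4, "b": 4},
        planted_effects=[(7, "a", 8.0)],
        noise_cv=0.05,
        seed=10,
    )
    table, _ = synth_feature_table(rec)
    _, vip = plsda_vip(table)
    assert max(vip, key=vip.get) == table.feature_ids[7]


def test_vip_changes_under_label_permutation():
    rng = np.random.default_rng(12)
    table, _ = synth_feature_table(
        TableRecipe(
            n_features=30, groups={"a": 3, "b": 3},
            planted_effects=[(0, "a", 8.0)], seed=13,
        )
    )
    _, vip1 = plsda_vip(table)
    permuted = FeatureTable(
        feature_ids=table.feature_ids,
        feature_mz=table.feature_mz,
        feature_rt=table.feature_rt,
        samples=table.samples,
        groups={s: ("a" if i % 2 else "b") for i, s in enumerate(table.samples)},
        areas=table.areas,
    )
    _, vip2 = plsda_vip(permuted)
    assert not np.allclose(list(vip1.values()), list(vip2.values()))


def test_plsda_requires_replicates():
    table = _table(np.random.default_rng(1).uniform(1, 10, (5, 3)),
                   groups={"s0": "a", "s1": "a", "s2": "b"})
    with pytest.raises(ValueError, match="fewer than 2"):
        plsda_vip(table)


def test_volcano_clear_up_regulation():
    areas = np.array([[40.0, 41.0, 39.0, 10.0, 10.5, 9.5]])
    res = volcano(_table(areas), "a", "b")
    assert res[0].direction == "up"
    assert res[0].log2_fc == pytest.approx(2.0, abs=0.1)


def test_volcano_identical_groups_ns():
    areas = np.tile([5.0, 6.0, 7.0], (3, 2)).reshape(3, 6)
    table = _table(np.column_stack([areas[:, :3], areas[:, :3]]))
    res = volcano(table, "a", "b")
    assert all(r.direction == "ns" and r.log2_fc == pytest.approx(0.0) for r in res)


def test_volcano_mirror_symmetry():
    rng = np.random.default_rng(14)
    table = _table(rng.uniform(1, 100, size=(20, 6)))
    ab = volcano(table, "a", "b")
    ba = volcano(table, "b", "a")
    for r1, r2 in zip(ab, ba):
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        assert r1.log2_fc == pytest.approx(-r2.log2_fc, abs=1e-12)
        flip = {"up": "down", "down": "up", "ns": "ns"}
        assert r2.direction == flip[r1.direction]


def test_volcano_planted_counts_recovered():
    rng = np.random.default_rng(15)
    up_idx = rng.choice(500, 20, replace=False)
    rest = [i for i in range(500) if i not in set(up_idx)]
    down_idx = rng.choice(rest, 10, replace=False)
    effects = [(int(i), "a", 8.0) for i in up_idx] + [(int(i), "b", 8.0) for i in down_idx]
    table, truth = synth_feature_table(
        TableRecipe(n_features=500, groups={"a": 3, "b": 3},
                    planted_effects=effects, noise_cv=0.1, seed=16)
    )
    res = volcano(table, "a", "b")
    up = {r.feature_id for r in res if r.direction == "up"}
    down = {r.feature_id for r in res if r.direction == "down"}
    assert up == {table.feature_ids[i] for i in up_idx}
    assert down == {table.feature_ids[i] for i in down_idx}


def test_volcano_zero_handling():
    areas = np.array([[0.0, 0.0, 0.0, 50.0, 55.0, 45.0]])
    res = volcano(_table(areas), "a", "b")
    assert np.isfinite(res[0].log2_fc)
    assert res[0].direction == "down"


def test_volcano_requires_replicates():
    table = _table(np.ones((3, 3)), groups={"s0": "a", "s1": "a", "s2": "b"})
    with pytest.raises(ValueError):
        volcano(table, "a", "b")


def test_select_differential_intersection():
    res = volcano(
        _table(np.array([
            [80.0, 82.0, 78.0, 10.0, 11.0, 9.0],
            [60.0, 61.0, 59.0, 10.0, 10.5, 9.5],
            [5.0, 5.1, 4.9, 5.0, 5.05, 4.95],
        ])),
        "a", "b",
    )
    vip = {"F0": 2.0, "F1": 0.5, "F2": 0.1}
    out, counts = select_differential(res, vip)
    assert [r.selected for r in out] == [True, False, False]
    assert counts == {"up": 1, "down": 0}


def test_select_differential_missing_vip_errors():
    res = volcano(_table(np.ones((2, 4)) + np.arange(8).reshape(2, 4)), "a", "b")
    with pytest.raises(ValueError, match="F1"):
        select_differential(res, {"F0": 1.0})


def test_select_thresholds_monotone():
    rng = np.random.default_rng(18)
    effects = [(int(i), "a", 4.0) for i in range(15)]
    table, _ = synth_feature_table(
        TableRecipe(n_features=200, groups={"a": 3, "b": 3},
                    planted_effects=effects, noise_cv=0.15, seed=19)
    )
    loose = volcano(table, "a", "b", fc_threshold=1.5, p_threshold=0.1)
    tight = volcano(table, "a", "b", fc_threshold=3.0, p_threshold=0.01)
    sig_loose = {r.feature_id for r in loose if r.direction != "ns"}
    sig_tight = {r.feature_id for r in tight if r.direction != "ns"}
    assert sig_tight <= sig_loose
    _, vip = plsda_vip(table)
    sel_lo, _ = select_differential(loose, vip, vip_threshold=0.5)
    sel_hi, _ = select_differential(loose, vip, vip_threshold=2.0)
    assert {r.feature_id for r in sel_hi if r.selected} <= {
        r.feature_id for r in sel_lo if r.selected
    }


def test_collapse_adducts_keeps_highest_total_area():
    areas = np.array([[10.0, 10.0], [100.0, 100.0], [1.0, 1.0]])
    table = _table(areas, groups={"s0": "a", "s1": "a"})
    collapsed = collapse_adducts(table, {"F0": "scopoletin", "F1": "scopoletin"})
    assert collapsed.feature_ids == ["F1", "F2"]
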