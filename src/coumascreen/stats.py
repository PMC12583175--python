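"""Multivariate and univariate differential analysis of feature tables.

PCA for unsupervised structure, PLS-DA (NIPALS, via scikit-learn) with
variable-importance-in-projection (VIP) scores for supervised group
discrimination, pairwise volcano analysis (fold change + Welch t-test on
log areas), and the joint selection rule: a feature is differential when
it passes the volcano criteria (|FC| >= 2, p < 0.05 by default) AND has
VIP > 1 in the PLS-DA model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _scipy_stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _SKPCA
from statsmodels.stats.multitest import multipletests

from .spectra import FeatureTable

__all__ = [
    "LatentModel",
    "DifferentialResult",
    "pca",
    "plsda_vip",
    "volcano",
    "select_differential",
    "collapse_adducts",
]

SCALINGS = ("none", "unit_variance", "pareto")


@dataclass
class LatentModel:
    """Scores/loadings decomposition of a (samples x features) matrix."""

    scores: np.ndarray              # samples x components
    loadings: np.ndarray            # features x components
    explained: np.ndarray           # variance fraction per component
    feature_ids: List[str]
    sample_ids: List[str]
    weights: Optional[np.ndarray] = None      # PLS x-weights
    y_encoding: Optional[np.ndarray] = None   # PLS one-hot group matrix
    group_order: Optional[List[str]] = None


def _preprocess(areas: np.ndarray, scaling: str) -> np.ndarray:
    """Transpose to samples x features, mean-center, optionally scale."""
    if scaling not in SCALINGS:
        raise ValueError(f"unknown scaling {scaling!r}; choose from {SCALINGS}")
    X = areas.T.astype(float)
    X = X - X.mean(axis=0)
    if scaling == "none":
        return X
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)  # constant features pass through unscaled
    if scaling == "unit_variance":
        return X / sd
    return X / np.sqrt(sd)  # pareto


def pca(
    table: FeatureTable,
    n_components: Optional[int] = None,
    scaling: str = "unit_variance",
) -> LatentModel:
    """Principal component analysis of the feature table.

    Samples are observations; areas are mean-centered (and scaled per
    `scaling`, unit variance by default) before singular value
    decomposition. Scores reproduce X_processed @ loadings.
    """
    if table.n_samples < 2 or table.n_features < 2:
        raise ValueError("PCA requires at least 2 samples and 2 features")
    X = _preprocess(table.areas, scaling)
    if not np.any(X):
        raise ValueError("no variance")
    max_comp = min(X.shape[0] - 1, X.shape[1])
    k = max_comp if n_components is None else min(n_components, max_comp)
    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    return LatentModel(
        scores=scores,
        loadings=model.components_.T,
        explained=model.explained_variance_ratio_,
        feature_ids=list(table.feature_ids),
        sample_ids=list(table.samples),
    )


def _one_hot(labels: Sequence[str]) -> Tuple[np.ndarray, List[str]]:
    order = sorted(set(labels))
    Y = np.zeros((len(labels), len(order)))
    for i, lab in enumerate(labels):
        Y[i, order.index(lab)] = 1.0
    return Y, order


def plsda_vip(
    table: FeatureTable,
    n_components: int = 2,
    scaling: str = "unit_variance",
) -> Tuple[LatentModel, Dict[str, float]]:
    """PLS-DA with VIP scores.

    Fits NIPALS PLS2 of the preprocessed areas against the one-hot group
    matrix and computes, per feature j,

        VIP_j = sqrt( p * sum_a SSY_a * w_ja^2 / sum_a SSY_a )

    with p the feature count, w the unit-norm x-weights and SSY_a the
    y-variance captured by component a. The mean of VIP^2 over features is
    identically 1.
    """
    labels = table.group_labels()
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("PLS-DA requires at least 2 groups")
    for g in groups:
        if labels.count(g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    X = _preprocess(table.areas, scaling)
    Y, order = _one_hot(labels)
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(X, Y)

    W = pls.x_weights_          # p x A, unit-norm columns
    T = pls.x_scores_           # n x A
    Q = pls.y_loadings_         # g x A
    ssy = np.array(
        [(T[:, a] @ T[:, a]) * (Q[:, a] @ Q[:, a]) for a in range(k)]
    )
    p = X.shape[1]
    vip = np.sqrt(p * (W**2 @ ssy) / ssy.sum())

    ssx_total = float((X**2).sum())
    P = pls.x_loadings_
    explained = np.array(
        [(T[:, a] @ T[:, a]) * (P[:, a] @ P[:, a]) / ssx_total for a in range(k)]
    )
    model = LatentModel(
        scores=T,
        loadings=P,
        explained=explained,
        feature_ids=list(table.feature_ids),
        sample_ids=list(table.samples),
        weights=W,
        y_encoding=Y,
        group_order=order,
    )
    return model, dict(zip(table.feature_ids, vip.tolist()))


@dataclass(frozen=True)
class DifferentialResult:
    """Volcano + VIP outcome for one feature in one group pair."""

    feature_id: str
    group_pair: Tuple[str, str]
    log2_fc: float
    p_value: float
    direction: str                  # up | down | ns (relative to group_a)
    vip: Optional[float] = None
    selected: bool = False


def volcano(
    table: FeatureTable,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    bh_correction: bool = False,
) -> List[DifferentialResult]:
    """Pairwise fold-change / significance analysis of two groups.

    The fold change is the ratio of arithmetic group means of raw areas
    (group_a over group_b); p-values are two-sided Welch t-tests on
    log-transformed areas. When zeros are present, half the smallest
    positive area in the two groups is added before log and ratio. A
    feature is ``up`` when FC >= fc_threshold and p < p_threshold,
    ``down`` when 1/FC >= fc_threshold and p < p_threshold, else ``ns``.
    With `bh_correction`, Benjamini-Hochberg adjusted p-values are used
    for the significance test.
    """
    idx_a = table.samples_in_group(group_a)
    idx_b = table.samples_in_group(group_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError(
            f"groups {group_a!r} and {group_b!r} need at least 2 samples each"
        )
    sub = table.areas[:, idx_a + idx_b]
    offset = 0.0
    if np.any(sub == 0):
        positives = sub[sub > 0]
        if positives.size == 0:
            raise ValueError("all areas are zero in the two groups")
        offset = 0.5 * positives.min()
    A = table.areas[:, idx_a] + offset
    B = table.areas[:, idx_b] + offset

    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    fc = mean_a / mean_b
    log2_fc = np.log2(fc)

    t_res = _scipy_stats.ttest_ind(np.log(A), np.log(B), axis=1, equal_var=False)
    p = np.asarray(t_res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-on-both-sides features
    p_test = multipletests(p, method="fdr_bh")[1] if bh_correction else p

    results = []
    for i, fid in enumerate(table.feature_ids):
        direction = "ns"
        if p_test[i] < p_threshold:
            if fc[i] >= fc_threshold:
                direction = "up"
            elif fc[i] > 0 and 1.0 / fc[i] >= fc_threshold:
                direction = "down"
        results.append(
            DifferentialResult(
                feature_id=fid,
                group_pair=(group_a, group_b),
                log2_fc=float(log2_fc[i]),
                p_value=float(p[i]),
                direction=direction,
            )
        )
    return results


def select_differential(
    volcano_results: Sequence[DifferentialResult],
    vip_map: Mapping[str, float],
    vip_threshold: float = 1.0,
) -> Tuple[List[DifferentialResult], Dict[str, int]]:
    """Intersect volcano-significant features with the VIP criterion.

    Returns the full result list with ``vip`` and ``selected`` filled in,
    plus up/down counts over the selected set. Raises when a volcano
    feature has no VIP score.
    """
    missing = [r.feature_id for r in volcano_results if r.feature_id not in vip_map]
    if missing:
        raise ValueError(f"features without VIP scores: {missing}")
    out = []
    counts = {"up": 0, "down": 0}
    for r in volcano_results:
        v = vip_map[r.feature_id]
        sel = r.direction != "ns" and v > vip_threshold
        out.append(replace(r, vip=v, selected=sel))
        if sel:
            counts[r.direction] += 1
    return out, counts


def collapse_adducts(
    table: FeatureTable, compound_map: Mapping[str, str]
) -> FeatureTable:
    """Keep one feature per annotated compound: the one with highest total area.

    Features absent from `compound_map` (unannotated) are kept as-is. Used
    before heatmap-style summaries so that multiple adduct ions of the same
    compound are not double-counted.
    """
    totals = table.areas.sum(axis=1)
    best: Dict[str, int] = {}
    for i, fid in enumerate(table.feature_ids):
        comp = compound_map.get(fid)
        if comp is None:
            continue
        if comp not in best or totals[i] > totals[best[comp]]:
            best[comp] = i
    keep = sorted(
        set(best.values())
        | {i for i, fid in enumerate(table.feature_ids) if fid not in compound_map}
    )
    return FeatureTable(
        feature_ids=[table.feature_ids[i] for i in keep],
        feature_mz=[table.feature_mz[i] for i in keep],
        feature_rt=[table.feature_rt[i] for i in keep],
        samples=list(table.samples),
        groups=dict(table.groups),
        areas=table.areas[keep, :],
    )
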