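"""Weighted gene co-expression networks: soft-threshold selection, topological
overlap, static-cut module detection, eigengenes, eigengene-based module
merging, and Bonferroni-controlled correlation tables.

Adjacency is unsigned, a_ij = |cor(x_i, x_j)|^beta, with Pearson correlation
throughout.  Module detection uses average-linkage hierarchical clustering of
the TOM dissimilarity with a static height cut; branches smaller than the
minimum module size are relabelled grey (label 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._stats import pearson_pvalue

GREY = 0


def adjacency_matrix(expr_values: np.ndarray, power: int) -> np.ndarray:
    """Unsigned soft-thresholded adjacency |cor|^beta with zero diagonal."""
    A = np.abs(np.corrcoef(expr_values)) ** power
    np.fill_diagonal(A, 0.0)
    return A


def pick_soft_threshold(
    expr_values: np.ndarray, powers: list[int] | None = None, n_bins: int = 10
) -> pd.DataFrame:
    """Scale-free-topology fit index and mean connectivity over candidate powers.

    For each power: connectivity k_i = sum_j a_ij; the fit index is the signed
    r-squared of log10 p(k) against log10 mean k over equal-width bins of k
    (negated when the slope is positive, so scale-free fits score high).
    """
    if expr_values.shape[0] < 20:
        raise ValueError("need at least 20 genes")
    if powers is None:
        powers = list(range(1, 21))
    rows = []
    for beta in powers:
        A = adjacency_matrix(expr_values, beta)
        k = A.sum(axis=1)
        rows.append((beta, _scale_free_r2(k, n_bins), float(k.mean())))
    return pd.DataFrame(rows, columns=["power", "sft_r2", "mean_connectivity"])


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) == 0:
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-9
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    means, freqs = [], []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            means.append(k[m].mean())
            freqs.append(m.mean())
    x = np.log10(np.asarray(means))
    y = np.log10(np.asarray(freqs))
    if x.size < 3 or np.ptp(x) == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    slope = r * y.std() / x.std()
    return float(-np.sign(slope) * r**2)


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with entries in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A  # with zero diagonal this is sum over u != i, j
    numer = shared + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    diss_tom: np.ndarray,
    min_module_size: int = 30,
    static_cut_height: float | None = None,
) -> np.ndarray:
    """Average-linkage clustering of a TOM dissimilarity with a static cut.

    ``static_cut_height=None`` cuts at 99% of the merge-height range.  Labels
    are positive integers ordered by decreasing module size; genes in branches
    below the minimum size get the grey label 0.
    """
    D = np.asarray(diss_tom, dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    n = D.shape[0]
    if min_module_size > n:
        return np.zeros(n, dtype=int)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    if static_cut_height is None:
        static_cut_height = 0.99 * Z[:, 2].max()
    raw = hierarchy.fcluster(Z, t=static_cut_height, criterion="distance")
    return _relabel_by_size(raw, min_module_size)


def _relabel_by_size(raw: np.ndarray, min_size: int) -> np.ndarray:
    labels = np.zeros(raw.size, dtype=int)
    sizes = pd.Series(raw).value_counts()
    nxt = 1
    for lab in sizes.index:
        if sizes[lab] >= min_size:
            labels[raw == lab] = nxt
            nxt += 1
    return labels


def module_eigengene(expr_values: np.ndarray) -> tuple[np.ndarray, float]:
    """First right singular vector of the gene-standardized module submatrix.

    Returns (eigengene over samples with unit norm, variance explained).
    The sign is oriented so the eigengene correlates positively with the mean
    standardized expression of the module.
    """
    X = np.asarray(expr_values, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[0] == 0:
        raise ValueError("empty module")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = Vt[0]
    var_explained = float(S[0] ** 2 / (S**2).sum()) if S.sum() > 0 else 0.0
    if np.dot(eig, Z.mean(axis=0)) < 0:
        eig = -eig
    return eig, var_explained


def eigengene_matrix(expr_values: np.ndarray, assignment: np.ndarray) -> pd.DataFrame:
    """Eigengenes for every non-grey module: samples x modules."""
    mods = sorted(set(assignment) - {GREY})
    cols = {}
    for m in mods:
        eig, _ = module_eigengene(expr_values[assignment == m])
        cols[m] = eig
    return pd.DataFrame(cols)


def module_membership(expr_values: np.ndarray, eigengene: np.ndarray) -> np.ndarray:
    """kME: Pearson correlation of each gene with a module eigengene."""
    X = np.asarray(expr_values, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    e = eigengene - eigengene.mean()
    num = Xc @ e
    den = np.sqrt((Xc**2).sum(axis=1) * (e**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def merge_modules(
    expr_values: np.ndarray,
    assignment: np.ndarray,
    merge_height: float = 0.10,
    max_iter: int = 20,
) -> np.ndarray:
    """Merge modules whose eigengenes cluster below `merge_height` in 1 - cor.

    Average-linkage clustering of eigengene dissimilarity; merging recomputes
    eigengenes and iterates to a fixed point.
    """
    labels = assignment.copy()
    for _ in range(max_iter):
        mods = sorted(set(labels) - {GREY})
        if len(mods) < 2:
            break
        E = eigengene_matrix(expr_values, labels)
        diss = 1.0 - np.corrcoef(E.to_numpy().T)
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2, 0, None)
        Z = hierarchy.linkage(squareform(diss, checks=False), method="average")
        grouping = hierarchy.fcluster(Z, t=merge_height, criterion="distance")
        if len(set(grouping)) == len(mods):
            break
        new = labels.copy()
        for g in set(grouping):
            members = [mods[i] for i in range(len(mods)) if grouping[i] == g]
            target = members[0]
            for m in members[1:]:
                new[labels == m] = target
        labels = _relabel_by_size(new, 1)
    return labels


def correlate_bonferroni(
    X: pd.DataFrame, Y: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise Pearson correlations between rows of X and rows of Y.

    Returns a long table (x, y, r, p, significant) with the Bonferroni
    threshold alpha / (number of testable pairs).  Zero-variance profiles are
    flagged and excluded from the family.
    """
    common = X.columns.intersection(Y.columns)
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    Xv = X[common].to_numpy(dtype=float)
    Yv = Y[common].to_numpy(dtype=float)
    n = len(common)
    ok_x = Xv.std(axis=1) > 0
    ok_y = Yv.std(axis=1) > 0
    rows = []
    n_pairs = int(ok_x.sum() * ok_y.sum())
    thr = alpha / n_pairs if n_pairs else np.nan
    Zx = (Xv - Xv.mean(axis=1, keepdims=True))
    Zy = (Yv - Yv.mean(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Zx @ Zy.T) / np.sqrt(
            np.outer((Zx**2).sum(axis=1), (Zy**2).sum(axis=1))
        )
    P = pearson_pvalue(R, n)
    for i, xi in enumerate(X.index):
        for j, yj in enumerate(Y.index):
            if not (ok_x[i] and ok_y[j]):
                rows.append((xi, yj, np.nan, np.nan, False))
            else:
                rows.append((xi, yj, R[i, j], P[i, j], bool(P[i, j] < thr)))
    return pd.DataFrame(rows, columns=["x", "y", "r", "p", "significant"])


@dataclass
class Network:
    """A completed co-expression network for one tissue."""

    power: int
    assignment: np.ndarray
    eigengenes: pd.DataFrame
    merge_height: float
    gene_ids: list


def build_network(
    expr: pd.DataFrame,
    power: int,
    min_module_size: int = 30,
    static_cut_height: float | None = None,
    merge_height: float = 0.10,
) -> Network:
    """Adjacency -> TOM -> static-cut modules -> eigengene merge, end to end."""
    V = expr.to_numpy(dtype=float)
    A = adjacency_matrix(V, power)
    diss = 1.0 - tom_similarity(A)
    labels = detect_modules(diss, min_module_size, static_cut_height)
    labels = merge_modules(V, labels, merge_height)
    E = eigengene_matrix(V, labels)
    E.index = expr.columns
    return Network(power, labels, E, merge_height, list(expr.index))
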