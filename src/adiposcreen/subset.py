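"""Exhaustive best-subset regression of a NAFLD trait on candidate gene
expression, with BIC model choice and a random-gene permutation null.

The response (histology grade, treated as numeric) and the candidate
expression are both residualized against covariates before the search; the
permutation p-value is the proportion of random same-size gene sets from the
expressed-gene universe whose r-squared strictly exceeds the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class SubsetResult:
    chosen: tuple
    r2: float
    bic_by_size: dict
    best_by_size: dict
    permutation_p: float | None = None
    permutation_p_smoothed: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    pool: list = field(default_factory=list)


def _residualize_against(y: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    if C is None:
        return y - y.mean(axis=0)
    D = np.column_stack([np.ones(C.shape[0]), C])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return y - D @ beta


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    """RSS of OLS of y on [1 | X]; pseudo-inverse on collinear inputs."""
    D = np.column_stack([np.ones(X.shape[0]), X])
    beta, res, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    if rank < D.shape[1]:
        warnings.warn("collinear candidates; using pseudo-inverse fit")
    fitted = D @ beta
    return float(np.sum((y - fitted) ** 2))


def r2_explained(
    y: np.ndarray, X_subset: np.ndarray, covariates: np.ndarray | None = None
) -> float:
    """Coefficient of determination of y on a gene subset, both sides
    residualized against the covariates first."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X_subset, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n = y.size
    if n <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors")
    yr = _residualize_against(y, covariates)
    Xr = _residualize_against(X, covariates)
    tss = float(np.sum((yr - yr.mean()) ** 2))
    if tss == 0:
        return 0.0
    return 1.0 - _rss(yr, Xr) / tss


def best_subset_search(
    y: np.ndarray,
    X: pd.DataFrame,
    max_size: int | None = None,
    covariates: np.ndarray | None = None,
) -> SubsetResult:
    """Exhaustively search gene subsets of each size for minimum RSS, then
    choose the size by BIC = n*ln(RSS/n) + (k+1)*ln(n).

    `X` is samples x candidate genes.  Ties in RSS break lexicographically on
    the sorted gene-id tuple.  Candidate pools are capped at 20 genes (2^20
    fits).
    """
    y = np.asarray(y, dtype=float)
    genes = list(X.columns)
    p = len(genes)
    if p > 20:
        raise ValueError("exhaustive search capped at 20 candidates")
    if max_size is None:
        max_size = p
    n = y.size
    yr = _residualize_against(y, covariates)
    Xr = _residualize_against(X.to_numpy(dtype=float), covariates)
    tss = float(np.sum((yr - yr.mean()) ** 2))

    best_by_size: dict[int, tuple] = {}
    rss_by_size: dict[int, float] = {}
    best_by_size[0] = ()
    rss_by_size[0] = tss
    for k in range(1, max_size + 1):
        best_rss, best_set = np.inf, None
        for combo in combinations(range(p), k):
            rss = _rss(yr, Xr[:, combo])
            ids = tuple(sorted(genes[i] for i in combo))
            if rss < best_rss - 1e-12 or (
                abs(rss - best_rss) <= 1e-12 and (best_set is None or ids < best_set)
            ):
                best_rss, best_set = rss, ids
        best_by_size[k] = best_set
        rss_by_size[k] = best_rss

    bic_by_size = {
        k: n * np.log(max(rss_by_size[k], 1e-300) / n) + (k + 1) * np.log(n)
        for k in best_by_size
    }
    k_star = min(bic_by_size, key=lambda k: (bic_by_size[k], k))
    chosen = best_by_size[k_star]
    r2 = 0.0 if k_star == 0 else 1.0 - rss_by_size[k_star] / tss
    return SubsetResult(chosen, float(r2), bic_by_size, best_by_size, pool=genes)


def permutation_pvalue(
    r2_obs: float,
    y: np.ndarray,
    expression_universe: pd.DataFrame,
    m: int,
    B: int = 10_000,
    seed: int = 0,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Permutation null for a best-subset model's r-squared.

    Draws B random m-gene sets from the expressed-gene universe (samples x
    genes), fits each by OLS on the identical residualized design, and
    returns (plain p, add-one smoothed p) where plain p uses the strict
    comparison  p = #{r2_perm > r2_obs} / B.
    """
    if B < 100:
        warnings.warn("B < 100 gives poor p-value resolution")
    genes = expression_universe.shape[1]
    if genes < m:
        raise ValueError("universe smaller than subset size")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    yr = _residualize_against(y, covariates)
    yr = yr - yr.mean()
    Xall = _residualize_against(expression_universe.to_numpy(dtype=float), covariates)
    Xall = Xall - Xall.mean(axis=0)
    tss = float(np.sum(yr**2))

    picks = np.empty((B, m), dtype=int)
    for b in range(B):
        picks[b] = rng.choice(genes, size=m, replace=False)
    # batched OLS through normal equations on centered data (intercept absorbed),
    # chunked to bound memory at large B
    r2_perm = np.empty(B)
    chunk = 5000
    eye = 1e-10 * np.eye(m)[None, :, :]
    for lo in range(0, B, chunk):
        sel = picks[lo : lo + chunk]
        Xb = np.moveaxis(Xall[:, sel], 1, 0)  # b x n x m
        G = np.einsum("bnm,bnk->bmk", Xb, Xb) + eye
        c = np.einsum("bnm,n->bm", Xb, yr)
        beta = np.linalg.solve(G, c[..., None])[..., 0]
        r2_perm[lo : lo + chunk] = np.einsum("bm,bm->b", beta, c) / tss
    p_plain = float(np.mean(r2_perm > r2_obs))
    p_smooth = float((np.sum(r2_perm > r2_obs) + 1) / (B + 1))
    return p_plain, p_smooth
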