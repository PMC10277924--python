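"""Case-control differential expression with precision weights and
empirical-Bayes moderated t-statistics, plus cross-tissue "aware" DE sets and
hypergeometric over-representation tests.

The case rule follows liver histology grading: a sample is a case for a trait
(steatosis, fibrosis, NASH) when its grade for that trait is nonzero, and a
control only when all three grades are zero; intermediate samples are neither.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._stats import bh_adjust
from .prep import CountMatrix, ExpressionMatrix

log = logging.getLogger(__name__)

TRAITS = ("steatosis", "fibrosis", "NASH")


@dataclass
class CaseControlDesign:
    trait: str
    case_ids: list[str]
    control_ids: list[str]
    design: pd.DataFrame  # samples x columns, includes intercept + group + covariates

    @property
    def sample_ids(self) -> list[str]:
        return list(self.design.index)


def build_case_control(
    pheno: pd.DataFrame,
    trait: str,
    covariates: pd.DataFrame | None = None,
) -> CaseControlDesign:
    """Construct the case/control contrast for one NAFLD histology trait.

    Cases: nonzero grade for `trait`.  Controls: zero grade for all three
    traits.  Samples that are neither (for example fibrosis-only samples in a
    steatosis contrast) are excluded.
    """
    if trait not in TRAITS:
        raise ValueError(f"trait must be one of {TRAITS}")
    for t in TRAITS:
        if t not in pheno.columns:
            raise ValueError(f"phenotype table lacks grade column '{t}'")
    cases = pheno.index[pheno[trait] > 0]
    controls = pheno.index[(pheno[list(TRAITS)] == 0).all(axis=1)]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError(f"trait {trait}: zero cases or zero controls")
    ids = list(cases) + list(controls)
    group = pd.Series(np.r_[np.ones(len(cases)), np.zeros(len(controls))], index=ids)
    cols = {"intercept": np.ones(len(ids)), "group": group}
    design = pd.DataFrame(cols, index=ids)
    if covariates is not None:
        design = pd.concat([design, covariates.reindex(ids)], axis=1)
    log.info("trait %s: %d cases, %d controls", trait, len(cases), len(controls))
    return CaseControlDesign(trait, list(cases), list(controls), design)


def voom_weights(
    log_cpm_expr: ExpressionMatrix,
    design: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    span: float = 0.5,
) -> np.ndarray:
    """Per-observation precision weights from the mean-variance trend.

    Fits sqrt(residual SD) against mean log-count per gene with lowess, then
    predicts a SD for every fitted observation and returns weight = SD^-4.
    """
    Y = log_cpm_expr.values.reindex(columns=design.index).to_numpy(dtype=float)
    D = design.to_numpy(dtype=float)
    n_genes, n = Y.shape
    if n_genes < 10:
        warnings.warn("fewer than 10 genes: returning flat voom weights")
        return np.ones_like(Y)
    if lib_sizes is None:
        eff = log_cpm_expr.meta.get("effective_lib")
        if eff is not None:
            lib = pd.Series(eff).reindex(design.index).to_numpy(dtype=float)
        else:
            lib = np.full(n, 1e6)
    else:
        lib = lib_sizes.reindex(design.index).to_numpy(dtype=float)

    beta, *_ = np.linalg.lstsq(D, Y.T, rcond=None)
    fitted = (D @ beta).T
    resid = Y - fitted
    df = n - D.shape[1]
    sd = np.sqrt((resid**2).sum(axis=1) / df)

    # mean log2-count per gene: shift log-cpm by the (log) geometric mean library size
    log_gm_lib = np.mean(np.log2(lib + 1))
    sx = Y.mean(axis=1) + log_gm_lib - np.log2(1e6)
    sy = np.sqrt(sd)
    fit = lowess(sy, sx, frac=span, return_sorted=True)
    fx, fy = fit[:, 0], fit[:, 1]

    fitted_logcount = fitted + (np.log2(lib + 1) - np.log2(1e6))[None, :]
    pred_sqrt_sd = np.interp(fitted_logcount, fx, fy, left=fy[0], right=fy[-1])
    pred_sqrt_sd = np.clip(pred_sqrt_sd, 1e-6, None)
    return pred_sqrt_sd**-4


def _trigamma_inverse(x: float) -> float:
    """Solve polygamma(1, y) = x for y > 0 (Newton on the limma recipe)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_variances(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate the inverse-chi-square prior (d0, s0^2) by moment matching on
    log sample variances.

    log s2_g is log s0^2 plus independent log-chi-square noise; matching the
    mean and variance of e_g = log s2_g - digamma(df/2) + log(df/2) gives the
    closed-form prior.  Returns (d0, s0sq); d0 = inf when the observed spread
    is at or below the pure sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if pos.sum() < 2:
        # no cross-gene information: fall back to the unmoderated variance
        return 0.0, float(s2[pos].mean()) if pos.any() else 1.0
    e = np.log(s2[pos]) - special.digamma(df / 2) + np.log(df / 2)
    ev = np.var(e, ddof=1)
    excess = ev - special.polygamma(1, df / 2)
    if excess <= 0:
        d0 = np.inf
        s0sq = float(np.exp(np.mean(e)))
    else:
        half_d0 = _trigamma_inverse(excess)
        d0 = 2 * half_d0
        s0sq = float(np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0sq


def fit_moderated(
    expr: ExpressionMatrix,
    design: pd.DataFrame,
    contrast: str = "group",
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene weighted least squares with empirical-Bayes variance moderation.

    Returns a table with columns ``logFC t p adj_p mean_expr`` indexed by gene.
    The moderated t divides the coefficient by its standard error scaled to
    the posterior residual variance, with d0 + df degrees of freedom.
    """
    D = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("design is rank deficient")
    Y = expr.values.reindex(columns=design.index).to_numpy(dtype=float)
    n_genes, n = Y.shape
    p = D.shape[1]
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    W = np.ones_like(Y) if weights is None else np.asarray(weights, dtype=float)
    ci = list(design.columns).index(contrast)

    # batched weighted normal equations: A_g = X' W_g X, b_g = X' W_g y_g
    A = np.einsum("gn,np,nq->gpq", W, D, D)
    b = np.einsum("gn,np,gn->gp", W, D, Y)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    fitted = np.einsum("np,gp->gn", D, beta)
    rss = np.einsum("gn,gn->g", W, (Y - fitted) ** 2)
    s2 = rss / df
    Ainv = np.linalg.inv(A)
    unscaled_var = Ainv[:, ci, ci]

    usable = s2 > 0
    if not usable.all():
        log.info("excluding %d genes with zero residual variance", int((~usable).sum()))
    d0, s0sq = moderate_variances(s2[usable], df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = d0 + df

    coef = beta[:, ci]
    se_post = np.sqrt(unscaled_var * s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se_post
    if np.isinf(df_total):
        pval = 2 * stats.norm.sf(np.abs(t))
    else:
        pval = 2 * stats.t.sf(np.abs(t), df=df_total)
    pval = np.where(usable, pval, np.nan)

    tab = pd.DataFrame(
        {
            "logFC": coef,
            "t": t,
            "p": pval,
            "adj_p": bh_adjust(pval),
            "mean_expr": Y.mean(axis=1),
        },
        index=expr.gene_ids,
    )
    return tab


@dataclass
class AwareSets:
    """Union and per-trait tissue-exclusive DE gene sets."""

    union_a: set
    union_b: set
    aware_union: set
    per_trait: dict = field(default_factory=dict)


def aware_de_sets(
    de_a: dict[str, pd.DataFrame],
    de_b: dict[str, pd.DataFrame],
    fdr: float = 0.05,
    strict_per_trait: bool = False,
) -> AwareSets:
    """Genes DE in tissue A but not in tissue B.

    The default removes any gene DE in tissue B for *any* of the traits;
    `strict_per_trait` only removes genes DE in B for the same trait.
    """
    if set(de_a) != set(de_b):
        raise ValueError("both tissues must be tested on the same trait list")
    sig_a = {t: set(tab.index[tab["adj_p"] < fdr]) for t, tab in de_a.items()}
    sig_b = {t: set(tab.index[tab["adj_p"] < fdr]) for t, tab in de_b.items()}
    union_a = set().union(*sig_a.values())
    union_b = set().union(*sig_b.values())
    per_trait = {}
    for t in de_a:
        drop = sig_b[t] if strict_per_trait else union_b
        per_trait[t] = sig_a[t] - drop
    return AwareSets(union_a, union_b, union_a - union_b, per_trait)


def hypergeometric_enrichment(
    hits: set, annotation_set: set, universe: set
) -> tuple[float, float]:
    """Over-representation of `annotation_set` among `hits` within `universe`.

    Returns (p, fold): p = P(X >= overlap) for X ~ Hypergeom(N, K, n),
    fold = observed / expected overlap.
    """
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe or not annotation_set <= universe:
        raise ValueError("hits and annotation_set must be subsets of the universe")
    N, K, n = len(universe), len(annotation_set), len(hits)
    k = len(hits & annotation_set)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    expected = K * n / N
    fold = k / expected if expected > 0 else np.nan
    return p, fold


def de_restricted(
    counts: CountMatrix,
    groups: pd.Series,
    gene_subset: list[str],
    min_group_total: int = 10,
    require_both_groups: bool = False,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Covariate-free two-group DE restricted to a gene subset.

    Genes must exceed `min_group_total` summed counts in at least one group
    (or both with ``require_both_groups``).  BH adjustment runs over the
    retained subset only — the contract used for small perturbation
    experiments (siRNA knockdowns, treatment assays).
    """
    from .prep import log_cpm, tmm_factors

    if not gene_subset:
        raise ValueError("gene_subset must be nonempty")
    present = [g for g in gene_subset if g in counts.gene_ids]
    missing = set(gene_subset) - set(present)
    if missing:
        warnings.warn(f"{len(missing)} subset genes absent from the count matrix; skipped")
    groups = groups.reindex(counts.sample_ids)
    g0 = counts.values.loc[present, groups == groups.unique()[0]].sum(axis=1)
    g1 = counts.values.loc[present, groups == groups.unique()[1]].sum(axis=1)
    if require_both_groups:
        keep = (g0 > min_group_total) & (g1 > min_group_total)
    else:
        keep = (g0 > min_group_total) | (g1 > min_group_total)
    kept = [g for g in present if keep[g]]

    factors = tmm_factors(counts)
    expr = log_cpm(counts, factors, prior_count=prior_count)
    expr_sub = ExpressionMatrix(expr.values.loc[kept], expr.transform, expr.meta)
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "group": (groups == groups.unique()[1]).astype(float),
        },
        index=counts.sample_ids,
    )
    w = voom_weights(expr_sub, design)
    return fit_moderated(expr_sub, design, "group", weights=w)
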