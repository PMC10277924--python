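"""Genetic association machinery: cis-eQTL mapping, LD r-squared, Wakefield
approximate Bayes factors, and enumeration-based colocalization posteriors.

The colocalization model assigns each variant pair configuration to one of
five hypotheses (no association, trait-1 only, trait-2 only, two distinct
causal variants, one shared causal variant) and computes posteriors from
per-variant log-ABFs in log space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, logdiffexp, logsumexp

log = logging.getLogger(__name__)


def map_cis_eqtls(
    expr: pd.DataFrame,
    dosages: pd.DataFrame,
    gene_coords: pd.DataFrame,
    variant_meta: pd.DataFrame,
    window: int = 1_000_000,
    cis_anchor: str = "both",
) -> pd.DataFrame:
    """Per gene-variant-pair linear eQTL scan within a cis window.

    `expr` is genes x samples (corrected expression), `dosages` samples x
    variants in [0, 2], `gene_coords` has chrom/start/end per gene and
    `variant_meta` chrom/pos per variant.  A variant is tested when it lies
    within `window` of either gene boundary (``cis_anchor="both"``) or of the
    gene end only (``cis_anchor="end_only"``).  Returns a table
    ``gene variant slope se t p fdr`` with BH FDR over all tested pairs.
    """
    if cis_anchor not in ("both", "end_only"):
        raise ValueError("cis_anchor must be 'both' or 'end_only'")
    samples = expr.columns.intersection(dosages.index)
    G = dosages.loc[samples].to_numpy(dtype=float)
    n = len(samples)
    rows = []
    vmeta = variant_meta[["chrom", "pos"]]
    for gene in expr.index:
        if gene not in gene_coords.index:
            continue
        chrom = gene_coords.at[gene, "chrom"]
        start = int(gene_coords.at[gene, "start"])
        end = int(gene_coords.at[gene, "end"])
        m = vmeta["chrom"] == chrom
        if cis_anchor == "both":
            m &= (vmeta["pos"] >= start - window) & (vmeta["pos"] <= end + window)
        else:
            m &= (vmeta["pos"] >= end - window) & (vmeta["pos"] <= end + window)
        vids = vmeta.index[m]
        if len(vids) == 0:
            continue
        y = expr.loc[gene, samples].to_numpy(dtype=float)
        yc = y - y.mean()
        cols = [dosages.columns.get_loc(v) for v in vids]
        X = G[:, cols]
        xm = X.mean(axis=0)
        Xc = X - xm
        sxx = (Xc**2).sum(axis=0)
        mono = sxx <= 0
        if mono.any():
            log.info("skipping %d monomorphic variants for gene %s", int(mono.sum()), gene)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (Xc * yc[:, None]).sum(axis=0) / sxx
            rss = (yc**2).sum() - slope**2 * sxx
            sigma2 = rss / (n - 2)
            se = np.sqrt(sigma2 / sxx)
            t = slope / se
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        for j, v in enumerate(vids):
            if mono[j]:
                continue
            rows.append((gene, v, slope[j], se[j], t[j], p[j]))
    tab = pd.DataFrame(rows, columns=["gene", "variant", "slope", "se", "t", "p"])
    tab["fdr"] = bh_adjust(tab["p"].to_numpy()) if len(tab) else []
    return tab


def ld_r2(dosages: pd.DataFrame, variants: list | None = None) -> pd.DataFrame:
    """Squared Pearson correlation between dosage vectors.

    Missing dosages are handled pairwise-complete; zero-variance variants get
    NaN rows/columns.
    """
    D = dosages if variants is None else dosages[list(variants)]
    if D.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if D.isna().any().any():
        r = D.corr(method="pearson", min_periods=2)
    else:
        X = D.to_numpy(dtype=float)
        sd = X.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r_np = np.corrcoef(X.T)
        r_np[sd == 0, :] = np.nan
        r_np[:, sd == 0] = np.nan
        r = pd.DataFrame(r_np, index=D.columns, columns=D.columns)
    return r**2


def wakefield_abf(beta: np.ndarray, se: np.ndarray, prior_sd: float = 0.15) -> np.ndarray:
    """Log approximate Bayes factor for a single-variant association.

    With z = beta/se, V = se^2, W = prior_sd^2, r = W/(W+V):
    log ABF = 0.5*[log(1-r) + r*z^2].
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    z = beta / se
    V = se**2
    W = prior_sd**2
    r = W / (W + V)
    return 0.5 * (np.log1p(-r) + r * z**2)


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    priors: tuple
    labf1: pd.Series
    labf2: pd.Series
    lead1: str
    lead2: str
    n_variants: int

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def coloc_abf(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.15,
) -> ColocResult:
    """Enumeration colocalization from two summary-statistic tables.

    Each table must be indexed by variant id with `beta` and `se` columns;
    only the shared variants are used.  Posteriors are computed entirely in
    log space.
    """
    shared = stats1.index.intersection(stats2.index)
    if len(shared) < 2:
        warnings.warn("fewer than 2 shared variants; H3 is not identifiable")
    if len(shared) == 0:
        raise ValueError("no shared variants")
    l1 = pd.Series(
        wakefield_abf(stats1.loc[shared, "beta"], stats1.loc[shared, "se"], prior_sd1),
        index=shared,
    )
    l2 = pd.Series(
        wakefield_abf(stats2.loc[shared, "beta"], stats2.loc[shared, "se"], prior_sd2),
        index=shared,
    )
    s1 = logsumexp(l1.to_numpy())
    s2 = logsumexp(l2.to_numpy())
    s12 = logsumexp(l1.to_numpy() + l2.to_numpy())
    h = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + logdiffexp(s1 + s2, s12),
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(h - logsumexp(h))
    pp /= pp.sum()
    return ColocResult(
        pp=pp,
        priors=(p1, p2, p12),
        labf1=l1,
        labf2=l2,
        lead1=str(l1.idxmax()),
        lead2=str(l2.idxmax()),
        n_variants=len(shared),
    )


def mask_second_signal(
    stats: pd.DataFrame, ld: pd.DataFrame, lead: str, r2_mask: float = 0.2
) -> pd.DataFrame:
    """Drop the lead variant's LD neighbourhood (r^2 > r2_mask) ahead of a
    second colocalization pass.

    The lead itself always goes (its self-r^2 of 1 exceeds any mask below 1).
    With ``r2_mask=0`` every variant with any nonzero correlation to the lead
    is removed.
    """
    if lead not in stats.index:
        raise ValueError(f"lead variant {lead} not in stats")
    r2 = ld[lead].reindex(stats.index)
    keep = ~(r2 > r2_mask).fillna(False)
    return stats.loc[keep]
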