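"""Two-sample Mendelian randomization: instrument selection from aware-DE
gene cis regions, allele harmonization, and the IVW, Egger and PRESSO
estimators.

Forward direction: exposure = serum triglyceride GWAS, outcome = NAFLD GWAS,
instruments drawn from adipose cis-eQTLs of adipose-aware DE genes.  The
reverse direction swaps the two GWAS tables and uses liver genes/eQTLs; the
cascade is identical up to the direction tag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import coloc_abf

log = logging.getLogger(__name__)

PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


def is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1.upper(), a2.upper())) in PALINDROMIC


@dataclass
class IVThresholds:
    gwas_p: float = 5e-8
    eqtl_fdr: float = 0.05
    pp4: float = 0.8
    ld_outcome_r2: float = 0.2
    ld_prune_r2: float = 0.2
    window: int = 1_000_000


@dataclass
class IVSet:
    table: pd.DataFrame  # columns: SNP effect_allele other_allele beta.exposure se.exposure beta.outcome se.outcome gene pp4
    audit: list = field(default_factory=list)
    direction: str = "forward"

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def failed(self) -> bool:
        """Explicit zero-instrument failure state."""
        return self.n == 0


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    p: float
    n_iv: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q: float | None = None
    q_p: float | None = None
    global_rss: float | None = None
    global_p: float | None = None
    outlier_flags: np.ndarray | None = None


def harmonize(exposure: pd.Series, outcome: pd.Series) -> pd.Series | None:
    """Align an outcome record to the exposure's effect-allele convention.

    Returns the harmonized outcome record, or None when the variant must be
    dropped (palindromic alleles, or alleles incompatible beyond a swap).
    """
    ea, oa = str(exposure["effect_allele"]).upper(), str(exposure["other_allele"]).upper()
    eb, ob = str(outcome["effect_allele"]).upper(), str(outcome["other_allele"]).upper()
    if is_palindromic(ea, oa):
        log.info("dropping palindromic variant %s", exposure.get("variant", "?"))
        return None
    if (ea, oa) == (eb, ob):
        return outcome
    if (ea, oa) == (ob, eb):
        out = outcome.copy()
        out["beta"] = -outcome["beta"]
        out["effect_allele"], out["other_allele"] = ea, oa
        return out
    log.info("dropping allele-incompatible variant %s", exposure.get("variant", "?"))
    return None


def select_ivs(
    aware_genes: set,
    eqtls: pd.DataFrame,
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    dosage_r2: pd.DataFrame,
    gene_coords: pd.DataFrame,
    variant_meta: pd.DataFrame,
    thresholds: IVThresholds | None = None,
    direction: str = "forward",
) -> IVSet:
    """Instrument-selection cascade over aware-DE gene cis regions.

    Steps, in order, with audit counts recorded after each:

    1. candidate regions: aware genes with a significant cis-eQTL
       (FDR < 0.05) and an exposure GWAS hit (p < 5e-8) that is not also an
       outcome GWAS hit (outcome p >= 5e-8) inside the cis window;
    2. colocalization of the exposure GWAS with the gene's eQTL profile,
       keeping regions with PP4 >= threshold;
    3. IV candidates = significant colocalized cis-eQTL variants present in
       both GWAS tables;
    4. drop candidates in LD (r^2 > 0.2) with any outcome GWAS hit in the
       region;
    5. LD prune at r^2 > 0.2, keeping the candidate with the smallest
       rank(eQTL p) + rank(exposure GWAS p), ties by eQTL p then variant id;
    6. drop strand-ambiguous (A/T, C/G) variants;
    7. harmonize outcome records to the exposure allele convention.
    """
    th = thresholds or IVThresholds()
    audit: list[tuple[str, int]] = [("aware_genes", len(aware_genes))]

    sig_eqtl = eqtls[eqtls["fdr"] < th.eqtl_fdr]
    region_vars: dict[str, pd.Index] = {}
    valid_regions: list[str] = []
    for gene in sorted(aware_genes):
        if gene not in gene_coords.index:
            continue
        chrom = gene_coords.at[gene, "chrom"]
        start, end = int(gene_coords.at[gene, "start"]), int(gene_coords.at[gene, "end"])
        inwin = (
            (variant_meta["chrom"] == chrom)
            & (variant_meta["pos"] >= start - th.window)
            & (variant_meta["pos"] <= end + th.window)
        )
        vids = variant_meta.index[inwin]
        region_vars[gene] = vids
        has_eqtl = ((sig_eqtl["gene"] == gene) & sig_eqtl["variant"].isin(vids)).any()
        exp_region = exposure_stats.index.intersection(vids)
        exp_hits = exp_region[exposure_stats.loc[exp_region, "p"] < th.gwas_p]
        # an exposure hit counts only when it is not itself an outcome hit
        clean_hits = [
            v
            for v in exp_hits
            if v not in outcome_stats.index or outcome_stats.at[v, "p"] >= th.gwas_p
        ]
        if has_eqtl and clean_hits:
            valid_regions.append(gene)
    audit.append(("valid_cis_regions", len(valid_regions)))

    coloc_regions: list[str] = []
    pp4_by_gene: dict[str, float] = {}
    for gene in valid_regions:
        vids = region_vars[gene]
        etab = (
            sig_eqtl[sig_eqtl["gene"] == gene]
            .set_index("variant")[["slope", "se"]]
            .rename(columns={"slope": "beta"})
        )
        full_etab = (
            eqtls[eqtls["gene"] == gene]
            .set_index("variant")[["slope", "se"]]
            .rename(columns={"slope": "beta"})
        )
        shared = full_etab.index.intersection(exposure_stats.index).intersection(vids)
        if len(shared) < 2:
            continue
        res = coloc_abf(exposure_stats.loc[shared], full_etab.loc[shared])
        pp4_by_gene[gene] = res.pp4
        if res.pp4 >= th.pp4:
            coloc_regions.append(gene)
    audit.append(("colocalized_regions", len(coloc_regions)))

    cand_rows = []
    for gene in coloc_regions:
        vids = region_vars[gene]
        etab = sig_eqtl[(sig_eqtl["gene"] == gene) & sig_eqtl["variant"].isin(vids)]
        for _, r in etab.iterrows():
            v = r["variant"]
            if v in exposure_stats.index and v in outcome_stats.index:
                cand_rows.append(
                    {
                        "SNP": v,
                        "gene": gene,
                        "eqtl_p": r["p"],
                        "gwas_p": exposure_stats.at[v, "p"],
                        "pp4": pp4_by_gene[gene],
                    }
                )
    cand = pd.DataFrame(cand_rows).drop_duplicates(subset="SNP")
    audit.append(("coloc_eqtl_candidates", len(cand)))

    if len(cand):
        out_hits = [
            v
            for gene in coloc_regions
            for v in outcome_stats.index.intersection(region_vars[gene])
            if outcome_stats.at[v, "p"] < th.gwas_p
        ]
        keep = []
        for _, r in cand.iterrows():
            v = r["SNP"]
            linked = any(
                h in dosage_r2.columns
                and v in dosage_r2.index
                and dosage_r2.at[v, h] > th.ld_outcome_r2
                for h in out_hits
            )
            if not linked:
                keep.append(v)
        cand = cand[cand["SNP"].isin(keep)]
    audit.append(("after_outcome_ld_filter", len(cand)))

    if len(cand):
        cand = cand.copy()
        cand["score"] = (
            cand["eqtl_p"].rank(method="average") + cand["gwas_p"].rank(method="average")
        )
        cand = cand.sort_values(["score", "eqtl_p", "SNP"]).reset_index(drop=True)
        accepted: list[str] = []
        for _, r in cand.iterrows():
            v = r["SNP"]
            linked = any(
                a in dosage_r2.columns
                and v in dosage_r2.index
                and dosage_r2.at[v, a] > th.ld_prune_r2
                for a in accepted
            )
            if not linked:
                accepted.append(v)
        cand = cand[cand["SNP"].isin(accepted)]
    audit.append(("after_ld_prune", len(cand)))

    rows = []
    for _, r in cand.iterrows():
        v = r["SNP"]
        exp = exposure_stats.loc[v].copy()
        exp["variant"] = v
        if is_palindromic(exp["effect_allele"], exp["other_allele"]):
            continue
        out = harmonize(exp, outcome_stats.loc[v])
        if out is None:
            continue
        rows.append(
            {
                "SNP": v,
                "effect_allele": str(exp["effect_allele"]).upper(),
                "other_allele": str(exp["other_allele"]).upper(),
                "beta.exposure": float(exp["beta"]),
                "se.exposure": float(exp["se"]),
                "beta.outcome": float(out["beta"]),
                "se.outcome": float(out["se"]),
                "gene": r["gene"],
                "pp4": r["pp4"],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "SNP",
            "effect_allele",
            "other_allele",
            "beta.exposure",
            "se.exposure",
            "beta.outcome",
            "se.outcome",
            "gene",
            "pp4",
        ],
    )
    audit.append(("final_ivs", len(table)))
    if len(table) == 0:
        log.warning("IV cascade (%s direction) ended with zero valid instruments", direction)
    return IVSet(table=table, audit=audit, direction=direction)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sey: np.ndarray) -> tuple[float, float]:
    w = 1.0 / sey**2
    denom = np.sum(w * bx**2)
    beta = np.sum(w * bx * by) / denom
    se = denom**-0.5
    return float(beta), float(se)


def mr_ivw(ivset: IVSet, random_effects: bool = False) -> MRResult:
    """Inverse-variance-weighted estimator; Wald ratio when J = 1.

    beta = sum(bx*by/sey^2) / sum(bx^2/sey^2); Cochran's Q reported; with
    ``random_effects`` the SE is inflated by max(1, sqrt(Q/(J-1))).
    """
    t = ivset.table
    if len(t) == 0:
        raise ValueError("empty IV set")
    bx = t["beta.exposure"].to_numpy(dtype=float)
    by = t["beta.outcome"].to_numpy(dtype=float)
    sey = t["se.outcome"].to_numpy(dtype=float)
    if len(t) == 1 and bx[0] == 0:
        raise ValueError("single IV with zero exposure effect")
    beta, se = _ivw_core(bx, by, sey)
    j = len(t)
    q = float(np.sum((by - beta * bx) ** 2 / sey**2))
    q_p = float(stats.chi2.sf(q, df=j - 1)) if j > 1 else np.nan
    if random_effects and j > 1:
        se *= max(1.0, np.sqrt(q / (j - 1)))
    p = 2 * stats.norm.sf(abs(beta / se))
    return MRResult("ivw", beta, se, float(p), j, q=q, q_p=q_p)


def mr_egger(ivset: IVSet) -> MRResult:
    """Egger regression: weighted LS of by on bx with intercept.

    Pairs are oriented so bx >= 0; the intercept estimates directional
    pleiotropy.  SEs use the multiplicative inflation max(1, sqrt(RSS/(J-2)))
    and t reference with J - 2 df.
    """
    t = ivset.table
    j = len(t)
    if j < 3:
        raise ValueError("Egger regression needs at least 3 IVs")
    bx = t["beta.exposure"].to_numpy(dtype=float).copy()
    by = t["beta.outcome"].to_numpy(dtype=float).copy()
    sey = t["se.outcome"].to_numpy(dtype=float)
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    w = 1.0 / sey**2
    X = np.column_stack([np.ones(j), bx])
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * by)
    coef = np.linalg.solve(XtWX, XtWy)
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    phi = max(1.0, rss / (j - 2))
    cov = np.linalg.inv(XtWX) * phi
    se = np.sqrt(np.diag(cov))
    tstats = coef / se
    pvals = 2 * stats.t.sf(np.abs(tstats), df=j - 2)
    return MRResult(
        "egger",
        float(coef[1]),
        float(se[1]),
        float(pvals[1]),
        j,
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_p=float(pvals[0]),
    )


def mr_presso(ivset: IVSet, n_sim: int = 1000, seed: int = 0) -> MRResult:
    """PRESSO global heterogeneity test with per-IV outlier flags.

    Observed statistic: RSS = sum_j w_j (by_j - bx_j * beta_(-j))^2 with
    leave-one-out IVW slopes.  The null distribution comes from a parametric
    bootstrap drawing by* ~ N(bx*beta_(-j), sey^2), bx* ~ N(bx, sex^2).
    Outliers: per-IV residuals beyond their simulated distribution after
    Bonferroni correction.  The point estimate reported is the all-IV IVW.
    """
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives poor p-value resolution")
    t = ivset.table
    j = len(t)
    if j < 4:
        raise ValueError("PRESSO needs at least 4 IVs")
    rng = np.random.default_rng(seed)
    bx = t["beta.exposure"].to_numpy(dtype=float)
    by = t["beta.outcome"].to_numpy(dtype=float)
    sex = t["se.exposure"].to_numpy(dtype=float)
    sey = t["se.outcome"].to_numpy(dtype=float)
    w = 1.0 / sey**2

    def loo_beta(bx_: np.ndarray, by_: np.ndarray) -> np.ndarray:
        s1 = np.sum(w * bx_ * by_)
        s2 = np.sum(w * bx_**2)
        return (s1 - w * bx_ * by_) / (s2 - w * bx_**2)

    b_loo = loo_beta(bx, by)
    res_obs = w * (by - bx * b_loo) ** 2
    rss_obs = float(res_obs.sum())

    bx_star = rng.normal(bx, sex, size=(n_sim, j))
    by_star = rng.normal(bx_star * b_loo[None, :], sey, size=(n_sim, j))
    s1 = np.einsum("j,sj,sj->s", w, bx_star, by_star)
    s2 = np.einsum("j,sj,sj->s", w, bx_star, bx_star)
    b_loo_star = (s1[:, None] - w * bx_star * by_star) / (s2[:, None] - w * bx_star**2)
    res_star = w * (by_star - bx_star * b_loo_star) ** 2
    rss_star = res_star.sum(axis=1)

    global_p = float(np.mean(rss_star >= rss_obs))
    per_iv_p = (res_star >= res_obs[None, :]).mean(axis=0)
    outliers = per_iv_p < 0.05 / j

    beta, se = _ivw_core(bx, by, sey)
    p = 2 * stats.norm.sf(abs(beta / se))
    return MRResult(
        "presso",
        beta,
        se,
        float(p),
        j,
        global_rss=rss_obs,
        global_p=global_p,
        outlier_flags=outliers,
    )
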