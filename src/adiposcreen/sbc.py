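"""Serum-biomarker-candidate (SBC) selection.

An SBC is an adipose-aware DE gene (DE in adipose for a NAFLD trait, not DE
in liver) that encodes a secreted protein, is well expressed in subcutaneous
adipose tissue (median TPM > 30), and is adipose-enriched (adipose/liver
median TPM ratio > 10).  Both thresholds are strict inequalities.  The
cascade keeps a full audit trail of what each filter removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .netcor import correlate_bonferroni

log = logging.getLogger(__name__)


@dataclass
class FilterStep:
    name: str
    n_in: int
    n_out: int
    removed: list


@dataclass
class FilterAudit:
    steps: list[FilterStep] = field(default_factory=list)
    final: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_in, s.n_out) for s in self.steps],
            columns=["filter", "n_in", "n_out"],
        )


def apply_sbc_filters(
    aware_de: set,
    annotation: pd.DataFrame,
    tpm_min: float = 30.0,
    ratio_min: float = 10.0,
) -> FilterAudit:
    """Run the SBC filter cascade over an aware-DE gene set.

    `annotation` must carry columns ``secreted`` (bool), ``adipose_tpm`` and
    ``liver_tpm`` (median TPM).  Genes missing from the annotation fail
    conservatively and are logged in a separate audit bucket.  A liver TPM of
    exactly 0 with positive adipose TPM passes the ratio filter (ratio = inf).
    """
    audit = FilterAudit()
    current = sorted(aware_de)

    missing = [g for g in current if g not in annotation.index]
    if missing:
        audit.notes.append(f"{len(missing)} aware-DE genes missing annotation (failed)")
        log.warning("%d aware-DE genes have no annotation; treated as failing", len(missing))
    annotated = [g for g in current if g in annotation.index]
    audit.steps.append(FilterStep("aware_de_input", len(current), len(annotated), missing))
    current = annotated

    sec = annotation.loc[current, "secreted"].astype(bool)
    keep = [g for g in current if sec[g]]
    audit.steps.append(
        FilterStep("secreted", len(current), len(keep), [g for g in current if not sec[g]])
    )
    current = keep

    tpm = annotation.loc[current, "adipose_tpm"].astype(float)
    keep = [g for g in current if tpm[g] > tpm_min]
    audit.steps.append(
        FilterStep(
            f"adipose_tpm>{tpm_min:g}",
            len(current),
            len(keep),
            [g for g in current if not tpm[g] > tpm_min],
        )
    )
    current = keep

    adip = annotation.loc[current, "adipose_tpm"].astype(float)
    liver = annotation.loc[current, "liver_tpm"].astype(float)
    with np.errstate(divide="ignore"):
        ratio = np.where(liver > 0, adip / liver, np.where(adip > 0, np.inf, 0.0))
    ratio = pd.Series(ratio, index=current)
    zero_liver = [g for g in current if liver[g] == 0 and adip[g] > 0]
    if zero_liver:
        audit.notes.append(f"{len(zero_liver)} genes with liver TPM 0 pass ratio as +inf")
    keep = [g for g in current if ratio[g] > ratio_min]
    audit.steps.append(
        FilterStep(
            f"adipose/liver_ratio>{ratio_min:g}",
            len(current),
            len(keep),
            [g for g in current if not ratio[g] > ratio_min],
        )
    )
    audit.final = keep
    return audit


@dataclass
class CorrelationBlocks:
    table: pd.DataFrame  # pairwise r/p/significant, genes ordered by PC1
    gene_order: list
    blocks: list  # list of lists of gene ids


def sbc_correlation_blocks(log_cpm_sbc: pd.DataFrame, alpha: float = 0.05) -> CorrelationBlocks:
    """Pairwise correlation structure of SBC adipose expression.

    Genes are ordered by their loading on the first principal component of
    the SBC expression matrix; blocks are connected components of the graph
    whose edges are Bonferroni-significant positive correlations.
    """
    if log_cpm_sbc.shape[0] < 2:
        raise ValueError("need at least 2 SBC genes")
    genes = list(log_cpm_sbc.index)
    X = log_cpm_sbc.to_numpy(dtype=float)
    Z = (X - X.mean(axis=1, keepdims=True))
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = Z / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    pc1 = U[:, 0]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    order = list(np.argsort(-pc1, kind="mergesort"))
    ordered_genes = [genes[i] for i in order]

    tab = correlate_bonferroni(log_cpm_sbc, log_cpm_sbc, alpha=alpha)
    tab = tab[tab["x"] != tab["y"]]

    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    adj = np.zeros((n, n), dtype=bool)
    for _, row in tab.iterrows():
        if row["significant"] and row["r"] > 0:
            adj[idx[row["x"]], idx[row["y"]]] = True
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    blocks = []
    for c in range(n_comp):
        members = [genes[i] for i in range(n) if labels[i] == c]
        blocks.append(sorted(members))
    blocks.sort(key=lambda b: (-len(b), b[0]))
    return CorrelationBlocks(tab, ordered_genes, blocks)
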