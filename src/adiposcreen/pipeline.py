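"""End-to-end orchestration of the screen on a study bundle: normalization,
per-tissue case-control DE across the three histology traits, the aware-DE
sets, and the SBC filter cascade."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import de as de_mod
from .de import TRAITS, aware_de_sets, build_case_control, fit_moderated, voom_weights
from .prep import CountMatrix, ExpressionMatrix, filter_expressed, log_cpm, tmm_factors
from .sbc import FilterAudit, apply_sbc_filters
from .synth import COVARIATE_COLUMNS, StudyBundle


@dataclass
class ScreenResult:
    de_adipose: dict
    de_liver: dict
    aware: de_mod.AwareSets
    sbc_audit: FilterAudit
    n_genes_tested: dict


def _tissue_de(
    counts: CountMatrix,
    pheno: pd.DataFrame,
    fdr: float,
    min_nonzero_fraction: float,
) -> tuple[dict, int]:
    kept = filter_expressed(counts, min_nonzero_fraction)
    factors = tmm_factors(kept)
    expr = log_cpm(kept, factors)
    covs = pheno[COVARIATE_COLUMNS]
    tables = {}
    for trait in TRAITS:
        design = build_case_control(pheno, trait, covariates=covs).design
        sub = ExpressionMatrix(expr.values[design.index], expr.transform, expr.meta)
        w = voom_weights(sub, design)
        tables[trait] = fit_moderated(sub, design, "group", weights=w)
    return tables, kept.values.shape[0]


def eqtl_expression(
    bundle: StudyBundle,
    tissue: str = "adipose",
    n_pcs: int = 5,
    min_nonzero_fraction: float = 0.9,
) -> pd.DataFrame:
    """Corrected expression for eQTL mapping: log-CPM -> INT -> residualize
    against covariates plus expression PCs -> second INT.

    Expression PCs stand in for latent technical factors; the factor count is
    configurable per tissue.
    """
    from .prep import expression_pcs, int_transform_matrix, residualize

    counts = bundle.adipose_counts if tissue == "adipose" else bundle.liver_counts
    kept = filter_expressed(counts, min_nonzero_fraction)
    expr = log_cpm(kept, tmm_factors(kept))
    expr = int_transform_matrix(expr)
    covs = bundle.pheno[COVARIATE_COLUMNS]
    if n_pcs > 0:
        pcs = expression_pcs(expr, n_pcs)
        covs = pd.concat([covs, pcs], axis=1)
    corrected = residualize(expr, covs, second_int=True)
    return corrected.values


def run_screen(
    bundle: StudyBundle,
    fdr: float = 0.05,
    min_nonzero_fraction: float = 0.9,
    tpm_min: float = 30.0,
    ratio_min: float = 10.0,
) -> ScreenResult:
    """Counts -> filter -> TMM -> log-CPM -> voom/moderated DE (both tissues,
    three traits) -> aware-DE sets -> SBC cascade."""
    de_a, n_a = _tissue_de(bundle.adipose_counts, bundle.pheno, fdr, min_nonzero_fraction)
    de_l, n_l = _tissue_de(bundle.liver_counts, bundle.pheno, fdr, min_nonzero_fraction)
    aware = aware_de_sets(de_a, de_l, fdr=fdr)
    audit = apply_sbc_filters(aware.aware_union, bundle.annotation, tpm_min, ratio_min)
    return ScreenResult(
        de_adipose=de_a,
        de_liver=de_l,
        aware=aware,
        sbc_audit=audit,
        n_genes_tested={"adipose": n_a, "liver": n_l},
    )
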