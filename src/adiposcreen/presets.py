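"""Canonical synthetic-study configurations used by the test suite and the
acceptance script.

These encode the study conditions the screen is exercised under: a
desk-scale dual-tissue cohort (200-300 samples, a few thousand genes) with
planted differential expression, ten planted serum-biomarker candidates,
eight cis-eQTL regions for instrument selection (six valid, two contaminated
by outcome-GWAS hits), and a planted causal exposure->outcome effect of
0.163 on the GWAS effect-size scale.
"""

from __future__ import annotations

import numpy as np

from .synth import GwasArchitecture, PlantedDE, PlantedEqtl, SimConfig

TRAITS = ("steatosis", "fibrosis", "NASH")

#: causal effect of the exposure (serum TG) on the outcome (NAFLD) planted in
#: the MR scenario
THETA_CAUSAL = 0.163


def screen_config(
    seed: int,
    n_samples: int = 200,
    n_genes: int = 2000,
    n_planted_de: int = 600,
    n_sbc: int = 10,
) -> SimConfig:
    """Dual-tissue screen fixture: ~600 planted adipose DE genes (the SBCs
    among them), 60 liver-only DE genes, annotation arranged so only the
    planted SBCs can pass the biomarker filters."""
    rng = np.random.default_rng(seed)
    sbc = [f"G{i:05d}" for i in range(n_sbc)]
    planted = []
    for i in range(n_planted_de):
        g = f"G{i:05d}"
        # balanced up/down regulation keeps the library composition stable
        lfc = 1.8 if i < n_sbc else float(rng.uniform(1.0, 2.0)) * (1 if i % 2 else -1)
        planted.append(PlantedDE(g, "adipose", TRAITS[i % 3], lfc))
    # liver-only DE genes, disjoint from the adipose set and the SBCs
    for i in range(n_planted_de + 50, n_planted_de + 110):
        planted.append(PlantedDE(f"G{i:05d}", "liver", TRAITS[i % 3], float(rng.uniform(1.2, 2.0))))
    return SimConfig(
        n_samples=n_samples,
        n_genes_adipose=n_genes,
        n_genes_liver=n_genes,
        n_shared_genes=int(0.8 * n_genes),
        n_variants=20,
        planted_de=planted,
        planted_sbc=sbc,
        seed=seed,
    )


def mr_forward_config(seed: int, n_samples: int = 300) -> SimConfig:
    """Instrument-selection fixture: eight cis regions, each one tight LD
    block of eight variants with a planted adipose eQTL and an exposure GWAS
    hit at the lead; regions 6 and 7 are contaminated with an outcome GWAS
    hit at the same variant and must be rejected by the cascade."""
    region_genes = [f"G{i:05d}" for i in range(8)]
    planted_eqtl = [
        PlantedEqtl(f"v{8 * k:05d}", region_genes[k], "adipose", 0.9) for k in range(8)
    ]
    # spread in instrument strength keeps the Egger slope well identified
    exp_betas = (0.035, 0.045, 0.055, 0.065, 0.075, 0.085, 0.05, 0.05)
    exp_causal = {f"v{8 * k:05d}": exp_betas[k] for k in range(8)}
    out_causal = {f"v{8 * k:05d}": 0.05 for k in (6, 7)}
    return SimConfig(
        n_samples=n_samples,
        n_genes_adipose=400,
        n_genes_liver=400,
        n_shared_genes=300,
        n_variants=64,
        maf_range=(0.2, 0.5),
        planted_eqtl=planted_eqtl,
        # the exposure GWAS is far better powered than the outcome GWAS (as
        # for serum lipids vs an imputed disease score), so mediated effects
        # stay below genome-wide significance in the outcome
        planted_gwas={
            "exposure": GwasArchitecture(exp_causal, 300_000),
            "outcome": GwasArchitecture(out_causal, 50_000),
        },
        theta_causal=THETA_CAUSAL,
        ld_block_size=8,
        ld_copy_prob=0.94,
        palindromic_fraction=0.0,
        variant_host_genes=region_genes,
        seed=seed,
    )


MR_REGION_GENES = [f"G{i:05d}" for i in range(8)]
MR_VALID_REGIONS = MR_REGION_GENES[:6]


def two_block_expression(
    seed: int, n_samples: int = 100, block_size: int = 40, within_cor: float = 0.9
):
    """Two independent co-expressed gene blocks plus background genes, for
    module-recovery checks.  Returns (expr genes x samples array, labels)."""
    rng = np.random.default_rng(seed)
    genes = []
    labels = []
    for b in range(2):
        driver = rng.standard_normal(n_samples)
        lam = np.sqrt(within_cor)
        for _ in range(block_size):
            genes.append(lam * driver + np.sqrt(1 - lam**2) * rng.standard_normal(n_samples))
            labels.append(b + 1)
    for _ in range(20):
        genes.append(rng.standard_normal(n_samples))
        labels.append(0)
    return np.array(genes), np.array(labels)
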