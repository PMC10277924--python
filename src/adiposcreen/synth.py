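"""Synthetic study generator with planted ground truth.

Emulates a dual-tissue (subcutaneous adipose + liver) bulk RNA-seq cohort
with liver-histology phenotypes, genotype dosages with block LD, and
GWAS summary statistics for an exposure (serum TG) and an outcome (NAFLD)
trait, so that every downstream stage of the screen can be scored against a
known truth record.

Design notes
------------
* Counts are negative binomial around gene baselines drawn log-normal, with a
  single dispersion per configuration.
* NAFLD grades (0-3) come from thresholding Gaussian liabilities that share a
  common component across the three traits and load on serum TG with weight
  ``theta_causal``; grade 0 in all three traits defines controls.
* GWAS summary statistics are generated analytically: marginal true effects
  are LD-propagated from the planted causal variants, and estimates are drawn
  ``N(true, se^2)`` with se from the allele frequency and effective sample
  size.  Outcome true effects are ``theta_causal`` times the exposure effects
  plus any direct (pleiotropic) outcome effects.
* One master seed; each stage draws from its own fixed-offset child stream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .prep import CountMatrix

TRAITS = ("steatosis", "fibrosis", "NASH")
COVARIATE_COLUMNS = [
    "age",
    "sex",
    "rin",
    "pct_uniquely_mapped",
    "pct_intronic",
    "median_3bias",
]

# rng stream offsets per stage
_S_ANNOT, _S_GENO, _S_PHENO, _S_ADIPOSE, _S_LIVER, _S_GWAS = range(6)

_GENE_SPACING = 2_500_000  # > 2 * cis window, so cis regions never overlap
_GENES_PER_CHROM = 100


@dataclass
class PlantedDE:
    gene: str
    tissue: str  # "adipose" | "liver"
    trait: str  # steatosis | fibrosis | NASH
    log2fc: float


@dataclass
class PlantedEqtl:
    variant: str
    gene: str
    tissue: str
    slope: float  # SD-expression per allele (approximate on the count scale)


@dataclass
class GwasArchitecture:
    causal: dict  # variant id -> true effect (per-allele, standardized trait)
    n_eff: int


@dataclass
class SimConfig:
    n_samples: int = 200
    n_genes_adipose: int = 2000
    n_genes_liver: int = 2000
    n_shared_genes: int = 1600
    n_variants: int = 200
    maf_range: tuple = (0.05, 0.5)
    nb_dispersion: float = 0.1
    planted_de: list = field(default_factory=list)
    planted_sbc: list = field(default_factory=list)
    planted_eqtl: list = field(default_factory=list)
    planted_gwas: dict = field(default_factory=dict)  # {"exposure": ..., "outcome": ...}
    theta_causal: float = 0.0
    seed: int = 0
    ld_block_size: int = 1
    ld_copy_prob: float = 0.0
    palindromic_fraction: float = 0.2
    variant_host_genes: list | None = None
    mean_library_size: float = 1.5e6

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_variants < 1:
            raise ValueError("counts must be positive")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("MAFs must lie in (0, 0.5]")
        if self.n_shared_genes > min(self.n_genes_adipose, self.n_genes_liver):
            raise ValueError("n_shared_genes exceeds a tissue gene count")
        genes = set(gene_ids(self))
        variants = set(variant_ids(self))
        for pde in self.planted_de:
            if pde.gene not in genes:
                raise ValueError(f"planted DE gene {pde.gene} not in annotation")
            if pde.trait not in TRAITS or pde.tissue not in ("adipose", "liver"):
                raise ValueError(f"bad planted DE entry {pde}")
        for g in self.planted_sbc:
            if g not in genes:
                raise ValueError(f"planted SBC gene {g} not in annotation")
        liver_de = {p.gene for p in self.planted_de if p.tissue == "liver"}
        bad = liver_de & set(self.planted_sbc)
        if bad:
            raise ValueError(
                f"planted SBC genes cannot also be planted liver DE: {sorted(bad)}"
            )
        for pe in self.planted_eqtl:
            if pe.variant not in variants:
                raise ValueError(f"planted eQTL variant {pe.variant} unknown")
            if pe.gene not in genes:
                raise ValueError(f"planted eQTL gene {pe.gene} unknown")


@dataclass
class Truth:
    planted_de: list
    planted_sbc: list
    planted_eqtl: list
    planted_gwas: dict
    theta_causal: float
    exposure_true_beta: pd.Series | None = None
    outcome_true_beta: pd.Series | None = None


@dataclass
class StudyBundle:
    adipose_counts: CountMatrix
    liver_counts: CountMatrix
    pheno: pd.DataFrame
    annotation: pd.DataFrame
    genotypes: pd.DataFrame  # samples x variants, dosages in [0, 2]
    variant_meta: pd.DataFrame
    exposure_stats: pd.DataFrame
    outcome_stats: pd.DataFrame
    truth: Truth

    def checksum(self) -> str:
        h = hashlib.md5()
        for df in (
            self.adipose_counts.values,
            self.liver_counts.values,
            self.pheno,
            self.annotation,
            self.genotypes,
            self.variant_meta,
            self.exposure_stats,
            self.outcome_stats,
        ):
            h.update(df.round(10).to_csv().encode())
        return h.hexdigest()


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def n_total_genes(config: SimConfig) -> int:
    return config.n_genes_adipose + config.n_genes_liver - config.n_shared_genes


def gene_ids(config: SimConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(n_total_genes(config))]


def adipose_gene_ids(config: SimConfig) -> list[str]:
    return gene_ids(config)[: config.n_genes_adipose]


def liver_gene_ids(config: SimConfig) -> list[str]:
    start = config.n_genes_adipose - config.n_shared_genes
    return gene_ids(config)[start : start + config.n_genes_liver]


def variant_ids(config: SimConfig) -> list[str]:
    return [f"v{i:05d}" for i in range(config.n_variants)]


def _gene_layout(config: SimConfig) -> pd.DataFrame:
    """Gene coordinates: BED-style half-open 0-based, 2.5 Mb spacing so cis
    windows (±1 Mb) of neighbouring genes never overlap."""
    ids = gene_ids(config)
    rows = []
    for i, g in enumerate(ids):
        chrom = f"chr{1 + i // _GENES_PER_CHROM}"
        j = i % _GENES_PER_CHROM
        start = _GENE_SPACING * j + 1_200_000
        rows.append((g, chrom, start, start + 10_000))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]).set_index("gene")


def _variant_hosts(config: SimConfig) -> list[str]:
    """Host gene per variant: planted eQTL variants sit in their gene's cis
    window; the rest cycle over `variant_host_genes` (default: all genes)."""
    vids = variant_ids(config)
    pinned = {}
    for pe in config.planted_eqtl:
        pinned.setdefault(pe.variant, pe.gene)
    cycle = list(config.variant_host_genes) if config.variant_host_genes else gene_ids(config)
    n_v = len(vids)
    # contiguous runs of variants per host gene, so LD blocks stay within one
    # cis region; pinned (planted-eQTL) variants override their slot
    hosts = [cycle[min((j * len(cycle)) // n_v, len(cycle) - 1)] for j in range(n_v)]
    for j, v in enumerate(vids):
        if v in pinned:
            hosts[j] = pinned[v]
    return hosts


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "T"), ("C", "A")]
_PALINDROMES = [("A", "T"), ("C", "G")]


def simulate_genotypes(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dosage matrix (samples x variants, values 0/1/2) plus variant metadata.

    Haplotypes are Bernoulli(MAF); within an LD block each subsequent variant
    copies the previous variant's haplotype with probability
    ``ld_copy_prob`` (copy probability 1 gives within-block r^2 = 1).
    A ``palindromic_fraction`` of variants receive A/T or C/G alleles.
    """
    config.validate()
    rng = _rng(config, _S_GENO)
    layout = _gene_layout(config)
    hosts = _variant_hosts(config)
    vids = variant_ids(config)
    n = config.n_samples
    raw_mafs = rng.uniform(*config.maf_range, size=config.n_variants)

    # MAF is shared within an LD block (tight LD implies matched frequencies),
    # so a copy probability c yields pairwise haplotype correlation c^k
    hap = np.zeros((2 * n, config.n_variants), dtype=np.int8)
    mafs = raw_mafs.copy()
    block_pos = 0
    for j in range(config.n_variants):
        new_block = j == 0 or hosts[j] != hosts[j - 1] or block_pos >= config.ld_block_size
        if new_block:
            block_pos = 1
            hap[:, j] = rng.random(2 * n) < mafs[j]
        else:
            mafs[j] = mafs[j - 1]
            fresh = rng.random(2 * n) < mafs[j]
            copy = rng.random(2 * n) < config.ld_copy_prob
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
            block_pos += 1
    dosages = hap[:n] + hap[n:]

    pal = rng.random(config.n_variants) < config.palindromic_fraction
    ea, oa, pos, chrom = [], [], [], []
    per_gene_counter: dict[str, int] = {}
    for j, v in enumerate(vids):
        g = hosts[j]
        k = per_gene_counter.get(g, 0)
        per_gene_counter[g] = k + 1
        # deterministic ladder of offsets inside the host gene's cis window
        offset = -800_000 + (k * 97_003) % 1_600_000
        pos.append(int(layout.at[g, "start"] + offset))
        chrom.append(layout.at[g, "chrom"])
        if pal[j]:
            a = _PALINDROMES[int(rng.integers(len(_PALINDROMES)))]
        else:
            a = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
        ea.append(a[0])
        oa.append(a[1])

    samples = [f"S{i:04d}" for i in range(n)]
    geno = pd.DataFrame(dosages, index=samples, columns=vids)
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "maf": mafs,
            "host_gene": hosts,
        },
        index=pd.Index(vids, name="variant"),
    )
    return geno, meta


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _simulate_pheno(config: SimConfig, genotypes: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(config, _S_PHENO)
    n = config.n_samples
    samples = genotypes.index

    exp_arch = config.planted_gwas.get("exposure")
    score = np.zeros(n)
    if exp_arch is not None and exp_arch.causal:
        for v, b in exp_arch.causal.items():
            score += b * genotypes[v].to_numpy(dtype=float)
    h2 = 0.3 if score.std() > 0 else 0.0
    tg_liab = (
        np.sqrt(h2) * _standardize(score) + np.sqrt(1 - h2) * rng.standard_normal(n)
        if h2 > 0
        else rng.standard_normal(n)
    )
    tg = 10 ** (2.2 + 0.2 * tg_liab)

    # strong shared component across the three histology liabilities, so a
    # usable fraction of the cohort is grade 0 in all three traits (controls)
    a = float(np.clip(config.theta_causal, -0.6, 0.6))
    b = 0.75
    c = np.sqrt(max(1.0 - a**2 - b**2, 0.05))
    common = rng.standard_normal(n)
    grades = {}
    from scipy.stats import norm

    # grade mix: ~45% grade 0, 25% grade 1, 20% grade 2, 10% grade 3 per trait
    thresholds = norm.ppf([0.45, 0.70, 0.90])
    for t in TRAITS:
        liab = a * tg_liab + b * common + c * rng.standard_normal(n)
        liab = _standardize(liab)
        g = np.digitize(liab, thresholds)
        grades[t] = g

    pheno = pd.DataFrame(
        {
            "steatosis": grades["steatosis"],
            "fibrosis": grades["fibrosis"],
            "NASH": grades["NASH"],
            "serum_tg": tg,
            "age": rng.normal(47, 9, n).round(1),
            "sex": rng.binomial(1, 0.3, n),
            "rin": rng.normal(7.5, 0.8, n).round(2),
            "pct_uniquely_mapped": rng.normal(85, 3, n).round(2),
            "pct_intronic": rng.normal(30, 5, n).round(2),
            "median_3bias": rng.normal(0.45, 0.05, n).round(3),
        },
        index=samples,
    )
    return pheno


def _simulate_annotation(config: SimConfig) -> pd.DataFrame:
    """Gene annotation with coordinates, secretion flag, median TPM per
    tissue, and cell-type marker-set membership.

    Only planted SBC genes receive a filter-passing combination (secreted AND
    adipose TPM > 30 AND adipose/liver ratio > 10); secreted non-SBC genes
    are assigned a failing TPM or ratio, which is what makes exact SBC
    recovery scoreable.
    """
    rng = _rng(config, _S_ANNOT)
    layout = _gene_layout(config)
    ids = list(layout.index)
    n = len(ids)
    sbc = set(config.planted_sbc)

    strand = np.where(rng.random(n) < 0.5, "+", "-")
    secreted = rng.random(n) < 0.15
    adipose_tpm = np.exp(rng.normal(1.5, 1.2, n))
    liver_tpm = np.exp(rng.normal(1.5, 1.2, n))
    marker = np.full(n, "", dtype=object)
    u = rng.random(n)
    marker[u < 0.05] = "adipocyte"
    marker[(u >= 0.05) & (u < 0.10)] = "hepatocyte"
    marker[(u >= 0.10) & (u < 0.13)] = "preadipocyte"

    for i, g in enumerate(ids):
        if g in sbc:
            secreted[i] = True
            adipose_tpm[i] = rng.uniform(40, 200)
            liver_tpm[i] = adipose_tpm[i] / rng.uniform(15, 40)
        elif secreted[i]:
            if rng.random() < 0.5:
                adipose_tpm[i] = rng.uniform(0.1, 29.0)  # fails TPM > 30
            else:
                adipose_tpm[i] = rng.uniform(31, 120)
                liver_tpm[i] = adipose_tpm[i] / rng.uniform(0.2, 9.0)  # fails ratio > 10

    annot = layout.copy()
    annot["strand"] = strand
    annot["secreted"] = secreted
    annot["adipose_tpm"] = adipose_tpm
    annot["liver_tpm"] = liver_tpm
    annot["marker_set"] = marker
    return annot


def _simulate_counts(
    config: SimConfig,
    tissue: str,
    genes: list[str],
    pheno: pd.DataFrame,
    genotypes: pd.DataFrame,
    stream: int,
) -> CountMatrix:
    rng = _rng(config, stream)
    n = config.n_samples
    g = len(genes)
    gene_index = {gid: i for i, gid in enumerate(genes)}

    baseline = rng.normal(5.0, 2.0, g)
    cov = pheno[COVARIATE_COLUMNS].to_numpy(dtype=float)
    covz = (cov - cov.mean(axis=0)) / np.where(cov.std(axis=0) > 0, cov.std(axis=0), 1.0)
    loadings = rng.normal(0.0, 0.1, size=(g, covz.shape[1]))

    eta = baseline[:, None] + loadings @ covz.T  # genes x samples, log2 scale

    for pde in config.planted_de:
        if pde.tissue != tissue or pde.gene not in gene_index:
            continue
        cases = (pheno[pde.trait] > 0).to_numpy()
        eta[gene_index[pde.gene], cases] += pde.log2fc

    s_g = np.log2(np.e) * np.sqrt(config.nb_dispersion)  # approx biological log2 SD
    for pe in config.planted_eqtl:
        if pe.tissue != tissue or pe.gene not in gene_index:
            continue
        dose = genotypes[pe.variant].to_numpy(dtype=float)
        eta[gene_index[pe.gene]] += pe.slope * s_g * dose

    w = 2.0**eta
    lib = rng.lognormal(np.log(config.mean_library_size), 0.1, n)
    mu = w / w.sum(axis=0, keepdims=True) * lib[None, :]
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12)))
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=pheno.index))


def _ld_propagated_betas(
    causal: dict, genotypes: pd.DataFrame, hosts: pd.Series
) -> pd.Series:
    """Marginal true effects: beta_j = sum_k r_jk (sd_k / sd_j) beta_k over
    causal variants sharing the host-gene region."""
    beta = pd.Series(0.0, index=genotypes.columns)
    sd = genotypes.std(axis=0)
    for v, b in causal.items():
        host = hosts[v]
        region = hosts.index[hosts == host]
        gv = genotypes[v].to_numpy(dtype=float)
        for u in region:
            su = sd[u]
            if su == 0:
                continue
            r = np.corrcoef(genotypes[u].to_numpy(dtype=float), gv)[0, 1]
            if np.isnan(r):
                continue
            beta[u] += r * (sd[v] / su) * b
    return beta


def simulate_gwas_summary(
    config: SimConfig,
    genotypes: pd.DataFrame | None = None,
    variant_meta: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Analytic exposure and outcome GWAS summary statistics.

    Returns (exposure_stats, outcome_stats, exposure_true, outcome_true).
    Estimates are N(true, se^2) with se = 1/sqrt(2*maf*(1-maf)*n_eff); the
    outcome's true effects are theta_causal times the exposure's plus any
    direct outcome effects; p-values are two-sided normal.
    """
    from scipy.stats import norm

    if genotypes is None or variant_meta is None:
        genotypes, variant_meta = simulate_genotypes(config)
    rng = _rng(config, _S_GWAS)
    hosts = variant_meta["host_gene"]

    exp_arch = config.planted_gwas.get("exposure", GwasArchitecture({}, 300_000))
    out_arch = config.planted_gwas.get("outcome", GwasArchitecture({}, 300_000))
    exp_true = _ld_propagated_betas(exp_arch.causal, genotypes, hosts)
    out_direct = _ld_propagated_betas(out_arch.causal, genotypes, hosts)
    out_true = config.theta_causal * exp_true + out_direct

    maf_hat = np.clip(genotypes.mean(axis=0).to_numpy() / 2.0, 1e-4, 1 - 1e-4)
    maf_hat = np.minimum(maf_hat, 1 - maf_hat)

    # estimation noise is correlated across variants through LD (cov r*se_u*se_v),
    # block-diagonal by host-gene region
    vids = list(genotypes.columns)
    pos_of = {v: i for i, v in enumerate(vids)}
    chol_blocks = []
    for host in hosts.unique():
        members = [pos_of[v] for v in hosts.index[hosts == host]]
        G = genotypes.iloc[:, members].to_numpy(dtype=float)
        sd = G.std(axis=0)
        ok = sd > 0
        R = np.eye(len(members))
        if ok.sum() > 1:
            sub = np.corrcoef(G[:, ok].T)
            R[np.ix_(ok, ok)] = sub
        L = np.linalg.cholesky(R + 1e-6 * np.eye(len(members)))
        chol_blocks.append((members, L))

    def correlated_noise() -> np.ndarray:
        eps = np.zeros(len(vids))
        for members, L in chol_blocks:
            eps[members] = L @ rng.standard_normal(len(members))
        return eps

    def build(true: pd.Series, n_eff: int) -> pd.DataFrame:
        se = 1.0 / np.sqrt(2 * maf_hat * (1 - maf_hat) * n_eff)
        beta_hat = true.to_numpy() + se * correlated_noise()
        z = beta_hat / se
        p = 2 * norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "chrom": variant_meta["chrom"],
                "pos": variant_meta["pos"],
                "effect_allele": variant_meta["effect_allele"],
                "other_allele": variant_meta["other_allele"],
                "beta": beta_hat,
                "se": se,
                "p": p,
            },
            index=variant_meta.index,
        )

    return build(exp_true, exp_arch.n_eff), build(out_true, out_arch.n_eff), exp_true, out_true


def simulate_study(config: SimConfig) -> StudyBundle:
    """Generate a complete dual-tissue study with planted structure."""
    config.validate()

    # auto-plant an adipose DE effect for SBC genes that lack one, so every
    # planted SBC is adipose-aware DE by construction
    extra = []
    adipose_de = {p.gene for p in config.planted_de if p.tissue == "adipose"}
    for i, g in enumerate(config.planted_sbc):
        if g not in adipose_de:
            extra.append(PlantedDE(g, "adipose", TRAITS[i % 3], 1.5))
    cfg = (
        replace(config, planted_de=list(config.planted_de) + extra) if extra else config
    )

    genotypes, variant_meta = simulate_genotypes(cfg)
    pheno = _simulate_pheno(cfg, genotypes)
    annotation = _simulate_annotation(cfg)
    adipose = _simulate_counts(
        cfg, "adipose", adipose_gene_ids(cfg), pheno, genotypes, _S_ADIPOSE
    )
    liver = _simulate_counts(cfg, "liver", liver_gene_ids(cfg), pheno, genotypes, _S_LIVER)
    exp_stats, out_stats, exp_true, out_true = simulate_gwas_summary(
        cfg, genotypes, variant_meta
    )
    truth = Truth(
        planted_de=list(cfg.planted_de),
        planted_sbc=list(cfg.planted_sbc),
        planted_eqtl=list(cfg.planted_eqtl),
        planted_gwas=dict(cfg.planted_gwas),
        theta_causal=cfg.theta_causal,
        exposure_true_beta=exp_true,
        outcome_true_beta=out_true,
    )
    return StudyBundle(
        adipose_counts=adipose,
        liver_counts=liver,
        pheno=pheno,
        annotation=annotation,
        genotypes=genotypes,
        variant_meta=variant_meta,
        exposure_stats=exp_stats,
        outcome_stats=out_stats,
        truth=truth,
    )


def write_bundle(bundle: StudyBundle, outdir) -> None:
    """Write every table of a bundle as TSV (counts gzip-compressed)."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.adipose_counts.values.to_csv(out / "adipose_counts.tsv.gz", sep="\t")
    bundle.liver_counts.values.to_csv(out / "liver_counts.tsv.gz", sep="\t")
    bundle.pheno.to_csv(out / "pheno.tsv", sep="\t")
    bundle.annotation.to_csv(out / "annotation.tsv", sep="\t")
    bundle.genotypes.to_csv(out / "genotypes.tsv", sep="\t")
    bundle.variant_meta.to_csv(out / "variant_meta.tsv", sep="\t")
    bundle.exposure_stats.to_csv(out / "exposure_stats.tsv", sep="\t")
    bundle.outcome_stats.to_csv(out / "outcome_stats.tsv", sep="\t")
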