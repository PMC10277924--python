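# adiposcreen

A tested, reusable implementation of a dual-tissue transcriptomic screen for
**adipose-origin serum biomarkers of non-alcoholic fatty liver disease
(NAFLD)**, exercised end to end on synthetic data with planted effects.

## The scientific problem

NAFLD is diagnosed from liver histology (steatosis, fibrosis, NASH grades),
but an invasive biopsy is a poor screening tool. Dysfunctional subcutaneous
adipose tissue is a plausible upstream driver of liver fat: genes that are
differentially expressed (DE) in adipose tissue — but *not* in the liver —
of NAFLD patients, and whose protein products are secreted into serum, are
candidate blood-based biomarkers with a clean tissue of origin. This package
implements the whole analytic chain needed to find and vet such candidates
from paired adipose/liver RNA-seq, genotypes, and GWAS summary statistics:

1. **Normalization** — TMM scaling factors, log-CPM, rank-based inverse
   normal transform (INT), covariate residualization, expression PCs
   (`prep`).
2. **Differential expression** — voom-style precision weights and
   empirical-Bayes moderated t-statistics per tissue and histology trait,
   with BH FDR; "aware-DE" genes are DE in one tissue but not the other
   (`de`).
3. **Co-expression networks** — soft-thresholded adjacency
   a_ij = |cor(x_i, x_j)|^β, topological overlap (TOM), average-linkage
   module detection, eigengenes, eigengene merging, Bonferroni-corrected
   module–trait correlation (`netcor`).
4. **Serum-biomarker-candidate (SBC) cascade** — aware-DE genes that are
   secreted, with adipose median TPM > 30 and adipose/liver TPM ratio > 10,
   with a full audit trail (`sbc`).
5. **Best-subset selection** — exhaustive search over SBC subsets for the
   model minimizing BIC = n·ln(RSS/n) + (k+1)·ln n, with a permutation null
   drawing random same-size gene sets from all expressed genes (`subset`).
6. **Genetics** — cis-eQTL mapping (±1 Mb), LD r², Wakefield approximate
   Bayes factors, and enumeration colocalization posteriors PP0–PP4
   (`genetics`).
7. **Mendelian randomization** — an instrument cascade (significant cis-eQTL
   + exposure GWAS hit that is not an outcome hit → colocalization PP4 ≥ 0.8
   → LD filters → strand-ambiguity removal → harmonization) followed by the
   IVW, MR-Egger, and MR-PRESSO estimators, forward and reverse (`mr`).
8. **Model comparison** — nested logistic models (serum TG vs TG + gene
   expression) compared by Nagelkerke pseudo-r² and ROC AUC (`evalreg`).

The `synth` module generates every input the pipeline consumes — negative-
binomial counts with planted DE effects, histology grades from Gaussian
liabilities, genotype dosages with block LD, and analytic GWAS summary
statistics with a planted causal exposure→outcome effect — so that every
stage can be scored against a known truth. See `docs/methods.md` for the
models and their assumptions.

## Worked example

```python
from adiposcreen.presets import screen_config
from adiposcreen.synth import simulate_study
from adiposcreen.pipeline import run_screen

bundle = simulate_study(screen_config(seed=1))   # 2000 genes x 200 samples, 2 tissues
result = run_screen(bundle)                      # DE -> aware sets -> SBC cascade
print(len(result.aware.aware_union))             # 628 adipose-aware DE genes
print(result.sbc_audit.to_frame())
print(sorted(result.sbc_audit.final) == sorted(bundle.truth.planted_sbc))  # True
```

which prints the audit trail of the biomarker cascade:

```
                   filter  n_in  n_out
0          aware_de_input   628    628
1                secreted   628    121
2          adipose_tpm>30   121     65
3  adipose/liver_ratio>10    65     10
```

628 adipose-aware DE genes are reduced to exactly the 10 planted serum
biomarker candidates: every survivor is DE in adipose (not liver), encodes a
secreted protein, is well expressed in adipose tissue, and is strongly
adipose-enriched.

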