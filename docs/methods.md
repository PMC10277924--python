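# Methods

This note documents the models, parameter choices, and numerical conventions
behind `adiposcreen`, and what the synthetic-data generator does and does not
emulate.

## Preprocessing (`prep`)

**Expression filter.** Genes are kept when they have a nonzero count in at
least ⌈0.9·n⌉ samples. Genes expressed in fewer samples tend to show bimodal
zero-inflated distributions that a rank transform cannot normalize. The
filter is idempotent.

**TMM factors.** The reference sample is the one whose 75th-percentile count
fraction is closest to the cohort mean of those quantiles. For each sample,
M = log2 ratio and A = log2 abundance are computed over genes nonzero in both
the sample and the reference; M values are trimmed 30% from each tail and A
values 5% from each tail (the edgeR convention), and the factor is
2^(precision-weighted mean of the surviving M values), using delta-method
variances (N−c)/(Nc) as inverse weights. Factors are rescaled to geometric
mean 1. A sample with no overlapping nonzero genes gets factor 1 with a
warning.

**log-CPM.** log2((count + 0.5) / (libsize·factor + 1) · 1e6). The prior
count of 0.5 keeps zeros finite; doubling depth changes values by < 0.02 for
counts ≥ 50.

**Inverse normal transform (INT).** Φ⁻¹((rank − c)/(n − 2c + 1)) with the
Blom constant c = 3/8 and average ranks for ties. A constant vector maps to
zeros with a warning. INT is invariant to monotone transforms of its input,
which is why per-gene length normalization (FPKM vs CPM) is irrelevant for
rank-based eQTL input.

**Residualization.** Per-gene OLS residuals against [1 | covariates]
(age, sex, RIN, % uniquely mapped, % intronic, median 3′ bias). The operation
is a projection (applying twice equals once to 1e-10); rank-deficient designs
raise an error naming the collinear columns. Network and eQTL inputs use
INT → residualize → INT, so the final per-gene distribution is again normal.

**Expression PCs.** Latent technical structure is captured by the top
principal components of the gene-standardized expression matrix instead of a
dedicated latent-factor tool; the factor count is configurable (25 adipose /
10 liver are natural choices at cohort scale; the desk-scale fixtures use 5).
The component sign is fixed by making the largest-magnitude loading positive.

## Differential expression (`de`)

Cases for a trait are samples with a nonzero grade for that trait; controls
have grade zero in *all three* traits; everything else is excluded from that
contrast. Sex is coded 0/1; grades are ordinal but the contrast is the
case/control dichotomy.

Precision weights follow the voom recipe: per-gene linear fits of log-CPM,
a lowess curve (span 0.5) of √(residual SD) against mean log-count, and
per-observation predicted SD⁻⁴ as weights, with the lowess clamped at its
endpoints. With fewer than 10 genes the trend is unidentifiable and weights
fall back to 1.

Moderated statistics use an inverse-chi-square prior on the per-gene
variances estimated by **moment matching on log variances**: with
e_g = ln s²_g − ψ(d/2) + ln(d/2), the excess of Var(e) over ψ′(d/2)
identifies d₀ through the trigamma inverse and the mean of e identifies s₀².
This closed form replaces the full F-distribution fit; in the
infinite-prior limit it reduces to a pooled-variance test, and with a single
gene it degrades gracefully to the unmoderated test. The moderated t uses
d₀ + d degrees of freedom. BH adjustment runs over the genes passing the
expression filter in that tissue/trait.

**Aware-DE sets.** A gene is adipose-aware DE when it is DE (FDR < 0.05) in
adipose for some trait and not DE in liver for *any* of the three traits;
a strict per-trait mode (removing only same-trait liver DE) is available as
a flag. The union rule is the default because the biomarker question is
"is the signal adipose-specific at all", not "trait by trait".

**Restricted DE.** Small perturbation experiments (siRNA knockdowns,
treatment assays) reuse the same machinery with an intercept+group design,
no covariates, genes prefiltered to a subset and by a group-total rule
(summed counts > 10 in at least one group; requiring both groups is a flag),
and BH across the subset only.

## Co-expression networks (`netcor`)

Unsigned adjacency |cor|^β with Pearson correlation. The scale-free fit
index is the signed r² of log10 p(k) against log10 mean k over ten
equal-width connectivity bins. TOM_ij = (Σ_u a_iu a_uj + a_ij) /
(min(k_i,k_j) + 1 − a_ij), unit diagonal; the matrix-product implementation
is tested against a naive triple loop. Modules come from average-linkage
clustering of 1 − TOM with a **static height cut** (default 99% of the merge
range) and a minimum size of 30 (desk-scale fixtures use 5); smaller
branches are relabelled grey. A static cut replaces the dynamic hybrid tree
cut: it preserves the testable contract (planted blocks are recovered
exactly) without importing a second algorithm family; absolute module counts
are therefore not comparable to dynamic-cut counts and are not treated as
targets. Eigengenes are first right singular vectors of the gene-standardized
module submatrix, sign-oriented toward the module mean; merging clusters
eigengenes at 1 − cor below the merge height (0.10 adipose / 0.25 liver
convention) and iterates to a fixed point. Correlation p-values use
t = R√((n−2)/(1−R²)); family-wise control is Bonferroni at 0.05 over the
pairs actually tested, with zero-variance profiles flagged and excluded.

## Biomarker cascade (`sbc`)

Filters run in order: aware-DE input → secreted flag → adipose median
TPM > 30 (strict) → adipose/liver median TPM ratio > 10 (strict). A liver
TPM of exactly 0 with positive adipose TPM passes the ratio filter (+∞) and
is logged. Genes missing annotation fail conservatively in a separate audit
bucket. Because the filters are independent predicates, the final set is
order-insensitive even though the audit counts are not. Correlation blocks
among the selected genes are connected components of the Bonferroni-
significant positive-correlation graph, with genes ordered by their PC1
loading.

## Best subset (`subset`)

Response and candidate expression are both residualized against covariates
before an exhaustive search (pool capped at 20 candidates). Per size, the
minimum-RSS subset wins; across sizes, BIC = n·ln(RSS/n) + (k+1)·ln n with
the intercept counted in the parameter load; ties break lexicographically on
gene ids. The permutation p is the proportion of B random same-size gene
sets from the expressed-gene universe — fitted on the identical residualized
design — whose r² *strictly* exceeds the observed one; an add-one smoothed
p is reported alongside. The default B is 10,000 for interactive use;
B = 100,000 reproduces the original setting. BIC's spurious-inclusion
probability is ≈ 2·P(χ²₁ > ln n), so near-certain support recovery is a
large-n property.

## Genetics (`genetics`)

cis-eQTLs: a variant is tested for a gene when it lies within 1 Mb of either
gene boundary (a gene-end-only anchor is a flag); per pair, OLS slope of
corrected expression on dosage with a t-test, BH FDR over all tested pairs
in the tissue; monomorphic variants are skipped. LD is squared Pearson
correlation of dosages, pairwise-complete under missingness.

Colocalization uses Wakefield log-ABFs, log ABF = ½[ln(1−r) + r·z²] with
r = W/(W+se²), prior SD 0.15 for quantitative traits (0.2 for binary), and
the standard enumeration priors p1 = p2 = 1e-4, p12 = 1e-5. All posterior
arithmetic is in log space (logsumexp / logdiffexp, with the H3 term clamped
when S1+S2 underflows against S12); the implementation matches a
linear-space oracle to 1e-8. Significant colocalization means PP4 ≥ 0.8.
Multiple signals per region are handled by a mask-and-rerun pass: variants
with r² > threshold to the lead are removed and colocalization is rerun on
the remainder, replacing a full conditional analysis.

## Mendelian randomization (`mr`)

The instrument cascade runs in this order, with audit counts at each step:
candidate cis regions need a significant eQTL (FDR < 0.05) *and* an exposure
GWAS hit (p < 5e-8) that is not itself an outcome hit (outcome p ≥ 5e-8);
surviving regions must colocalize (PP4 ≥ 0.8); the colocalized significant
eQTL variants become candidates; candidates in LD (r² > 0.2) with any
outcome hit in the region are dropped (region-local by default; genome-wide
is a flag); LD pruning at r² > 0.2 keeps the candidate with the smallest
rank(eQTL p) + rank(exposure GWAS p), ties by eQTL p then variant id;
palindromic (A/T, C/G) variants are removed; outcome records are harmonized
to the exposure allele convention (swap ⇒ sign flip; incompatible ⇒ drop).
An empty result is an explicit failure state, which is the expected outcome
of the reverse direction when no liver region qualifies.

Estimators: IVW β̂ = Σβ_X β_Y/se_Y² ÷ Σβ_X²/se_Y² (fixed-effect by default;
multiplicative random-effects inflation max(1, √(Q/(J−1))) optional), which
reduces to the Wald ratio for a single instrument; Egger WLS of β_Y on β_X
with intercept after orienting pairs jointly so β_X ≥ 0, SEs inflated by
max(1, √(RSS/(J−2))) with a t reference on J−2 df (requires J ≥ 3); PRESSO
computes RSS over leave-one-out IVW predictions and calibrates it by a
parametric bootstrap (default 1,000 draws) that redraws both β_X and β_Y,
with per-instrument outlier tests Bonferroni-corrected over J (requires
J ≥ 4). Egger needs spread in instrument strength to separate slope from
intercept; with few similar-strength instruments its estimate is noisy,
which the fixtures deliberately exhibit.

## Model comparison (`evalreg`)

Serum TG enters as log10(TG); gene expression is INT-transformed. Base
(TG + covariates) and augmented (TG + gene + covariates) logistic models are
fitted by IRLS (iteration cap 100, |Δdeviance| < 1e-8; separable data warn
rather than fail) and compared by Nagelkerke pseudo-r² —
[1 − exp((2/n)(ℓ₀−ℓ₁))]/[1 − exp((2/n)ℓ₀)], computed from log-likelihoods —
and by rank-based AUC (Mann-Whitney identity, ties counted ½). The analogous
linear models report r² and adjusted r².

## The synthetic-data generator (`synth`)

What it emulates, and how:

- **Counts**: negative binomial around log-normal gene baselines
  (log2 baseline ~ N(5, 2²)), one dispersion per configuration (default
  0.1), log-normal library sizes (mean 1.5e6, CV 10%). Covariates get
  N(0, 0.1) log2 loadings on every gene; planted DE adds its log2FC to case
  samples of its trait/tissue; planted eQTLs add slope·s_g per allele with
  s_g = log2(e)·√dispersion, an approximation of the gene's biological log2
  SD (so SD-unit slopes survive INT only approximately on the count path —
  exact slope-recovery checks use direct Gaussian expression).
- **Phenotypes**: the three histology liabilities share a common factor
  (loading 0.75) plus a serum-TG loading clipped at the planted causal
  effect; grades 0–3 are liability quantiles (45/25/20/10%), so "grade 0 in
  all three traits" yields a usable control group. TG is log-normal with a
  30% heritable share from the planted exposure variants.
- **Genotypes**: haplotypes are Bernoulli(MAF), MAF uniform in the
  configured range but *shared within an LD block* (tight LD implies matched
  frequencies), and within a block each variant copies its neighbour's
  haplotype with the configured probability, so copy probability c gives
  pairwise correlation ≈ c^k at lag k. Variants are laid out in contiguous
  runs inside host-gene cis windows; genes are spaced 2.5 Mb apart so ±1 Mb
  cis windows never overlap.
- **GWAS summary statistics** are analytic: true marginal effects are
  LD-propagated from planted causal variants (β_j = Σ r_jk (sd_k/sd_j) β_k
  within the host region), the outcome's true effects are θ_causal times the
  exposure's plus direct (pleiotropic) effects, and estimates are drawn with
  **LD-correlated noise** (cov = r·se_u·se_v, block-diagonal by region).
  Correlated noise matters: with independent noise the top variant flips
  between traits under strong power and colocalization spuriously favours
  two-distinct-signals. Standard errors come from 1/√(2·maf·(1−maf)·n_eff).
  In the instrument fixture the exposure GWAS (n_eff 300,000) is far better
  powered than the outcome GWAS (n_eff 50,000), as for serum lipids versus
  an imputed disease score; otherwise mediated effects would reach
  genome-wide significance in the outcome and the contamination filter would
  (correctly, per its rule) reject genuinely causal regions.
- **Annotation**: only planted SBC genes receive a filter-passing
  combination (secreted, adipose TPM uniform 40–200, adipose/liver ratio
  15–40); secreted non-SBC genes are assigned a failing TPM or ratio. This
  is what makes the end-to-end exact-recovery check scoreable: the screen
  must find all ten planted genes and nothing else.

One master seed drives fixed-offset child streams (annotation, genotypes,
phenotypes, per-tissue counts, GWAS), so identical configurations are
bit-identical and stages can be regenerated independently.

What it does **not** emulate: realistic human LD maps or allele-frequency
spectra, sequence-level effects, single-nucleus data, batch structure,
ancestry stratification, or winner's-curse effects in the summary
statistics. Passing tests therefore demonstrate the correctness and
calibration of the machinery under the stated generative model, not
performance on real cohorts.

## Problem sizes

The default suites run at desk scale: 2,000 genes × 200 samples for the
screen (which plants 600 DE genes and recovers the 10 biomarkers exactly),
8 cis regions × 8 variants × 300 samples for the instrument cascade
(recovering 6 instruments and θ ≈ 0.163), 20 replicates for each p-value
calibration family, and 500 replicates for estimator recovery/coverage.
Larger configurations are a matter of changing `SimConfig` fields.

## Known limitations

- The moderated-variance prior uses the closed-form moment-matching
  estimator; for very small gene counts it degrades to an unmoderated test.
- The permutation p has resolution 1/B and is reported with and without
  add-one smoothing.
- Egger estimates on ≤ 6 instruments with narrow strength spread are noisy
  by construction; IVW and PRESSO are the primary estimators.
- The mask-based second-signal pass is a pragmatic substitute for
  conditional colocalization and shares its blind spot when two causal
  variants are in moderate LD.
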