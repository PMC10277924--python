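"""Expression preprocessing: expression filters, TMM scaling factors, log-CPM,
rank-based inverse normal transformation, covariate residualization, and
expression principal components.

All matrix-valued functions operate on :class:`CountMatrix` /
:class:`ExpressionMatrix` containers whose ``values`` are genes x samples
DataFrames.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CountMatrix:
    """Integer gene-by-sample counts for one tissue."""

    values: pd.DataFrame  # genes x samples, non-negative ints

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)


@dataclass
class ExpressionMatrix:
    """Real-valued gene-by-sample expression with a transform tag."""

    values: pd.DataFrame
    transform: str = "cpm"  # one of {cpm, log_cpm_tmm, int, residualized}
    meta: dict = field(default_factory=dict)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def filter_expressed(counts: CountMatrix, min_nonzero_fraction: float = 0.9) -> CountMatrix:
    """Keep genes with a nonzero count in at least ceil(fraction * n_samples) samples.

    Genes expressed in fewer samples typically show bimodal distributions that
    an inverse normal transform cannot fix, hence the hard 90% default.
    """
    if not (0 < min_nonzero_fraction <= 1):
        raise ValueError("min_nonzero_fraction must be in (0, 1]")
    n = counts.values.shape[1]
    need = math.ceil(min_nonzero_fraction * n)
    keep = (counts.values > 0).sum(axis=1) >= need
    if not keep.any():
        warnings.warn("filter_expressed removed every gene", stacklevel=2)
    return CountMatrix(counts.values.loc[keep])


def tmm_factors(counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those quantiles.  M (log ratio) values are trimmed
    30% from each tail and A (log abundance) values 5% from each tail; the
    factor is 2**(precision-weighted mean of the surviving M values).
    """
    X = counts.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = X.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    frac = X / lib
    q75 = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    factors = np.ones(X.shape[1])
    xr, nr = X[:, ref], lib[ref]
    for s in range(X.shape[1]):
        if s == ref:
            continue
        xs, ns = X[:, s], lib[s]
        both = (xs > 0) & (xr > 0)
        if not both.any():
            warnings.warn(f"sample {counts.sample_ids[s]} shares no nonzero genes with reference")
            continue
        cs, cr = xs[both], xr[both]
        m = np.log2((cs / ns) / (cr / nr))
        a = 0.5 * np.log2((cs / ns) * (cr / nr))
        # asymptotic (delta-method) variance of M, used as precision weights
        w = (ns - cs) / (ns * cs) + (nr - cr) / (nr * cr)

        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        factors[s] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))

    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def log_cpm(
    counts: CountMatrix, factors: pd.Series | None = None, prior_count: float = 0.5
) -> ExpressionMatrix:
    """log2 counts-per-million on TMM-effective library sizes.

    value = log2((count + prior) / (libsize * factor + 2 * prior) * 1e6)
    """
    lib = counts.library_sizes.to_numpy(dtype=float)
    f = np.ones_like(lib) if factors is None else factors.reindex(counts.sample_ids).to_numpy()
    eff = lib * f
    vals = np.log2(
        (counts.values.to_numpy(dtype=float) + prior_count) / (eff + 2 * prior_count) * 1e6
    )
    tag = "cpm" if factors is None else "log_cpm_tmm"
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
        transform=tag,
        meta={
            "prior_count": prior_count,
            "effective_lib": pd.Series(eff, index=counts.sample_ids),
        },
    )


def inverse_normal_transform(x: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offset c = 3/8.

    value_i = Phi^-1((rank_i - c) / (n - 2c + 1)); ties receive average ranks.
    A constant vector maps to all zeros with a warning.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0:
        warnings.warn("constant vector passed to inverse_normal_transform", stacklevel=2)
        return np.zeros(n)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - c) / (n - 2 * c + 1))


def int_transform_matrix(expr: ExpressionMatrix, c: float = 3.0 / 8.0) -> ExpressionMatrix:
    """Apply the inverse normal transform to every gene row."""
    vals = np.apply_along_axis(inverse_normal_transform, 1, expr.values.to_numpy(), c=c)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=expr.gene_ids, columns=expr.sample_ids), transform="int"
    )


def _check_full_rank(design: np.ndarray, names: list[str] | None) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify a dependent column via QR pivoting on the correlation structure
        _, r = np.linalg.qr(design)
        bad = [i for i in range(design.shape[1]) if abs(r[i, i]) < 1e-10 * abs(r[0, 0])]
        labels = [names[i] if names else str(i) for i in bad]
        raise ValueError(f"design is rank deficient; collinear columns: {labels}")


def residualize(
    expr: ExpressionMatrix,
    covariates: pd.DataFrame,
    second_int: bool = False,
) -> ExpressionMatrix:
    """Replace each gene by OLS residuals against [1 | covariates].

    With ``second_int`` the residuals are re-inverse-normal-transformed per
    gene, matching the INT -> residualize -> INT recipe used for network and
    eQTL input.
    """
    C = covariates.reindex(expr.sample_ids).to_numpy(dtype=float)
    D = np.column_stack([np.ones(C.shape[0]), C])
    _check_full_rank(D, ["intercept"] + list(covariates.columns))
    Y = expr.values.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = (Y - D @ beta).T
    out = ExpressionMatrix(
        pd.DataFrame(resid, index=expr.gene_ids, columns=expr.sample_ids),
        transform="residualized",
    )
    if second_int:
        out = int_transform_matrix(out)
        out.transform = "residualized"
    return out


def expression_pcs(expr: ExpressionMatrix, k: int) -> pd.DataFrame:
    """Top-k principal-component sample scores of the gene-standardized matrix.

    Sign convention: the loading entry with the largest magnitude is positive,
    so scores are deterministic across runs.
    """
    X = expr.values.to_numpy(dtype=float)
    if k >= min(X.shape):
        raise ValueError("k must be smaller than min(genes, samples)")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = (Vt[:k].T * S[:k])  # samples x k
    for j in range(k):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(
        scores, index=expr.sample_ids, columns=[f"PC{j + 1}" for j in range(k)]
    )
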