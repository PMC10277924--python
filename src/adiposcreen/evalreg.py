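"""Added explanatory value of a gene's adipose expression over serum
triglycerides for NAFLD status: nested logistic models compared by Nagelkerke
pseudo-r-squared and ROC AUC, plus the analogous linear models.

Serum TG is log10-transformed and the gene expression inverse-normal
transformed before fitting, and both models carry the same covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .prep import inverse_normal_transform


def logistic_fit(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, float]:
    """Logistic regression by IRLS; returns (coefficients, log-likelihood).

    The design must include its own intercept column.  Separable data hit the
    iteration cap and warn rather than error.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    D = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("design is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        model = sm.GLM(y, D, family=sm.families.Binomial())
        try:
            fit = model.fit(maxiter=100, tol=1e-8)
        except Exception:
            warnings.warn("logistic fit did not converge (possible separation)")
            fit = model.fit(maxiter=25, tol=1e-4)
    if not getattr(fit, "converged", True):
        warnings.warn("logistic fit reached the iteration cap (possible separation)")
    return np.asarray(fit.params), float(fit.llf)


def nagelkerke_r2(llf0: float, llf1: float, n: int) -> float:
    """Nagelkerke pseudo-r-squared from null and full model log-likelihoods.

    R2 = [1 - (L0/L1)^(2/n)] / [1 - L0^(2/n)], evaluated in log space.
    """
    if llf1 < llf0 - 1e-8:
        raise ValueError("full model must nest the null (llf1 >= llf0)")
    num = 1.0 - np.exp((2.0 / n) * (llf0 - llf1))
    den = 1.0 - np.exp((2.0 / n) * llf0)
    if den <= 0:
        return 0.0
    return float(num / den)


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney U) identity,
    ties counted one half."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = np.sum(ranks[y == 1]) - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


@dataclass
class ModelComparison:
    trait: str
    nagelkerke_base: float
    nagelkerke_aug: float
    auc_base: float
    auc_aug: float
    r2_base: float
    r2_aug: float
    adj_r2_base: float
    adj_r2_aug: float
    llf_base: float
    llf_aug: float


def _linear_r2(y: np.ndarray, D: np.ndarray) -> tuple[float, float]:
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / tss
    n, p = D.shape
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    return float(r2), float(adj)


def compare_models(
    status: np.ndarray,
    tg: np.ndarray,
    gene_expr: np.ndarray,
    covariates: np.ndarray | None = None,
    trait: str = "NASH",
) -> ModelComparison:
    """Compare TG-only vs TG + gene-expression models for a binary NAFLD status.

    TG enters as log10(TG); the gene expression (CPM scale) enters inverse-
    normal transformed.  Reports Nagelkerke pseudo-r2 and AUC for the logistic
    pair and r2 / adjusted r2 for the linear pair.
    """
    y = np.asarray(status, dtype=float)
    tg_t = np.log10(np.asarray(tg, dtype=float))
    g_t = inverse_normal_transform(np.asarray(gene_expr, dtype=float))
    n = y.size
    cov = (
        np.empty((n, 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    if cov.shape[0] != n:
        cov = cov.T
    ones = np.ones((n, 1))
    D_null = np.hstack([ones, cov])
    D_base = np.hstack([ones, tg_t[:, None], cov])
    D_aug = np.hstack([ones, tg_t[:, None], g_t[:, None], cov])

    _, llf_null = logistic_fit(y, D_null)
    cb, llf_base = logistic_fit(y, D_base)
    ca, llf_aug = logistic_fit(y, D_aug)

    nag_base = nagelkerke_r2(llf_null, llf_base, n)
    nag_aug = nagelkerke_r2(llf_null, llf_aug, n)
    auc_base = roc_auc(D_base @ cb, y)
    auc_aug = roc_auc(D_aug @ ca, y)
    r2_base, adj_base = _linear_r2(y, D_base)
    r2_aug, adj_aug = _linear_r2(y, D_aug)
    return ModelComparison(
        trait,
        nag_base,
        nag_aug,
        auc_base,
        auc_aug,
        r2_base,
        r2_aug,
        adj_base,
        adj_aug,
        llf_base,
        llf_aug,
    )
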