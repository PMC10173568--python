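"""Fit indices and chi-square difference summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def fit_indices_from(
    stat: float, df: int, stat0: float, df0: int, n_total: int, n_groups: int
) -> tuple[float, float]:
    """CFI and RMSEA from model and baseline test statistics.

    CFI   = 1 - max(T - df, 0) / max(T0 - df0, T - df, 0)
    RMSEA = sqrt(max(T - df, 0) / (df * N)) * sqrt(G)

    A saturated model (df = 0) reports CFI 1, RMSEA 0.  The sqrt(G)
    multiplier applies only in multi-group (independent samples) fits.
    """
    if df0 < df:
        raise ValueError("baseline df smaller than model df")
    excess = max(stat - df, 0.0)
    denom = max(stat0 - df0, stat - df, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - excess / denom
    if df == 0:
        rmsea = 0.0
    else:
        rmsea = float(np.sqrt(excess / (df * n_total)) * np.sqrt(n_groups))
    return float(np.clip(cfi, 0.0, 1.0)), rmsea


def srmr(S: np.ndarray, sigma: np.ndarray) -> float:
    """Standardized root mean squared residual, covariance block only.

    Both matrices are scaled into the correlation metric by the *sample*
    standard deviations, so variance residuals contribute; mean residuals do
    not enter this variant.  Averaged over the p(p+1)/2 nonredundant cells.
    """
    sd = np.sqrt(np.diag(S))
    scale = np.outer(sd, sd)
    resid = S / scale - sigma / scale
    p = S.shape[0]
    tri = np.tril_indices(p)
    return float(np.sqrt(np.mean(resid[tri] ** 2)))


@dataclass
class DiffResult:
    d_stat: float
    d_df: int
    d_cfi: float
    d_rmsea: float
    d_srmr: float


def chisq_diff(nested_fit, parent_fit) -> DiffResult:
    """Fit deterioration of a nested (more constrained) model vs its parent.

    ΔCFI = CFI_parent - CFI_nested and ΔRMSEA = RMSEA_nested - RMSEA_parent,
    so positive values always mean 'the constraint hurt'.
    """
    if nested_fit.df < parent_fit.df:
        raise ValueError(
            "models are not nested: the constrained model must have >= df"
        )
    if nested_fit.n_total != parent_fit.n_total:
        raise ValueError("fits use different samples")
    d_stat = nested_fit.stat - parent_fit.stat
    if d_stat < -1e-6 * max(1.0, abs(parent_fit.stat)):
        raise ValueError(
            f"nested statistic smaller than parent ({d_stat:.3g}); "
            "specs are likely not nested"
        )
    return DiffResult(
        d_stat=max(d_stat, 0.0),
        d_df=nested_fit.df - parent_fit.df,
        d_cfi=parent_fit.cfi - nested_fit.cfi,
        d_rmsea=nested_fit.rmsea - parent_fit.rmsea,
        d_srmr=nested_fit.srmr - parent_fit.srmr,
    )
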