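"""Inverse probability weighting for unit nonresponse.

A logistic model for the propensity to be a complete case is fitted by
iteratively reweighted least squares; complete cases receive the reciprocal
propensity (trimmed at a high quantile), which is multiplied by the survey
weight and rescaled to mean 1 over the analysed cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class SeparationError(RuntimeError):
    """Perfect separation: some covariate predicts completeness exactly."""


@dataclass
class PropensityModel:
    coef: np.ndarray
    names: list[str]
    converged: bool
    n_iter: int
    fitted: np.ndarray  # probabilities for every case

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.names, "coef": self.coef})


@dataclass
class WeightSet:
    ipw: np.ndarray  # complete cases only (aligned to `analysed` mask)
    combined: np.ndarray  # ipw * survey weight, mean 1 over analysed cases
    analysed: np.ndarray  # boolean mask into the original frame
    trim_bound: float
    model: PropensityModel


def fit_completeness_model(
    covariates: pd.DataFrame | np.ndarray,
    complete_flag: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> PropensityModel:
    """Logistic regression of completeness on fully observed covariates.

    Converges when the largest coefficient change drops below ``tol``.
    A constant outcome returns propensities of the observed rate with a
    warning (no model needed); perfect separation raises.
    """
    if isinstance(covariates, pd.DataFrame):
        names = ["(intercept)"] + list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = ["(intercept)"] + [f"x{j}" for j in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("propensity covariates must be fully observed")
    y = np.asarray(complete_flag, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("complete_flag must be binary")
    n = len(y)
    X = np.column_stack([np.ones(n), X])

    rate = y.mean()
    if rate in (0.0, 1.0):
        warnings.warn(
            "completeness flag is constant; returning constant propensities",
            stacklevel=2,
        )
        return PropensityModel(
            coef=np.full(X.shape[1], np.nan), names=names, converged=True,
            n_iter=0, fitted=np.full(n, rate),
        )

    beta = np.zeros(X.shape[1])
    beta[0] = np.log(rate / (1 - rate))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        if w.max() < 1e-10:
            raise SeparationError(
                "perfect separation detected; remove the offending covariate"
            )
        # Newton step via weighted least squares
        WX = X * w[:, None]
        try:
            step = np.linalg.solve(X.T @ WX, X.T @ (y - p))
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information; covariates collinear or separating"
            ) from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 30:
            raise SeparationError(
                "coefficients diverging; perfect separation likely — "
                "remove the offending covariate"
            )
    fitted = 1.0 / (1.0 + np.exp(-(X @ beta)))
    return PropensityModel(beta, names, converged, it, fitted)


def make_ipw(propensities: np.ndarray, trim_quantile: float = 0.99) -> tuple[np.ndarray, float]:
    """1/propensity, capped at the ``trim_quantile`` of the untrimmed weights."""
    p = np.asarray(propensities, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1 + 1e-12) or np.isnan(p).any():
        raise ValueError("propensities must lie in (0, 1)")
    ipw = 1.0 / p
    bound = float(np.quantile(ipw, trim_quantile))
    return np.minimum(ipw, bound), bound


def combine_weights(ipw: np.ndarray, survey_weight: np.ndarray) -> np.ndarray:
    """Elementwise product rescaled to mean 1."""
    ipw = np.asarray(ipw, dtype=float)
    sw = np.asarray(survey_weight, dtype=float)
    if ipw.shape != sw.shape:
        raise ValueError("weight vectors differ in length")
    if np.any(sw <= 0):
        raise ValueError("survey weights must be positive")
    combined = ipw * sw
    return combined / combined.mean()


def build_weights(
    frame: pd.DataFrame,
    covariate_cols: list[str],
    complete_col: str = "complete",
    survey_weight_col: str = "svywt",
    trim_quantile: float = 0.99,
) -> WeightSet:
    """End-to-end: propensity model -> trimmed IPW -> combined analysis weight.

    Incomplete cases carry no weight and are excluded from ``analysed``.
    """
    model = fit_completeness_model(
        frame[covariate_cols], frame[complete_col].to_numpy()
    )
    analysed = frame[complete_col].to_numpy().astype(bool)
    ipw, bound = make_ipw(model.fitted[analysed], trim_quantile)
    sw = frame.loc[analysed, survey_weight_col].to_numpy(dtype=float)
    combined = combine_weights(ipw, sw)
    return WeightSet(ipw=ipw, combined=combined, analysed=analysed,
                     trim_bound=bound, model=model)


def attach_weights(frame: pd.DataFrame, ws: WeightSet, column: str = "combwt") -> pd.DataFrame:
    out = frame.copy()
    out[column] = np.nan
    out.loc[ws.analysed, column] = ws.combined
    out[column + "_ipw"] = np.nan
    out.loc[ws.analysed, column + "_ipw"] = ws.ipw
    return out
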