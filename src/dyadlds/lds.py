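"""Latent difference score models for two-reporter dyads.

The self-report factor is measured by the self items; the parent factor by
the parent items with its latent mean fixed to zero, a unit regression on
the self factor, and a unit loading from a second-order factor.  That
second-order factor is then the latent discrepancy: its mean is the true
parent-minus-self difference (positive = parents rate higher), free of
measurement error.  Conditional models regress both the self factor and the
discrepancy on one binary covariate, so the covariate's effect on the
discrepancy is net of its effect on self-report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import item_columns, scored_item_frame, subscale_definition
from .invariance import (
    InvarianceReport,
    LadderError,
    MARKER_POS,
    _load_label,
    _int_label,
    accepted_equality_sets,
)
from .sem import GroupData, ModelSpec, fit_ml, FitResult, ParameterTable

# parameter labels used throughout
A_SELF = "lds_alpha_self"
A_DELTA = "lds_alpha_delta"
PSI_SS = "lds_psi_self"
PSI_DD = "lds_psi_delta"
PSI_SD = "lds_cov_self_delta"
B_SELF = "lds_beta_self"
B_DELTA = "lds_beta_delta"
A_X = "lds_alpha_x"
PSI_XX = "lds_psi_x"

REFERENCE_LEVELS = {"sex": "female", "distress": "low distress", "edu": "low education"}


def stars(p: float | None) -> str:
    if p is None or np.isnan(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


# ---------------------------------------------------------------------------
# spec construction
# ---------------------------------------------------------------------------


def build_lds_spec(
    construct: str,
    loading_eq: frozenset[int],
    intercept_eq: frozenset[int],
    covariate: str | None = None,
    residual_cov: bool = False,
    fix_delta_mean: bool = False,
) -> ModelSpec:
    """LDS ModelSpec carrying the accepted invariance constraints verbatim.

    ``loading_eq`` / ``intercept_eq`` are the non-marker positions still
    constrained equal across reporters (from the invariance ladder).
    """
    self_cols = item_columns(construct, "self")
    parent_cols = item_columns(construct, "parent")
    latents = ["fS", "fP", "d"]
    observed = self_cols + parent_cols
    if covariate is not None:
        observed = observed + [covariate]
        latents = latents + ["x"]
    spec = ModelSpec(observed, latents)
    for reporter, cols, factor in (("self", self_cols, "fS"), ("parent", parent_cols, "fP")):
        for pos, col in enumerate(cols):
            if pos == MARKER_POS:
                spec.add("lambda", col, factor, free=False, value=1.0)
                spec.add("nu", col, free=False, value=0.0)
            else:
                lab_l = _load_label(construct, pos) if (
                    reporter == "self" or pos in loading_eq) else None
                lab_n = _int_label(construct, pos) if (
                    reporter == "self" or pos in intercept_eq) else None
                spec.add("lambda", col, factor, free=True, value=1.0, label=lab_l)
                spec.add("nu", col, free=True, value=0.0, label=lab_n)
            spec.add("theta", col, col, free=True, value=0.3)
    if residual_cov:
        for s_col, p_col in zip(self_cols, parent_cols):
            spec.add("theta", s_col, p_col, free=True, value=0.0)

    # structural core: parent = self + discrepancy, exactly
    spec.add("beta", "fP", "fS", free=False, value=1.0)
    spec.add("beta", "fP", "d", free=False, value=1.0)
    spec.add("alpha", "fS", free=True, value=0.3, label=A_SELF)
    # parent factor: mean fixed 0, no residual variance (cells left at zero)
    spec.add("alpha", "d", free=not fix_delta_mean, value=0.0, label=A_DELTA)
    spec.add("psi", "fS", "fS", free=True, value=0.3, label=PSI_SS)
    spec.add("psi", "d", "d", free=True, value=0.1, label=PSI_DD)
    spec.add("psi", "fS", "d", free=True, value=0.0, label=PSI_SD)

    if covariate is not None:
        spec.add("lambda", covariate, "x", free=False, value=1.0)
        spec.add("alpha", "x", free=True, value=0.5, label=A_X)
        spec.add("psi", "x", "x", free=True, value=0.25, label=PSI_XX)
        spec.add("beta", "fS", "x", free=True, value=0.0, label=B_SELF)
        spec.add("beta", "d", "x", free=True, value=0.0, label=B_DELTA)
    return spec


def spec_from_invariance(
    report: InvarianceReport,
    covariate: str | None = None,
    residual_cov: bool = False,
) -> ModelSpec:
    """The paper-contract entry point: refuses non-accepted invariance input."""
    l_eq, n_eq = accepted_equality_sets(report)  # raises if not invariant
    return build_lds_spec(report.construct, l_eq, n_eq, covariate, residual_cov)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class LDSResult:
    construct: str
    n: int
    fit: FitResult
    table: ParameterTable
    mean_raw: float
    mean_raw_se: float
    variance: float
    variance_se: float
    covariance_raw: float
    covariance_raw_se: float
    self_variance: float
    mean_std: float
    mean_std_se: float
    covariance_std: float
    covariance_std_se: float
    degenerate: bool = False

    @property
    def mean_p(self) -> float:
        return _wald_p(self.mean_raw, self.mean_raw_se)

    @property
    def variance_p(self) -> float:
        return _wald_p(self.variance, self.variance_se)

    @property
    def covariance_p(self) -> float:
        return _wald_p(self.covariance_raw, self.covariance_raw_se)

    def to_row(self) -> dict:
        return {
            "construct": self.construct, "n": self.n,
            "CFI": self.fit.cfi, "RMSEA": self.fit.rmsea, "SRMR": self.fit.srmr,
            "mean_std": self.mean_std, "mean_stars": stars(self.mean_p),
            "variance": self.variance, "variance_stars": stars(self.variance_p),
            "cov_std": self.covariance_std, "cov_stars": stars(self.covariance_p),
            "mean_raw": self.mean_raw, "cov_raw": self.covariance_raw,
        }


@dataclass
class GroupEstimate:
    level: str
    value: float  # standardized discrepancy mean at this level
    se: float
    ci_low: float
    ci_high: float
    self_mean: float  # raw predicted factor means for plotting
    parent_mean: float


@dataclass
class ConditionalLDSResult:
    construct: str
    covariate: str
    n: int
    fit: FitResult
    table: ParameterTable
    beta_self: float
    beta_self_se: float
    beta_self_std: float
    beta_delta: float
    beta_delta_se: float
    beta_delta_std: float
    reference: GroupEstimate
    other: GroupEstimate

    @property
    def beta_self_p(self) -> float:
        return _wald_p(self.beta_self, self.beta_self_se)

    @property
    def beta_delta_p(self) -> float:
        return _wald_p(self.beta_delta, self.beta_delta_se)

    def to_row(self) -> dict:
        return {
            "construct": self.construct, "covariate": self.covariate, "n": self.n,
            "beta_self_std": self.beta_self_std, "beta_self_stars": stars(self.beta_self_p),
            "beta_delta_std": self.beta_delta_std, "beta_delta_stars": stars(self.beta_delta_p),
            "ref_level": self.reference.level, "ref_est": self.reference.value,
            "ref_ci": (self.reference.ci_low, self.reference.ci_high),
            "other_est": self.other.value,
            "other_ci": (self.other.ci_low, self.other.ci_high),
        }


def _wald_p(est: float, se: float) -> float:
    if se is None or not np.isfinite(se) or se <= 0:
        return float("nan")
    return 2.0 * float(stats.norm.sf(abs(est / se)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _lds_data(frame: pd.DataFrame, construct: str, weights, covariate=None):
    blocks = [
        scored_item_frame(frame, construct, "self"),
        scored_item_frame(frame, construct, "parent"),
    ]
    if covariate is not None:
        col = frame[covariate].astype(float)
        bad = ~col.dropna().isin((0.0, 1.0))
        if bad.any():
            raise ValueError(f"covariate {covariate!r} must be binary 0/1")
        blocks.append(col.to_frame())
    data = pd.concat(blocks, axis=1)
    if isinstance(weights, str):
        w = frame[weights].to_numpy(dtype=float)
    elif weights is None:
        w = np.ones(len(frame))
    else:
        w = np.asarray(weights, dtype=float)
    return data, w


def fit_lds(
    frame: pd.DataFrame,
    spec: ModelSpec,
    construct: str,
    weights=None,
    mode: str = "moments",
    seed: int = 0,
) -> LDSResult:
    """Fit the unconditional LDS and standardize the discrepancy parameters."""
    covariate = spec.observed[10] if len(spec.observed) > 10 else None
    data, w = _lds_data(frame, construct, weights, covariate)
    keep = ~np.isnan(w)
    gd = GroupData(data[keep].to_numpy(dtype=float), w[keep], list(data.columns))
    table, fit = fit_ml([spec], [gd], mode=mode, seed=seed)

    a_d = table.estimate(A_DELTA)
    se_a = table.se(A_DELTA)
    phi = table.estimate(PSI_DD)
    se_phi = table.se(PSI_DD)
    cov_sd = table.estimate(PSI_SD)
    se_cov = table.se(PSI_SD)
    psi_s = table.estimate(PSI_SS)

    degenerate = phi <= 10 * 1e-6
    if degenerate:
        mean_std, mean_std_se = float("nan"), float("nan")
        cov_std, cov_std_se = float("nan"), float("nan")
    else:
        mean_std, mean_std_se = table.delta_method(
            lambda v: v[0] / np.sqrt(v[1]), [A_DELTA, PSI_DD]
        )
        cov_std, cov_std_se = table.delta_method(
            lambda v: v[0] / (np.sqrt(v[1]) * np.sqrt(v[2])), [PSI_SD, PSI_DD, PSI_SS]
        )
    return LDSResult(
        construct=construct, n=fit.n_total, fit=fit, table=table,
        mean_raw=a_d, mean_raw_se=se_a, variance=phi, variance_se=se_phi,
        covariance_raw=cov_sd, covariance_raw_se=se_cov, self_variance=psi_s,
        mean_std=mean_std, mean_std_se=mean_std_se,
        covariance_std=cov_std, covariance_std_se=cov_std_se,
        degenerate=degenerate,
    )


def fit_conditional_lds(
    frame: pd.DataFrame,
    spec: ModelSpec,
    construct: str,
    covariate: str,
    weights=None,
    mode: str = "moments",
    seed: int = 0,
    reference_label: str | None = None,
) -> ConditionalLDSResult:
    """Fit one conditional LDS (one binary covariate; separate models per
    covariate by contract) and compute per-level estimates with delta-method
    95% CIs on the standardized scale."""
    if covariate not in spec.observed:
        raise ValueError("spec does not carry this covariate")
    data, w = _lds_data(frame, construct, weights, covariate)
    keep = ~np.isnan(w)
    gd = GroupData(data[keep].to_numpy(dtype=float), w[keep], list(data.columns))
    table, fit = fit_ml([spec], [gd], mode=mode, seed=seed)

    b_s = table.estimate(B_SELF)
    b_d = table.estimate(B_DELTA)
    psi_x = table.estimate(PSI_XX)
    psi_s = table.estimate(PSI_SS)
    phi = table.estimate(PSI_DD)
    sd_x = float(np.sqrt(max(psi_x, 0.0)))
    # standardized by the factor's conditional (reference-level) SD
    b_s_std = b_s * sd_x / float(np.sqrt(max(psi_s, 1e-12)))
    b_d_std = b_d * sd_x / float(np.sqrt(max(phi, 1e-12)))

    ref_label = reference_label or REFERENCE_LEVELS.get(covariate, f"{covariate}=0")
    oth_label = {
        "sex": "male", "distress": "high distress", "edu": "high education",
    }.get(covariate, f"{covariate}=1")

    def level_std(x):
        def fn(v):  # v = (alpha_d, beta_d, phi_d)
            return (v[0] + v[1] * x) / np.sqrt(v[2])
        return fn

    ref_val, ref_se = table.delta_method(level_std(0.0), [A_DELTA, B_DELTA, PSI_DD])
    oth_val, oth_se = table.delta_method(level_std(1.0), [A_DELTA, B_DELTA, PSI_DD])
    a_s = table.estimate(A_SELF)
    a_d = table.estimate(A_DELTA)
    z = float(stats.norm.ppf(0.975))
    ref = GroupEstimate(ref_label, ref_val, ref_se, ref_val - z * ref_se,
                        ref_val + z * ref_se, a_s, a_s + a_d)
    oth = GroupEstimate(oth_label, oth_val, oth_se, oth_val - z * oth_se,
                        oth_val + z * oth_se, a_s + b_s,
                        a_s + b_s + a_d + b_d)
    return ConditionalLDSResult(
        construct=construct, covariate=covariate, n=fit.n_total, fit=fit,
        table=table, beta_self=b_s, beta_self_se=table.se(B_SELF),
        beta_self_std=b_s_std, beta_delta=b_d, beta_delta_se=table.se(B_DELTA),
        beta_delta_std=b_d_std, reference=ref, other=oth,
    )


def conditional_group_estimates(result: ConditionalLDSResult) -> pd.DataFrame:
    """Per-level standardized discrepancy estimates with 95% CIs (plot-ready)."""
    rows = []
    for ge in (result.reference, result.other):
        rows.append({
            "construct": result.construct, "covariate": result.covariate,
            "level": ge.level, "estimate": ge.value, "se": ge.se,
            "ci_low": ge.ci_low, "ci_high": ge.ci_high,
            "self_factor_mean": ge.self_mean, "parent_factor_mean": ge.parent_mean,
        })
    return pd.DataFrame(rows)
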