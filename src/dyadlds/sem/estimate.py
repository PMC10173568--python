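"""Maximum-likelihood estimation for mean-and-covariance structure models.

Two estimation modes are provided:

``moments``
    Minimizes ``sum_g n_g F_g`` where ``F`` is the ML discrepancy between
    (weighted) sample moments and implied moments.  Compatible with case
    weights; rows with any missing model variable are dropped.

``fiml``
    Full-information maximum likelihood: maximizes the casewise loglikelihood
    over each row's observed subset, so item-level missingness is retained.

Standard errors come from the inverse observed information on unweighted
complete data and from a sandwich estimator whenever weights are supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .model import ParamIndex, ModelSpec
from .moments import (
    Moments,
    implied_moments,
    gradient_from_adjoints,
    moment_jacobians,
    expected_information,
)

_LN2PI = float(np.log(2.0 * np.pi))
_BIG = 1e12
VARIANCE_FLOOR = 1e-6


class NotPositiveDefiniteError(ValueError):
    def __init__(self, which: str):
        super().__init__(f"matrix {which} is not positive definite")
        self.which = which


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class GroupData:
    """One group's raw data aligned to a spec's observed-variable order."""

    y: np.ndarray  # n x p, NaN for missing
    weights: np.ndarray  # n, normalized to mean 1 lazily
    names: list[str]

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        columns: list[str],
        weights: np.ndarray | str | None = None,
    ) -> "GroupData":
        y = frame[columns].to_numpy(dtype=float)
        if isinstance(weights, str):
            w = frame[weights].to_numpy(dtype=float)
        elif weights is None:
            w = np.ones(len(frame))
        else:
            w = np.asarray(weights, dtype=float)
        if w.shape[0] != y.shape[0]:
            raise ValueError("weights length does not match data")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and nonnegative")
        return cls(y, w, list(columns))

    def complete_cases(self) -> "GroupData":
        keep = ~np.isnan(self.y).any(axis=1)
        return GroupData(self.y[keep], self.weights[keep], self.names)

    def any_observed(self) -> "GroupData":
        keep = ~np.isnan(self.y).all(axis=1)
        return GroupData(self.y[keep], self.weights[keep], self.names)

    @property
    def n(self) -> int:
        return self.y.shape[0]


def weighted_moments(y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted mean and ML (biased) covariance; weights renormalized to mean 1."""
    w = w / w.mean()
    W = w.sum()
    mbar = (w[:, None] * y).sum(axis=0) / W
    z = y - mbar
    S = (z.T * w) @ z / W
    return S, mbar, W


# ---------------------------------------------------------------------------
# discrepancy
# ---------------------------------------------------------------------------


def _chol(mat: np.ndarray, name: str):
    try:
        return cho_factor(mat, lower=True)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(name) from exc


def fml_discrepancy(S: np.ndarray, mbar: np.ndarray, sigma: np.ndarray, mu: np.ndarray) -> float:
    """ML discrepancy  F = log|Sigma| + tr(S Sigma^-1) - log|S| - p + d' Sigma^-1 d."""
    p = S.shape[0]
    cs = _chol(S, "S")
    csig = _chol(sigma, "Sigma")
    logdet_s = 2.0 * np.log(np.diag(cs[0])).sum()
    logdet_sig = 2.0 * np.log(np.diag(csig[0])).sum()
    d = mbar - mu
    siginv_d = cho_solve(csig, d)
    tr = np.trace(cho_solve(csig, S))
    return float(logdet_sig + tr - logdet_s - p + d @ siginv_d)


# ---------------------------------------------------------------------------
# objective functions
# ---------------------------------------------------------------------------


class _MomentsObjective:
    """T(theta) = sum_g n_g F_g for weighted sample moments."""

    def __init__(self, index: ParamIndex, groups: list[GroupData]):
        self.index = index
        self.S: list[np.ndarray] = []
        self.mbar: list[np.ndarray] = []
        self.n: list[float] = []
        self.logdet_s: list[float] = []
        for gd in groups:
            S, mbar, W = weighted_moments(gd.y, gd.weights)
            cs = _chol(S, "S")
            self.S.append(S)
            self.mbar.append(mbar)
            self.n.append(float(gd.n))
            self.logdet_s.append(2.0 * np.log(np.diag(cs[0])).sum())

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        total = 0.0
        grad = np.zeros(self.index.n_free)
        for g, (S, mbar, n_g) in enumerate(zip(self.S, self.mbar, self.n)):
            mom = implied_moments(self.index, g, theta)
            p = S.shape[0]
            try:
                csig = _chol(mom.sigma, "Sigma")
            except NotPositiveDefiniteError:
                return _BIG, np.zeros(self.index.n_free)
            logdet_sig = 2.0 * np.log(np.diag(csig[0])).sum()
            siginv = cho_solve(csig, np.eye(p))
            d = mbar - mom.mu
            sd = siginv @ d
            F = logdet_sig + float(np.sum(siginv * S)) - self.logdet_s[g] - p + float(d @ sd)
            total += n_g * F
            G = siginv - siginv @ (S + np.outer(d, d)) @ siginv
            G = 0.5 * (G + G.T)
            h = -2.0 * sd
            gradient_from_adjoints(self.index, g, mom, n_g * G, n_g * h, grad)
        return total, grad


class _FimlObjective:
    """f(theta) = -2 * sum_i w_i * loglik_i over each row's observed subset."""

    def __init__(self, index: ParamIndex, groups: list[GroupData]):
        self.index = index
        self.patterns: list[list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = []
        self.W: list[float] = []
        for gd in groups:
            mask = ~np.isnan(gd.y)
            w = gd.weights / gd.weights.mean()
            pats: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
            codes = np.array([hash(m.tobytes()) for m in mask])
            for code in pd.unique(codes):
                rows = codes == code
                ix = np.flatnonzero(mask[rows][0])
                if ix.size == 0:
                    continue
                pats.append((ix, gd.y[np.ix_(rows, ix)], w[rows]))
            self.patterns.append(pats)
            self.W.append(float(w.sum()))

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        total = 0.0
        grad = np.zeros(self.index.n_free)
        for g, pats in enumerate(self.patterns):
            mom = implied_moments(self.index, g, theta)
            p = mom.sigma.shape[0]
            Gfull = np.zeros((p, p))
            hfull = np.zeros(p)
            for ix, Y, w in pats:
                k = ix.size
                sig_o = mom.sigma[np.ix_(ix, ix)]
                mu_o = mom.mu[ix]
                try:
                    c = _chol(sig_o, "Sigma")
                except NotPositiveDefiniteError:
                    return _BIG, np.zeros(self.index.n_free)
                siginv = cho_solve(c, np.eye(k))
                logdet = 2.0 * np.log(np.diag(c[0])).sum()
                Z = Y - mu_o
                U = Z @ siginv
                quad = np.einsum("ij,ij->i", U, Z)
                Wp = w.sum()
                total += float(w @ (k * _LN2PI + logdet + quad))  # = -2*loglik
                C = (Z.T * w) @ Z
                dl_dsig = -0.5 * (Wp * siginv - siginv @ C @ siginv)
                dl_dmu = siginv @ (w @ Z)
                # objective = -2*loglik
                Gfull[np.ix_(ix, ix)] += -2.0 * dl_dsig
                hfull[ix] += -2.0 * dl_dmu
            gradient_from_adjoints(self.index, g, mom, Gfull, hfull, grad)
        return total, grad

    def loglik(self, theta: np.ndarray) -> float:
        return -0.5 * self.value_and_grad(theta)[0]


# ---------------------------------------------------------------------------
# saturated / baseline models under missing data (EM)
# ---------------------------------------------------------------------------


def em_saturated(gd: GroupData, tol: float = 1e-10, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray, float]:
    """ML estimates of an unstructured (mu, Sigma) under ignorable missingness.

    Plain EM over missingness patterns with case weights; returns
    (mu, Sigma, loglik).  With complete data this converges immediately to the
    weighted ML moments.
    """
    y = gd.y
    w = gd.weights / gd.weights.mean()
    n, p = y.shape
    mask = ~np.isnan(y)
    mu = np.nanmean(y, axis=0)
    filled = np.where(mask, y, mu)
    S, mbar, W = weighted_moments(filled, w)
    sigma = S + np.eye(p) * 1e-6
    mu = mbar
    codes = np.array([hash(m.tobytes()) for m in mask])
    pats = []
    for code in pd.unique(codes):
        rows = codes == code
        obs = np.flatnonzero(mask[rows][0])
        pats.append((np.flatnonzero(rows), obs))
    last = -np.inf
    ll = last
    for _ in range(max_iter):
        Ey = np.zeros((n, p))
        Eyy = np.zeros((p, p))
        ll = 0.0
        for rows, obs in pats:
            mis = np.setdiff1d(np.arange(p), obs)
            Yo = y[np.ix_(rows, obs)]
            wg = w[rows]
            sig_oo = sigma[np.ix_(obs, obs)]
            c = _chol(sig_oo, "Sigma")
            siginv = cho_solve(c, np.eye(obs.size))
            Z = Yo - mu[obs]
            ll += -0.5 * float(
                wg @ (obs.size * _LN2PI + 2.0 * np.log(np.diag(c[0])).sum()
                      + np.einsum("ij,ij->i", Z @ siginv, Z))
            )
            Ey[np.ix_(rows, obs)] = Yo
            if mis.size:
                beta = sigma[np.ix_(mis, obs)] @ siginv
                cond = mu[mis] + Z @ beta.T
                Ey[np.ix_(rows, mis)] = cond
                cov_cond = sigma[np.ix_(mis, mis)] - beta @ sigma[np.ix_(obs, mis)]
                Eyy[np.ix_(mis, mis)] += wg.sum() * cov_cond
        W = w.sum()
        mu = (w[:, None] * Ey).sum(axis=0) / W
        Zf = Ey - mu
        Eyy += (Zf.T * w) @ Zf
        sigma = Eyy / W
        sigma = 0.5 * (sigma + sigma.T)
        if abs(ll - last) < tol * (1.0 + abs(ll)):
            break
        last = ll
    return mu, sigma, ll


def fiml_independence_loglik(gd: GroupData) -> tuple[float, int]:
    """Loglik of the FIML baseline model (free means and variances, zero
    covariances): per-variable ML on each variable's observed cases."""
    w = gd.weights / gd.weights.mean()
    ll = 0.0
    n_params = 0
    for j in range(gd.y.shape[1]):
        col = gd.y[:, j]
        obs = ~np.isnan(col)
        wj = w[obs]
        yj = col[obs]
        m = (wj @ yj) / wj.sum()
        v = (wj @ (yj - m) ** 2) / wj.sum()
        v = max(v, VARIANCE_FLOOR)
        ll += -0.5 * float(wj @ (_LN2PI + np.log(v) + (yj - m) ** 2 / v))
        n_params += 2
    return ll, n_params


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    stat: float  # chi-square test statistic T
    df: int
    stat_baseline: float
    df_baseline: int
    cfi: float
    rmsea: float
    srmr: float
    n_groups: list[int]
    n_free: int
    loglik: float | None
    converged: bool
    mode: str
    weighted: bool
    saturated: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return int(sum(self.n_groups))

    def to_dict(self) -> dict:
        return {
            "chisq": self.stat, "df": self.df, "cfi": self.cfi,
            "rmsea": self.rmsea, "srmr": self.srmr, "n": self.n_total,
            "n_free": self.n_free, "loglik": self.loglik,
            "converged": self.converged, "mode": self.mode,
            "weighted": self.weighted,
        }


@dataclass
class ParamEstimate:
    group: int
    matrix: str
    row: str
    col: str | None
    label: str | None
    free: bool
    value: float
    se: float | None
    z: float | None
    pvalue: float | None
    std: float | None


class ParameterTable:
    """Fitted estimates with SEs, standardized values and provenance."""

    def __init__(
        self,
        index: ParamIndex,
        theta: np.ndarray,
        cov: np.ndarray | None,
        rows: list[ParamEstimate],
        discrepancy: float,
        convergence: dict,
    ):
        self.index = index
        self.theta = theta
        self.cov = cov
        self.rows = rows
        self.discrepancy = discrepancy
        self.convergence = convergence
        self._label_pos = {lab: i for i, lab in enumerate(index.labels)}

    def estimate(self, label: str) -> float:
        return float(self.theta[self._label_pos[label]])

    def se(self, label: str) -> float:
        if self.cov is None:
            return float("nan")
        i = self._label_pos[label]
        return float(np.sqrt(max(self.cov[i, i], 0.0)))

    def get(self, group: int, matrix: str, row: str, col: str | None = None) -> ParamEstimate:
        for r in self.rows:
            if (r.group, r.matrix, r.row, r.col) == (group, matrix, row, col):
                return r
        raise KeyError((group, matrix, row, col))

    def delta_method(self, func, labels: list[str]) -> tuple[float, float]:
        """Value and SE of ``func(values)`` of the named parameters."""
        if self.cov is None:
            raise ValueError("no parameter covariance available")
        idx = [self._label_pos[lab] for lab in labels]
        x0 = self.theta[idx]
        val = float(func(x0))
        grad = np.zeros(len(idx))
        for k in range(len(idx)):
            h = 1e-6 * (1.0 + abs(x0[k]))
            xp = x0.copy(); xp[k] += h
            xm = x0.copy(); xm[k] -= h
            grad[k] = (func(xp) - func(xm)) / (2.0 * h)
        sub = self.cov[np.ix_(idx, idx)]
        var = float(grad @ sub @ grad)
        return val, float(np.sqrt(max(var, 0.0)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": r.group, "matrix": r.matrix, "row": r.row,
                    "col": r.col, "label": r.label, "free": r.free,
                    "value": r.value, "se": r.se, "z": r.z,
                    "pvalue": r.pvalue, "std": r.std,
                }
                for r in self.rows
            ]
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _as_group_list(specs, data, weights) -> tuple[list[ModelSpec], list[GroupData]]:
    if isinstance(specs, ModelSpec):
        specs = [specs]
    if isinstance(data, (pd.DataFrame, GroupData)):
        data = [data]
    if len(specs) != len(data):
        raise ValueError("one data group per spec required")
    groups = []
    for spec, d in zip(specs, data):
        if isinstance(d, pd.DataFrame):
            groups.append(GroupData.from_frame(d, spec.observed, weights))
        else:
            groups.append(d)
    return list(specs), groups


def _numeric_hessian(fun_grad, theta: np.ndarray) -> np.ndarray:
    q = theta.size
    H = np.zeros((q, q))
    for j in range(q):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        gp = fun_grad(tp)[1]
        gm = fun_grad(tm)[1]
        H[j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _casewise_scores(
    index: ParamIndex, theta: np.ndarray, groups: list[GroupData]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-case loglik scores s_i = d loglik_i / d theta and the case weights.

    Handles item-level missingness by restricting each row to its observed
    subset (so it serves both moments mode on complete data and FIML).
    """
    all_scores = []
    all_w = []
    for g, gd in enumerate(groups):
        mom = implied_moments(index, g, theta)
        dsig, dmu = moment_jacobians(index, g, theta, mom)
        mask = ~np.isnan(gd.y)
        codes = np.array([hash(m.tobytes()) for m in mask])
        w = gd.weights / gd.weights.mean()
        scores = np.zeros((gd.n, index.n_free))
        for code in pd.unique(codes):
            rows = codes == code
            ix = np.flatnonzero(mask[rows][0])
            if ix.size == 0:
                continue
            sub = np.ix_(ix, ix)
            siginv = np.linalg.inv(mom.sigma[sub])
            Z = gd.y[np.ix_(np.flatnonzero(rows), ix)] - mom.mu[ix]
            U = Z @ siginv
            dsig_o = dsig[:, ix][:, :, ix]
            dmu_o = dmu[:, ix]
            tr_term = np.einsum("pq,jqp->j", siginv, dsig_o)
            quad = np.einsum("ip,jpq,iq->ij", U, dsig_o, U)
            scores[rows] = 0.5 * (quad - tr_term[None, :]) + U @ dmu_o.T
        all_scores.append(scores)
        all_w.append(w)
    return np.vstack(all_scores), np.concatenate(all_w)


def fit_ml(
    specs,
    data,
    weights=None,
    mode: str = "moments",
    se: str = "auto",
    max_iter: int = 500,
    tol: float = 1e-10,
    restarts: int = 3,
    seed: int = 0,
    compute_se: bool = True,
) -> tuple[ParameterTable, FitResult]:
    """Fit a (multi-group) SEM by ML.

    Parameters
    ----------
    specs : ModelSpec or list of ModelSpec
    data : DataFrame / GroupData or list thereof
    weights : column name, array, or None (applies when data are DataFrames)
    mode : 'moments' (listwise, weighted sample moments) or 'fiml'
    se : 'auto' (sandwich when weights vary, otherwise observed), 'observed',
         'sandwich', or 'none'
    """
    if mode not in ("moments", "fiml"):
        raise ValueError(f"unknown mode {mode!r}")
    specs, groups = _as_group_list(specs, data, weights)
    raw_groups = groups
    if mode == "moments":
        groups = [g.complete_cases() for g in groups]
    else:
        groups = [g.any_observed() for g in groups]
    for spec, g in zip(specs, groups):
        if g.n <= len(spec.free_labels()):
            raise ValueError("fewer cases than free parameters")
    index = ParamIndex(specs)
    weighted = any(np.ptp(g.weights) > 1e-12 for g in groups)

    obj = _MomentsObjective(index, groups) if mode == "moments" else _FimlObjective(index, groups)
    bounds = index.variance_bounds(VARIANCE_FLOOR)

    rng = np.random.default_rng(seed)
    theta0 = index.start.copy()
    best = None
    converged = False
    n_iter_used = 0
    for attempt in range(restarts + 1):
        res = optimize.minimize(
            obj.value_and_grad, theta0, jac=True, method="L-BFGS-B",
            bounds=bounds, options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
        )
        n_iter_used = int(res.nit)
        if best is None or res.fun < best.fun:
            best = res
        grad_norm = float(np.max(np.abs(res.jac)))
        if res.fun < _BIG and (res.success or grad_norm < 1e-4):
            converged = True
            best = res
            break
        jitter = rng.normal(scale=0.1, size=theta0.size)
        theta0 = index.start + jitter
        lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
        theta0 = np.maximum(theta0, lo + 0.01)
    assert best is not None
    theta = best.x
    fit_warnings: list[str] = []
    if not converged:
        fit_warnings.append("optimizer did not converge")

    heywood = [
        index.labels[j]
        for j, b in enumerate(bounds)
        if b[0] is not None and theta[j] <= b[0] * 1.5
    ]
    if heywood:
        fit_warnings.append("variance parameters at lower bound: " + ", ".join(heywood))
        warnings.warn("Heywood case: " + ", ".join(heywood), stacklevel=2)

    # -- test statistic, baseline, indices ---------------------------------
    from .indices import fit_indices_from, srmr as srmr_fn

    n_groups = [g.n for g in groups]
    n_total = sum(n_groups)
    p_list = [s.n_observed for s in specs]
    n_moments = sum(p * (p + 3) // 2 for p in p_list)
    df = n_moments - index.n_free
    loglik = None

    if mode == "moments":
        stat = float(best.fun)
        stat0 = 0.0
        df0 = 0
        srmr_parts = []
        for g, spec in enumerate(specs):
            S = obj.S[g]  # type: ignore[attr-defined]
            p = S.shape[0]
            corr_det = np.linalg.slogdet(
                S / np.sqrt(np.outer(np.diag(S), np.diag(S)))
            )[1]
            stat0 += n_groups[g] * (-corr_det)
            df0 += p * (p - 1) // 2
            mom = implied_moments(index, g, theta)
            srmr_parts.append((n_groups[g], srmr_fn(S, mom.sigma)))
        # complete-data loglik at the optimum (useful for comparisons)
        sat_ll = sum(
            -0.5 * n_groups[g] * (obj.logdet_s[g] + p_list[g] * (1 + _LN2PI))  # type: ignore[attr-defined]
            for g in range(len(specs))
        )
        loglik = float(sat_ll - 0.5 * stat)
    else:
        f_model = float(best.fun)
        stat = 0.0
        stat0 = 0.0
        df0 = 0
        srmr_parts = []
        for g, gd in enumerate(groups):
            mu_sat, sig_sat, ll_sat = em_saturated(gd)
            ll0, _ = fiml_independence_loglik(gd)
            pats = _FimlObjective(index, [gd])
            f_g = pats.value_and_grad(theta)[0]
            stat += f_g - (-2.0 * ll_sat)
            stat0 += (-2.0 * ll0) - (-2.0 * ll_sat)
            df0 += p_list[g] * (p_list[g] - 1) // 2
            mom = implied_moments(index, g, theta)
            srmr_parts.append((n_groups[g], srmr_fn(sig_sat, mom.sigma)))
        stat = max(stat, 0.0)
        loglik = -0.5 * f_model

    cfi, rmsea = fit_indices_from(stat, df, stat0, df0, n_total, len(specs))
    srmr_val = sum(n * s for n, s in srmr_parts) / n_total

    fit = FitResult(
        stat=stat, df=df, stat_baseline=stat0, df_baseline=df0,
        cfi=cfi, rmsea=rmsea, srmr=srmr_val,
        n_groups=n_groups, n_free=index.n_free, loglik=loglik,
        converged=converged, mode=mode, weighted=weighted,
        saturated=(df == 0), warnings=fit_warnings,
    )

    # -- standard errors ----------------------------------------------------
    cov = None
    if compute_se and se != "none":
        use_sandwich = se == "sandwich" or (se == "auto" and weighted)
        H = _numeric_hessian(obj.value_and_grad, theta)
        # loglik = -objective/2, so observed information = H/2
        try:
            A_inv = np.linalg.inv(0.5 * H)
            if use_sandwich:
                scores, w = _casewise_scores(index, theta, groups)
                B = (scores.T * (w**2)) @ scores
                cov = A_inv @ B @ A_inv
            else:
                cov = A_inv
            if np.any(np.diag(cov) < -1e-8):
                fit_warnings.append("information matrix not positive definite")
            cov = 0.5 * (cov + cov.T)
        except np.linalg.LinAlgError:
            fit_warnings.append("singular information matrix; SEs unavailable")
            cov = None

    table = _build_table(index, specs, theta, cov, float(best.fun), {
        "converged": converged, "n_iter": n_iter_used, "mode": mode,
        "objective": float(best.fun), "grad_norm": float(np.max(np.abs(best.jac))),
        "seed": seed,
    })
    return table, fit


def _build_table(
    index: ParamIndex,
    specs: list[ModelSpec],
    theta: np.ndarray,
    cov: np.ndarray | None,
    discrepancy: float,
    convergence: dict,
) -> ParameterTable:
    rows: list[ParamEstimate] = []
    for g, spec in enumerate(specs):
        mom = implied_moments(index, g, theta)
        sd_obs = np.sqrt(np.clip(np.diag(mom.sigma), 1e-12, None))
        lat_cov = mom.M
        sd_lat = np.sqrt(np.clip(np.diag(lat_cov), 1e-12, None))
        obs_ix = {v: i for i, v in enumerate(spec.observed)}
        lat_ix = {v: i for i, v in enumerate(spec.latents)}
        for cell in spec.cells():
            if cell.free:
                lab = index.label_of(g, cell.matrix, cell.row, cell.col)
                j = index.theta_index(g, cell.matrix, cell.row, cell.col)
                val = float(theta[j])
                se_v = None
                if cov is not None:
                    se_v = float(np.sqrt(max(cov[j, j], 0.0)))
                z = val / se_v if se_v and se_v > 0 else None
                pv = 2.0 * float(stats.norm.sf(abs(z))) if z is not None else None
            else:
                lab, val, se_v, z, pv = cell.label, cell.value, None, None, None
            std = _standardize(cell, val, sd_obs, sd_lat, obs_ix, lat_ix)
            rows.append(ParamEstimate(g, cell.matrix, cell.row, cell.col, lab,
                                      cell.free, val, se_v, z, pv, std))
    return ParameterTable(index, theta, cov, rows, discrepancy, convergence)


def _standardize(cell, val, sd_obs, sd_lat, obs_ix, lat_ix) -> float | None:
    m = cell.matrix
    if m == "lambda":
        return val * sd_lat[lat_ix[cell.col]] / sd_obs[obs_ix[cell.row]]
    if m == "nu":
        return val / sd_obs[obs_ix[cell.row]]
    if m == "theta":
        return val / (sd_obs[obs_ix[cell.row]] * sd_obs[obs_ix[cell.col]])
    if m == "beta":
        return val * sd_lat[lat_ix[cell.col]] / sd_lat[lat_ix[cell.row]]
    if m == "psi":
        return val / (sd_lat[lat_ix[cell.row]] * sd_lat[lat_ix[cell.col]])
    if m == "alpha":
        return val / sd_lat[lat_ix[cell.row]]
    return None
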