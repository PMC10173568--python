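"""Model-implied moments and their derivatives.

For matrices (Lambda, nu, Theta, B, Psi, alpha) the implied moments are::

    A     = (I - B)^{-1}
    Sigma = Lambda A Psi A' Lambda' + Theta
    mu    = nu + Lambda A alpha

Both an adjoint (reverse-mode) gradient and forward-mode Jacobians are
provided; the former drives the optimizer, the latter the expected
information used by standard errors and modification indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ParamIndex


class StructuralCycleError(ValueError):
    """(I - B) is singular: the latent regression structure has a cycle."""


@dataclass
class Moments:
    """Implied moments plus the intermediates needed for derivatives."""

    sigma: np.ndarray  # p x p
    mu: np.ndarray  # p
    A: np.ndarray  # (I - B)^{-1}, m x m
    L: np.ndarray  # Lambda @ A, p x m
    M: np.ndarray  # A Psi A' (latent covariance), m x m
    eta_mean: np.ndarray  # A alpha, m
    mats: dict


def implied_moments(index: ParamIndex, group: int, theta: np.ndarray) -> Moments:
    mats = index.matrices(group, theta)
    lam, nu, th = mats["lambda"], mats["nu"], mats["theta"]
    b, psi, alpha = mats["beta"], mats["psi"], mats["alpha"]
    m = b.shape[0]
    imb = np.eye(m) - b
    try:
        A = np.linalg.inv(imb)
    except np.linalg.LinAlgError as exc:
        raise StructuralCycleError("I - B is singular") from exc
    L = lam @ A
    M = A @ psi @ A.T
    eta_mean = A @ alpha
    sigma = L @ psi @ L.T + th
    sigma = 0.5 * (sigma + sigma.T)
    mu = nu + lam @ eta_mean
    return Moments(sigma, mu, A, L, M, eta_mean, mats)


def gradient_from_adjoints(
    index: ParamIndex,
    group: int,
    mom: Moments,
    dF_dsigma: np.ndarray,
    dF_dmu: np.ndarray,
    out: np.ndarray,
) -> None:
    """Accumulate dF/dtheta into ``out`` given dF/dSigma (symmetric) and dF/dmu.

    Off-diagonal symmetric cells receive the doubled contribution because one
    packed parameter controls both (r, c) and (c, r).
    """
    G = dF_dsigma
    h = dF_dmu
    lam = mom.mats["lambda"]
    L, M, A = mom.L, mom.M, mom.A
    gm = index.groups[group]

    need = {m: bool(gm.free_cells[m]) for m in gm.free_cells}

    if need["lambda"]:
        # Sigma = Lambda M Lambda' + Theta ; mu = nu + Lambda (A alpha)
        dlam = 2.0 * G @ lam @ M + np.outer(h, mom.eta_mean)
        for r, c, j in gm.free_cells["lambda"]:
            out[j] += dlam[r, c]
    if need["nu"]:
        for r, _, j in gm.free_cells["nu"]:
            out[j] += h[r]
    if need["theta"]:
        for r, c, j in gm.free_cells["theta"]:
            out[j] += G[r, c] if r == c else 2.0 * G[r, c]
    if need["psi"]:
        dpsi = L.T @ G @ L
        for r, c, j in gm.free_cells["psi"]:
            out[j] += dpsi[r, c] if r == c else 2.0 * dpsi[r, c]
    if need["alpha"]:
        dalpha = L.T @ h
        for r, _, j in gm.free_cells["alpha"]:
            out[j] += dalpha[r]
    if need["beta"]:
        psi = mom.mats["psi"]
        db = 2.0 * L.T @ G @ L @ psi @ A.T + np.outer(L.T @ h, mom.eta_mean)
        for r, c, j in gm.free_cells["beta"]:
            out[j] += db[r, c]


def moment_jacobians(
    index: ParamIndex, group: int, theta: np.ndarray, mom: Moments | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-mode Jacobians (dSigma/dtheta_j, dmu/dtheta_j) for every free j.

    Returns arrays of shape (q, p, p) and (q, p); rows for parameters that do
    not enter this group are zero.
    """
    if mom is None:
        mom = implied_moments(index, group, theta)
    p = mom.sigma.shape[0]
    q = index.n_free
    dsig = np.zeros((q, p, p))
    dmu = np.zeros((q, p))
    lam = mom.mats["lambda"]
    psi = mom.mats["psi"]
    L, M, A, eta_mean = mom.L, mom.M, mom.A, mom.eta_mean
    lamM = lam @ M  # p x m
    MlamT = lamM.T  # m x p
    gm = index.groups[group]

    for r, c, j in gm.free_cells["lambda"]:
        e = np.zeros(p)
        e[r] = 1.0
        v = lamM[:, c]
        dsig[j] += np.outer(e, v) + np.outer(v, e)
        dmu[j, r] += eta_mean[c]
    for r, _, j in gm.free_cells["nu"]:
        dmu[j, r] += 1.0
    for r, c, j in gm.free_cells["theta"]:
        dsig[j, r, c] += 1.0
        if r != c:
            dsig[j, c, r] += 1.0
    for r, c, j in gm.free_cells["psi"]:
        if r == c:
            dsig[j] += np.outer(L[:, r], L[:, r])
        else:
            dsig[j] += np.outer(L[:, r], L[:, c]) + np.outer(L[:, c], L[:, r])
    for r, _, j in gm.free_cells["alpha"]:
        dmu[j] += L[:, r]
    for r, c, j in gm.free_cells["beta"]:
        # dA = A E_rc A ;  dSigma = L E_rc (A Psi A' Lambda') + sym
        w = MlamT[c]  # row c of M Lambda' = (A Psi A' Lambda')[c]
        dsig[j] += np.outer(L[:, r], w) + np.outer(w, L[:, r])
        dmu[j] += eta_mean[c] * L[:, r]
    return dsig, dmu


def expected_information(
    index: ParamIndex, group: int, theta: np.ndarray, mom: Moments | None = None
) -> np.ndarray:
    """Per-observation expected Fisher information of the loglikelihood.

    I_jk = dmu_j' Sigma^{-1} dmu_k + 0.5 tr(Sigma^{-1} dSigma_j Sigma^{-1} dSigma_k)
    """
    if mom is None:
        mom = implied_moments(index, group, theta)
    dsig, dmu = moment_jacobians(index, group, theta, mom)
    siginv = np.linalg.inv(mom.sigma)
    # mean part
    t = dmu @ siginv  # q x p
    info = t @ dmu.T
    # covariance part: 0.5 * tr(W_j W_k) with W_j = Sigma^-1 dSigma_j
    W = np.einsum("pq,jqr->jpr", siginv, dsig)
    info += 0.5 * np.einsum("jpr,krp->jk", W, W)
    return 0.5 * (info + info.T)
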