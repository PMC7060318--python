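"""Omics relationship matrix, REML variance components and BLUP effects.

Model: ``y = C beta + W u + e`` with ``u ~ N(0, I sigma_u^2)``, so
``var(y) = A sigma_o^2 + I sigma_e^2`` where ``A = WW'/m`` (the omics
relationship matrix) and ``sigma_o^2 = m sigma_u^2``. The fraction of
phenotypic variance captured jointly by all probes is
``rho^2 = sigma_o^2 / (sigma_o^2 + sigma_e^2)``, estimated by restricted
maximum likelihood. A binary phenotype is analysed as 0/1 on the observed
scale, exactly as reported by the upstream OSCA-style workflow.

The REML engine is average-information (AI) with an expectation-
maximization (EM) safeguard and parameter clamping at ``1e-6 * var(y)``.
It accepts an arbitrary list of PSD covariance structures, which the
MOMENT scan reuses for its two-component model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .data import (BLUPEffects, CohortDesign, MultiVarianceEstimate,
                   OmicsRelationshipMatrix, StandardizedMethylation,
                   VarianceEstimate)


def compute_orm(W: StandardizedMethylation) -> OmicsRelationshipMatrix:
    """A = WW'/m. With population-variance standardization the diagonal
    averages exactly 1."""
    if W.n_probes == 0:
        raise ValueError("cannot build an ORM from zero probes")
    V = W.values
    A = (V @ V.T) / W.n_probes
    A = (A + A.T) / 2.0
    return OmicsRelationshipMatrix(A=A, m=W.n_probes, sample_ids=W.sample_ids)


class REMLError(RuntimeError):
    def __init__(self, message: str, history: list):
        super().__init__(message)
        self.history = history


def _restricted_loglik(y, X, V):
    n, p = X.shape
    c, low = sla.cho_factor(V, lower=True)
    logdetV = 2.0 * np.log(np.diag(c)).sum()
    Vi_y = sla.cho_solve((c, low), y)
    Vi_X = sla.cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    beta = np.linalg.solve(XtViX, Vi_X.T @ y)
    yPy = y @ Vi_y - (Vi_X.T @ y) @ beta
    return -0.5 * (logdetV + logdetX + yPy)


def reml(y: np.ndarray, X: np.ndarray, components: list[np.ndarray], *,
         init: np.ndarray | None = None, max_iter: int = 100,
         tol: float = 1e-8, method: str = "ai") -> MultiVarianceEstimate:
    """REML over ``V = sum_k sigma_k^2 G_k`` (append an identity for the
    residual). ``method`` is "ai" (AI updates with EM first step and EM
    fallback) or "em" (pure EM, monotone in the restricted likelihood)."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    k = len(components)
    if n < p + 2:
        raise ValueError("need n >= p + 2 samples for REML")
    vary = y.var(ddof=1)
    floor = 1e-6 * vary
    sig = (np.full(k, vary / k) if init is None
           else np.asarray(init, dtype=float).copy())
    history: list[dict] = []
    clamped = False
    ll_prev = -np.inf
    AI = np.eye(k)
    for it in range(max_iter):
        V = sum(s * G for s, G in zip(sig, components))
        try:
            c, low = sla.cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            raise REMLError("covariance matrix not positive definite", history)
        Vi = sla.cho_solve((c, low), np.eye(n))
        logdetV = 2.0 * np.log(np.diag(c)).sum()
        ViX = Vi @ X
        XtViX = X.T @ ViX
        XtViX_inv = np.linalg.inv(XtViX)
        Viy = Vi @ y
        beta = XtViX_inv @ (ViX.T @ y)
        Py = Viy - ViX @ beta

        def P_times(M):  # P @ M without forming P
            return Vi @ M - ViX @ (XtViX_inv @ (ViX.T @ M))

        sign, logdetX = np.linalg.slogdet(XtViX)
        ll = -0.5 * (logdetV + logdetX + y @ Py)
        history.append({"iter": it, "loglik": ll, "sigmas": sig.copy()})
        if it > 0 and abs(ll - ll_prev) < tol:
            break
        ll_prev = ll

        GPy = [G @ Py for G in components]
        trPG = []
        for G in components:
            ViG = Vi @ G
            tr = np.trace(ViG) - np.einsum("ij,ji->", XtViX_inv, ViX.T @ (G @ ViX))
            trPG.append(tr)
        yPGPy = np.array([Py @ g for g in GPy])
        score = -0.5 * (np.array(trPG) - yPGPy)

        PGPy = [P_times(g) for g in GPy]
        AI = 0.5 * np.array([[GPy[i] @ PGPy[j] for j in range(k)] for i in range(k)])
        AI = (AI + AI.T) / 2.0

        def clamp(v):
            nonlocal clamped
            if np.any(v < floor):
                clamped = True
                v = np.maximum(v, floor)
            return v

        def try_ll(v):
            try:
                return _restricted_loglik(y, X, sum(s * G for s, G in zip(v, components)))
            except (np.linalg.LinAlgError, ValueError):
                return -np.inf

        em_step = clamp(sig + sig**2 * (yPGPy - np.array(trPG)) / n)
        if method == "em" or it == 0:
            sig = em_step
            continue
        # AI step over the free parameters only: components pinned at the
        # floor with a negative gradient would otherwise distort the solve
        free = ~((sig <= floor * (1 + 1e-8)) & (score <= 0))
        step = np.zeros(k)
        if free.any():
            try:
                step[free] = np.linalg.solve(AI[np.ix_(free, free)], score[free])
            except np.linalg.LinAlgError:
                step[:] = np.nan
        if not np.all(np.isfinite(step)):
            sig = em_step
            continue
        # cap the step so no component overshoots past the boundary (keep
        # 70% of the distance at most), then halve while likelihood is lost
        neg = step < 0
        t = 1.0
        if neg.any():
            t = min(1.0, float(0.7 * np.min((sig[neg] - floor) /
                                            np.maximum(-step[neg], 1e-300))))
        new = clamp(sig + t * step)
        for _ in range(8):
            if try_ll(new) >= ll - 1e-10:
                break
            new = clamp(sig + 0.5 * (new - sig))
        else:
            new = em_step
        sig = new
    else:
        raise REMLError(f"REML did not converge in {max_iter} iterations", history)

    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return MultiVarianceEstimate(sigmas=sig, cov_sigmas=cov, loglik=ll,
                                 n_iter=it + 1, converged=True,
                                 clamped=clamped, history=history)


def reml_fit(design: CohortDesign, A: OmicsRelationshipMatrix, *,
             max_iter: int = 100, tol: float = 1e-8,
             method: str = "ai", lrt: bool = True) -> VarianceEstimate:
    """OREML: estimate sigma_o^2, sigma_e^2 and rho^2 with SEs (delta method
    from the AI-matrix inverse) plus a 0.5*chi2_0 + 0.5*chi2_1 mixture LRT
    against sigma_o^2 = 0 (our convention for the test of rho^2)."""
    y = design.y
    X = design.design_matrix()
    n = len(y)
    fit = reml(y, X, [A.A, np.eye(n)], max_iter=max_iter, tol=tol, method=method)
    so, se_comp = fit.sigmas
    # variance attributed to the probes is sigma_o * mean(diag A) (= sigma_o
    # under this repo's standardization); keeps rho2 scale-free in W
    dbar = float(np.mean(np.diag(A.A)))
    tot = so * dbar + se_comp
    rho2 = so * dbar / tot
    g = np.array([dbar * se_comp, -so * dbar]) / tot**2
    var_rho2 = float(g @ fit.cov_sigmas @ g)
    p_rho2 = None
    if lrt:
        null = reml(y, X, [np.eye(n)], max_iter=max_iter, tol=tol)
        stat = max(0.0, 2.0 * (fit.loglik - null.loglik))
        p_rho2 = 0.5 * stats.chi2.sf(stat, 1) if stat > 0 else 1.0
    return VarianceEstimate(
        sigma_o=float(so), sigma_e=float(se_comp), rho2=float(rho2),
        se_sigma_o=float(np.sqrt(max(fit.cov_sigmas[0, 0], 0.0))),
        se_sigma_e=float(np.sqrt(max(fit.cov_sigmas[1, 1], 0.0))),
        se_rho2=float(np.sqrt(max(var_rho2, 0.0))),
        loglik=fit.loglik, n_iter=fit.n_iter, converged=fit.converged,
        clamped=fit.clamped, p_rho2=p_rho2, history=fit.history)


def blup_probe_effects(design: CohortDesign, W: StandardizedMethylation,
                       var: VarianceEstimate) -> BLUPEffects:
    """u_hat = (sigma_o^2/m) W' V^-1 (y - C beta_hat) with beta_hat the GLS
    fixed effects under V = A sigma_o^2 + I sigma_e^2."""
    if not var.converged:
        raise ValueError("variance components did not converge; refusing BLUP")
    assert var.sigma_e > 0, "V is singular only if sigma_e = 0"
    y = design.y
    X = design.design_matrix()
    n, m = W.values.shape
    A = (W.values @ W.values.T) / m
    V = var.sigma_o * A + var.sigma_e * np.eye(n)
    c, low = sla.cho_factor(V, lower=True)
    ViX = sla.cho_solve((c, low), X)
    beta = np.linalg.solve(X.T @ ViX, ViX.T @ y)
    resid = y - X @ beta
    Vir = sla.cho_solve((c, low), resid)
    u = (var.sigma_o / m) * (W.values.T @ Vir)
    return BLUPEffects(u=pd.Series(u, index=W.probe_ids),
                       sigma_o=var.sigma_o, sigma_e=var.sigma_e,
                       probe_means=pd.Series(W.means, index=W.probe_ids),
                       probe_sds=pd.Series(W.sds, index=W.probe_ids))
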