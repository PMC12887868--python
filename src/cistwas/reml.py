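"""Restricted-maximum-likelihood machinery for single-GRM mixed models.

All models here are of the form

    y = 1*mu + g + e,   g ~ N(0, G * Vg),   e ~ N(0, I * Ve)

with an intercept as the only fixed effect.  Working in the eigenbasis of G
makes every likelihood, gradient and average-information evaluation O(n),
so the iterative fits cost one symmetric eigendecomposition each.

Two fitting strategies are provided:

* :func:`ai_reml` — average-information updates with an EM first step and EM
  fallback whenever AI proposes an out-of-bounds move; used for the per-gene
  cis variance components, where Vg is frequently at its boundary.
* :func:`profile_reml_ratio` — 1-D profiled REML over the variance ratio
  delta = Vg/Ve on a log grid plus Brent refinement; used for the per-trait
  association null model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["EigenGRM", "REMLFit", "ai_reml", "profile_reml_ratio", "restricted_loglik_null"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class EigenGRM:
    """Eigendecomposition of a GRM with the response/intercept pre-rotated."""

    s: np.ndarray       # eigenvalues of G, ascending, clipped at 0
    U: np.ndarray       # eigenvectors, columns
    y_rot: np.ndarray   # U' y
    one_rot: np.ndarray  # U' 1

    @classmethod
    def build(cls, G: np.ndarray, y: np.ndarray) -> "EigenGRM":
        G = np.asarray(G, dtype=float)
        y = np.asarray(y, dtype=float)
        s, U = np.linalg.eigh((G + G.T) / 2.0)
        s = np.clip(s, 0.0, None)
        return cls(s=s, U=U, y_rot=U.T @ y, one_rot=U.T @ np.ones(len(y)))

    @property
    def n(self) -> int:
        return len(self.s)


@dataclass
class REMLFit:
    Vg: float
    Ve: float
    loglik: float
    loglik_null: float
    converged: bool
    n_iter: int


def _loglik_parts(eig: EigenGRM, Vg: float, Ve: float):
    """Restricted log-likelihood and reusable intermediates at (Vg, Ve)."""
    d = Vg * eig.s + Ve
    u, yv = eig.one_rot, eig.y_rot
    C = float(np.sum(u * u / d))                       # 1' V^-1 1
    beta = float(np.sum(u * yv / d)) / C               # GLS intercept
    r = yv - beta * u
    ypy = float(np.sum(r * r / d))
    ll = -0.5 * ((eig.n - 1) * _LOG2PI + float(np.sum(np.log(d))) + np.log(C) + ypy)
    return ll, d, C, beta, r


def restricted_loglik(eig: EigenGRM, Vg: float, Ve: float) -> float:
    return _loglik_parts(eig, Vg, Ve)[0]


def restricted_loglik_null(eig: EigenGRM) -> float:
    """Restricted log-likelihood maximized over Ve with Vg fixed at 0."""
    n = eig.n
    # With V = Ve*I the GLS intercept is the sample mean and y'Py = RSS/Ve.
    u, yv = eig.one_rot, eig.y_rot
    beta = float(np.sum(u * yv)) / n
    rss = float(np.sum((yv - beta * u) ** 2))
    if rss <= 0:
        raise ValueError("response has zero variance")
    ve = rss / (n - 1)
    return -0.5 * ((n - 1) * _LOG2PI + n * np.log(ve) + np.log(n / ve) + (n - 1))


def _score_ai(eig: EigenGRM, d, C, r):
    """REML score vector and average-information matrix for (Vg, Ve).

    dV/dVg = diag(s) in the eigenbasis; dV/dVe = I.
    """
    s, u = eig.s, eig.one_rot
    py = r / d                      # rotated P y
    uinv = u / d
    # tr(P A) = sum(a/d) - (u' D^-1 A D^-1 u)/C  for diagonal A
    tr_pg = float(np.sum(s / d)) - float(np.sum(uinv * s * uinv)) / C
    tr_pe = float(np.sum(1.0 / d)) - float(np.sum(uinv * uinv)) / C
    ypgpy = float(np.sum(s * py * py))
    ypepy = float(np.sum(py * py))
    score = np.array([-0.5 * (tr_pg - ypgpy), -0.5 * (tr_pe - ypepy)])

    def P(v):
        return v / d - uinv * (float(np.sum(uinv * v)) / C)

    pgpy = P(s * py)
    pepy = P(py)
    ai = 0.5 * np.array([
        [float(np.sum(s * py * pgpy)), float(np.sum(s * py * pepy))],
        [float(np.sum(py * pgpy)), float(np.sum(py * pepy))],
    ])
    return score, ai, ypgpy, ypepy, tr_pg, tr_pe


def ai_reml(eig: EigenGRM, max_iter: int = 100, tol: float = 1e-8,
            floor_frac: float = 1e-6) -> REMLFit:
    """Fit (Vg, Ve) by AI-REML with EM fallback steps.

    Estimates are floored at ``floor_frac * var(y)`` rather than zero so the
    downstream BLUP system stays non-singular.  Convergence is declared when
    the restricted log-likelihood moves by less than ``tol``.
    """
    n = eig.n
    # sample variance of y (rotation preserves norms; mean via intercept projection)
    beta0 = float(np.sum(eig.one_rot * eig.y_rot)) / n
    y_var = float(np.sum((eig.y_rot - beta0 * eig.one_rot) ** 2)) / (n - 1)
    if y_var <= 0:
        raise ValueError("response has zero variance")
    floor = floor_frac * y_var

    theta = np.array([0.5 * y_var, 0.5 * y_var])
    ll, d, C, _, r = _loglik_parts(eig, *theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, ai, ypgpy, ypepy, tr_pg, tr_pe = _score_ai(eig, d, C, r)
        em = theta + (theta ** 2 / n) * np.array([ypgpy - tr_pg, ypepy - tr_pe])
        if it == 1:
            proposal = em
        else:
            try:
                # out-of-bounds AI components are clamped to the floor rather
                # than discarded; a failed solve falls back to EM
                proposal = np.maximum(theta + np.linalg.solve(ai, score), floor)
            except np.linalg.LinAlgError:
                proposal = em
        proposal = np.maximum(proposal, floor)
        new_ll, new_d, new_C, _, new_r = _loglik_parts(eig, *proposal)
        # step-halve toward the current iterate if the proposal loses
        # likelihood; fall back to EM if halving does not rescue it
        halvings = 0
        while new_ll < ll - 1e-10 and halvings < 10:
            proposal = np.maximum(theta + 0.5 * (proposal - theta), floor)
            new_ll, new_d, new_C, _, new_r = _loglik_parts(eig, *proposal)
            halvings += 1
        if new_ll < ll - 1e-10:
            proposal = np.maximum(em, floor)
            new_ll, new_d, new_C, _, new_r = _loglik_parts(eig, *proposal)
        delta_ll = new_ll - ll
        theta, ll, d, C, r = proposal, new_ll, new_d, new_C, new_r
        if abs(delta_ll) < tol:
            converged = True
            break

    ll_null = restricted_loglik_null(eig)
    ll = max(ll, ll_null)  # floored Vg can sit epsilon below the exact null
    return REMLFit(Vg=float(theta[0]), Ve=float(theta[1]), loglik=ll,
                   loglik_null=ll_null, converged=converged, n_iter=it)


def profile_reml_ratio(eig: EigenGRM, log_delta_bounds: tuple[float, float] = (-8.0, 8.0),
                       n_grid: int = 40) -> tuple[float, float, float]:
    """Profiled REML over delta = Vg/Ve; returns (Vg, Ve, loglik).

    For a given delta the scaled covariance is D = delta*s + 1 and the
    profiled residual variance has the closed form Ve = y'Py / (n - 1).
    The profile likelihood is scanned on a log-delta grid (including the
    delta = 0 boundary) and refined with bounded Brent minimization.
    """
    n = eig.n
    u, yv, s = eig.one_rot, eig.y_rot, eig.s

    def neg_profile(log_delta: float) -> float:
        delta = np.exp(log_delta)
        h = delta * s + 1.0
        C = float(np.sum(u * u / h))
        beta = float(np.sum(u * yv / h)) / C
        r = yv - beta * u
        ypy = float(np.sum(r * r / h))
        ve = ypy / (n - 1)
        if ve <= 0:
            return np.inf
        ll = -0.5 * ((n - 1) * _LOG2PI + (n - 1) * np.log(ve)
                     + float(np.sum(np.log(h))) + np.log(C) - np.log(ve) + (n - 1))
        return -ll

    lo, hi = log_delta_bounds
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([neg_profile(g) for g in grid])
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, n_grid - 1)]
    res = optimize.minimize_scalar(neg_profile, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-8})
    best_ll = -res.fun
    best_delta = float(np.exp(res.x))

    ll_boundary = restricted_loglik_null(eig)
    if ll_boundary >= best_ll:
        beta = float(np.sum(u * yv)) / n
        ve = float(np.sum((yv - beta * u) ** 2)) / (n - 1)
        return 0.0, ve, ll_boundary

    h = best_delta * s + 1.0
    C = float(np.sum(u * u / h))
    beta = float(np.sum(u * yv / h)) / C
    r = yv - beta * u
    ve = float(np.sum(r * r / h)) / (n - 1)
    return best_delta * ve, ve, best_ll
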