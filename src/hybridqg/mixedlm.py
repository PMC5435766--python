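"""Restricted maximum likelihood machinery shared by the scanning,
variance-decomposition and prediction modules.

Two solvers:

* :func:`spectral_reml` — single random effect plus residual, profiled over
  the variance ratio via one eigendecomposition (the EMMA device).  Used by
  the genome scans, where thousands of fixed-effect models share one null
  covariance.
* :func:`ai_reml` — arbitrary list of covariance components, average-
  information updates with a monotone fixed-point fallback and non-negativity
  projection.  Used for multi-kernel GBLUP and the combining-ability model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .core import DataError

RIDGE = 1e-6


# ---------------------------------------------------------------------------
# Spectral (single-kernel) REML
# ---------------------------------------------------------------------------


@dataclass
class SpectralNull:
    """Null-model fit y = X beta + u + e with u ~ N(0, K s2u), e ~ N(0, I s2e).

    Stores the eigendecomposition so fixed-effect models can be refit in
    O(n p^2) per marker (the P3D shortcut).
    """

    eigvals: np.ndarray  # eigenvalues of K (length n)
    U: np.ndarray  # eigenvectors, columns
    lam: float  # s2u / s2e at the REML optimum
    sigma2_u: float
    sigma2_e: float
    loglik: float
    y_rot: np.ndarray
    X_rot: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        return self.lam * self.eigvals + 1.0

    def whiten(self, M: np.ndarray) -> np.ndarray:
        """Rotate columns into the eigenbasis and scale to unit error variance."""
        R = self.U.T @ M
        w = np.sqrt(self.weights)
        return R / w[:, None] if R.ndim > 1 else R / w


def _reml_loglik_profile(lam: float, eigvals: np.ndarray, y_rot: np.ndarray, X_rot: np.ndarray) -> tuple:
    """Profiled REML log-likelihood at variance ratio lam, plus GLS pieces."""
    w = lam * eigvals + 1.0
    Xw = X_rot / w[:, None]
    XtWX = X_rot.T @ Xw
    XtWy = Xw.T @ y_rot
    beta = np.linalg.solve(XtWX, XtWy)
    resid = y_rot - X_rot @ beta
    rss = float(resid @ (resid / w))
    n, p = X_rot.shape
    df = n - p
    sigma2_e = rss / df
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    _, logdet_xx = np.linalg.slogdet(X_rot.T @ X_rot)
    ll = -0.5 * (
        df * np.log(2.0 * np.pi * sigma2_e)
        + df
        + float(np.sum(np.log(w)))
        + logdet_xwx
        - logdet_xx
    )
    return ll, beta, sigma2_e, XtWX


def spectral_reml(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | None = None,
    eig: tuple | None = None,
    lam_bounds: tuple = (1e-6, 1e6),
) -> SpectralNull:
    """REML for one kernel + residual via eigendecomposition of K.

    ``eig=(eigvals, U)`` may be supplied to reuse a decomposition.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if eig is None:
        if K is None:
            raise DataError("either K or its eigendecomposition is required")
        Ks = (K + K.T) / 2.0
        eigvals, U = np.linalg.eigh(Ks)
        eigvals = np.maximum(eigvals, 0.0)
    else:
        eigvals, U = eig
    y_rot = U.T @ y
    X_rot = U.T @ X

    def neg_ll(log_lam: float) -> float:
        return -_reml_loglik_profile(np.exp(log_lam), eigvals, y_rot, X_rot)[0]

    if lam_bounds[0] == lam_bounds[1]:
        lam = float(lam_bounds[0])
    else:
        grid = np.linspace(np.log(lam_bounds[0]), np.log(lam_bounds[1]), 41)
        vals = [neg_ll(g) for g in grid]
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-10})
        lam = float(np.exp(res.x))
    # boundary: compare to (numerically) zero genetic variance
    ll_best, beta, sigma2_e, _ = _reml_loglik_profile(lam, eigvals, y_rot, X_rot)
    ll_zero = _reml_loglik_profile(lam_bounds[0], eigvals, y_rot, X_rot)[0]
    if ll_zero >= ll_best:
        lam, ll_best = lam_bounds[0], ll_zero
        _, beta, sigma2_e, _ = _reml_loglik_profile(lam, eigvals, y_rot, X_rot)
    return SpectralNull(
        eigvals=eigvals,
        U=U,
        lam=lam,
        sigma2_u=lam * sigma2_e,
        sigma2_e=sigma2_e,
        loglik=float(ll_best),
        y_rot=y_rot,
        X_rot=X_rot,
    )


def wald_fixed_effects(
    y_white: np.ndarray, X_white: np.ndarray
) -> tuple:
    """OLS on whitened data; per-coefficient Wald t-tests.

    Returns (beta, se, p, df, rank).  Rank-deficient designs are solved by
    least squares; aliased coefficients get se = inf, p = 1.
    """
    n, p = X_white.shape
    beta, _, rank, sv = np.linalg.lstsq(X_white, y_white, rcond=None)
    resid = y_white - X_white @ beta
    df = n - rank
    if df <= 0:
        raise DataError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    XtX = X_white.T @ X_white
    try:
        cov = np.linalg.inv(XtX) * sigma2
        var = np.diag(cov).copy()
    except np.linalg.LinAlgError:
        var = np.diag(np.linalg.pinv(XtX)) * sigma2
    var = np.where(var <= 0, np.inf, var)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.where(np.isfinite(t), pvals, 1.0)
    return beta, se, pvals, df, rank


# ---------------------------------------------------------------------------
# Multi-component AI-REML
# ---------------------------------------------------------------------------


@dataclass
class RemlFit:
    variances: np.ndarray  # one per component (+ residual if free)
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    Py: np.ndarray
    Vinv: np.ndarray
    X: np.ndarray

    def blup(self, K: np.ndarray, sigma2: float) -> np.ndarray:
        return sigma2 * (K @ self.Py)


def _reml_loglik(y, X, V):
    """Restricted log-likelihood only (no explicit inverse)."""
    n, p = X.shape
    cf = linalg.cho_factor(V, lower=True)
    Viy = linalg.cho_solve(cf, y)
    ViX = linalg.cho_solve(cf, X)
    XtViX = X.T @ ViX
    cx = linalg.cho_factor(XtViX)
    beta = linalg.cho_solve(cx, X.T @ Viy)
    Py = Viy - ViX @ beta
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    logdetXViX = 2.0 * float(np.sum(np.log(np.diag(cx[0]))))
    ll = -0.5 * (logdetV + logdetXViX + float(y @ Py) + (n - p) * np.log(2.0 * np.pi))
    return ll, beta, Py, cf


def _reml_pieces(y, X, V):
    n, p = X.shape
    ll, beta, Py, cf = _reml_loglik(y, X, V)
    Vinv = linalg.cho_solve(cf, np.eye(n))
    return ll, beta, Py, Vinv, None


def ai_reml(
    y: np.ndarray,
    X: np.ndarray,
    Ks: Sequence[np.ndarray],
    R0: np.ndarray | None = None,
    include_residual: bool = True,
    max_iter: int = 200,
    tol: float = 1e-8,
    start: np.ndarray | None = None,
    min_var_frac: float = 1e-8,
) -> RemlFit:
    """Average-information REML for V = R0 + sum_k theta_k K_k (+ theta_e I).

    Components are projected to >= a small floor relative to var(y); the AI
    step falls back to a monotone multiplicative update whenever it fails to
    improve the restricted likelihood.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n = len(y)
    if n < 2:
        raise DataError("fewer than 2 observations")
    comps = [np.asarray(K, dtype=float) for K in Ks]
    if include_residual:
        comps = comps + [np.eye(n)]
    q = len(comps)
    vy = float(np.var(y))
    if vy == 0:
        # degenerate: constant response
        theta = np.zeros(q)
        V = (R0 if R0 is not None else 0.0) + np.eye(n) * max(vy, 1.0) * 1e-12 + np.eye(n) * RIDGE
        ll, beta, Py, Vinv, _ = _reml_pieces(y, X, V)
        return RemlFit(theta, beta, ll, True, 0, Py * 0.0, Vinv, X)
    floor = vy * min_var_frac
    mean_diag = np.array([max(np.mean(np.diag(K)), 1e-12) for K in comps])
    theta = np.full(q, vy / q) / mean_diag if start is None else np.asarray(start, dtype=float).copy()

    def build_V(th):
        V = np.zeros((n, n)) if R0 is None else R0.copy()
        for k in range(q):
            if th[k] > 0:
                V += th[k] * comps[k]
        V[np.diag_indices(n)] += RIDGE * vy
        return V

    ll, beta, Py, cf = _reml_loglik(y, X, build_V(theta))
    converged = False
    it = 0
    stall = 0
    for it in range(1, max_iter + 1):
        Vinv = linalg.cho_solve(cf, np.eye(n))
        ViX = Vinv @ X
        P = Vinv - ViX @ np.linalg.solve(X.T @ ViX, ViX.T)
        KPy = [comps[k] @ Py for k in range(q)]
        trPK = np.array([float(np.sum(P * comps[k])) for k in range(q)])
        yPKPy = np.array([float(Py @ KPy[k]) for k in range(q)])
        score = -0.5 * (trPK - yPKPy)
        AI = np.empty((q, q))
        PKPy = [P @ KPy[k] for k in range(q)]
        for a in range(q):
            for b in range(a, q):
                AI[a, b] = AI[b, a] = 0.5 * float(KPy[a] @ PKPy[b])
        try:
            delta = np.linalg.solve(AI + np.eye(q) * 1e-10, score)
        except np.linalg.LinAlgError:
            delta = score / np.maximum(np.diag(AI), 1e-10)
        accepted = False
        step = 1.0
        dll = 0.0
        for _ in range(8):
            cand = np.maximum(theta + step * delta, 0.0)
            cand[cand < floor] = 0.0
            if np.array_equal(cand, theta):
                break
            try:
                ll_new, beta_new, Py_new, cf_new = _reml_loglik(y, X, build_V(cand))
            except np.linalg.LinAlgError:
                step /= 2.0
                continue
            if ll_new >= ll - 1e-12:
                dll = ll_new - ll
                theta, beta, Py, cf, ll = cand, beta_new, Py_new, cf_new, ll_new
                accepted = True
                break
            step /= 2.0
        if not accepted:
            # monotone fixed-point fallback: theta <- theta * sqrt(yPKPy / trPK)
            cand = theta.copy()
            for k in range(q):
                if trPK[k] > 0 and theta[k] > 0:
                    cand[k] = theta[k] * np.sqrt(max(yPKPy[k], 0.0) / trPK[k])
            cand = np.maximum(cand, 0.0)
            cand[cand < floor] = 0.0
            if not np.array_equal(cand, theta):
                try:
                    ll_new, beta_new, Py_new, cf_new = _reml_loglik(y, X, build_V(cand))
                    if ll_new >= ll - 1e-10:
                        dll = ll_new - ll
                        theta, beta, Py, cf, ll = cand, beta_new, Py_new, cf_new, ll_new
                except np.linalg.LinAlgError:
                    pass
        if abs(dll) < tol * max(1.0, abs(ll)):
            converged = True
            break
        # updates deterministically rejected in consecutive rounds: fixed point
        stall = stall + 1 if dll == 0.0 else 0
        if stall >= 2:
            converged = True
            break
    Vinv = linalg.cho_solve(cf, np.eye(n))
    return RemlFit(theta, beta, float(ll), converged, it, Py, Vinv, X)


def lrt_variance_component(ll_full: float, ll_reduced: float) -> float:
    """P-value of the likelihood-ratio test for one variance component on the
    boundary: 0.5 chi2_0 + 0.5 chi2_1 mixture."""
    lr = max(0.0, 2.0 * (ll_full - ll_reduced))
    if lr == 0.0:
        return 1.0
    return 0.5 * float(stats.chi2.sf(lr, 1))
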