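"""Restricted maximum likelihood for grouped random-intercept models.

The mixed model fitted here is

    y = X beta + Z b + e,   b_g ~ N(0, g_{class(g)}),   e ~ N(0, sigma^2 I)

where ``Z`` assigns every observation to exactly one group (in the distance
regression: the dyad-by-task of the row) and groups share variance
parameters by *class* (the task).  Because the groups partition the rows,
the marginal covariance ``V = sigma^2 I + Z G Z'`` is block
compound-symmetric, and both ``V^{-1}`` and ``log|V|`` have closed forms per
group.  All the per-iteration linear algebra therefore reduces to a few
dense ``p x p`` matrices precomputed once from the (sparse) design, which is
what lets the fit scale to hundreds of thousands of rows and tens of
thousands of random effects.

With a single residual variance the criterion is profiled over ``sigma^2``
and optimized over log variance ratios; with task-specific residual
variances (an option) all log-parameters are optimized jointly.  Inference
on fixed effects uses Satterthwaite's degrees-of-freedom approximation:

    df = 2 (l' C l)^2 / (d' W d)

with ``C`` the fixed-effect covariance at the REML optimum, ``d`` the
gradient of ``l' C(theta) l`` in the variance parameters (central finite
differences), and ``W`` the inverse observed REML information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

__all__ = ["RemlFit", "fit_grouped_reml"]

#: lower floor for variance ratios on the log scale (effectively zero)
LOG_RATIO_MIN = np.log(1e-8)
LOG_RATIO_MAX = np.log(1e8)
#: relative convergence tolerance of the bounded quasi-Newton optimizer
REML_TOL = 1e-8
MAX_ITER = 500


@dataclass
class RemlFit:
    """Result of a grouped-random-intercept REML fit."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: np.ndarray          # residual variance(s), one per residual class
    g: np.ndarray               # random-intercept variance per class
    loglik: float               # REML log-likelihood (lme4 convention)
    converged: bool
    n_iter: int
    n_obs: int
    rank: int
    boundary: np.ndarray        # per class: variance ratio pinned at the floor
    theta: np.ndarray           # (g_1..g_B, sigma2_1..sigma2_R)
    theta_cov: np.ndarray       # inverse observed REML information
    history: list = field(default_factory=list, repr=False)
    _core: "_RemlCore | None" = field(default=None, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    @property
    def resid_df(self) -> int:
        return self.n_obs - self.rank

    def satterthwaite_df(self, L: np.ndarray) -> np.ndarray:
        """Satterthwaite df for each contrast row of ``L`` (k x p)."""
        L = np.atleast_2d(np.asarray(L, dtype=float))
        core = self._core
        f0 = core.contrast_var(self.theta, L)
        grads = np.zeros((L.shape[0], self.theta.size))
        for i in range(self.theta.size):
            h = 1e-5 * (1.0 + abs(self.theta[i]))
            tp = self.theta.copy(); tp[i] += h
            tm = self.theta.copy(); tm[i] -= h
            grads[:, i] = (core.contrast_var(tp, L) - core.contrast_var(tm, L)) / (2 * h)
        denom = np.einsum("ki,ij,kj->k", grads, self.theta_cov, grads)
        df = np.full(L.shape[0], float(self.resid_df))
        ok = denom > 0
        df[ok] = 2.0 * f0[ok] ** 2 / denom[ok]
        return np.minimum(np.maximum(df, 1.0), float(self.resid_df))


class _RemlCore:
    """Precomputed sufficient statistics and the REML criterion."""

    def __init__(self, X, y, groups, group_class, residual_class, n_classes, n_resid):
        y = np.asarray(y, dtype=float)
        n = y.size
        X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
        p = X.shape[1]
        groups = np.asarray(groups)
        if groups.shape[0] != n:
            raise ValueError("groups must have one entry per observation")
        q = int(groups.max()) + 1 if n else 0
        group_class = np.asarray(group_class, dtype=int)
        if residual_class is None:
            residual_class = np.zeros(n, dtype=int)
            n_resid = 1
        residual_class = np.asarray(residual_class, dtype=int)

        # group sizes and per-group residual class (constant within a group)
        m_g = np.bincount(groups, minlength=q)
        if np.any(m_g == 0):
            raise ValueError("empty random-effect group")
        rc_g = np.zeros(q, dtype=int)
        rc_g[groups] = residual_class

        Z = sp.csr_matrix(
            (np.ones(n), (np.arange(n), groups)), shape=(n, q)
        )
        A = np.asarray((Z.T @ X).todense()).T  # p x q: column sums of X per group
        Zty = np.asarray(Z.T @ y).ravel()

        # per residual class Gram pieces
        self.XtX_r, self.Xty_r, self.yty_r, self.nrows_r = [], [], [], []
        for r in range(n_resid):
            rows = residual_class == r
            Xr = X[rows]
            self.XtX_r.append(np.asarray((Xr.T @ Xr).todense()))
            self.Xty_r.append(np.asarray(Xr.T @ y[rows]).ravel())
            self.yty_r.append(float(y[rows] @ y[rows]))
            self.nrows_r.append(int(rows.sum()))

        # blocks of groups sharing (variance class, residual class, size)
        self.blocks = []
        keys = {}
        for gi in range(q):
            keys.setdefault((group_class[gi], rc_g[gi], m_g[gi]), []).append(gi)
        for (vc, rc, m), gids in sorted(keys.items()):
            Ab = A[:, gids]
            zb = Zty[gids]
            self.blocks.append(
                dict(
                    vc=int(vc), rc=int(rc), m=int(m), q=len(gids),
                    M=Ab @ Ab.T, v=Ab @ zb, s=float(zb @ zb),
                )
            )
        self.n, self.p, self.q = n, p, q
        self.n_classes, self.n_resid = n_classes, n_resid

    # -- criterion ---------------------------------------------------------

    def _assemble(self, g, s2):
        p = self.p
        S = np.zeros((p, p))
        u = np.zeros(p)
        yVy = 0.0
        logdetV = 0.0
        for r in range(self.n_resid):
            inv = 1.0 / s2[r]
            S += inv * self.XtX_r[r]
            u += inv * self.Xty_r[r]
            yVy += inv * self.yty_r[r]
        for b in self.blocks:
            denom = s2[b["rc"]] + b["m"] * g[b["vc"]]
            c = g[b["vc"]] / denom / s2[b["rc"]]
            S -= c * b["M"]
            u -= c * b["v"]
            yVy -= c * b["s"]
            logdetV += b["q"] * ((b["m"] - 1) * np.log(s2[b["rc"]]) + np.log(denom))
        return S, u, yVy, logdetV

    def neg2ll(self, theta):
        """-2 REML log-likelihood at theta = (g_1..g_B, s2_1..s2_R)."""
        g = theta[: self.n_classes]
        s2 = theta[self.n_classes:]
        S, u, yVy, logdetV = self._assemble(g, s2)
        try:
            cf = cho_factor(S, lower=True)
        except np.linalg.LinAlgError:
            return 1e12  # numerically infeasible corner of the parameter space
        beta = cho_solve(cf, u)
        yPy = yVy - u @ beta
        logdetS = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return (
            logdetV + logdetS + yPy + (self.n - self.p) * np.log(2 * np.pi)
        )

    def profiled_neg2ll(self, rho):
        """Criterion profiled over a single shared residual variance.

        ``rho`` are log variance ratios lambda_b = g_b / sigma^2.
        Returns (value, sigma2_hat)."""
        lam = np.exp(rho)
        p, n = self.p, self.n
        S = self.XtX_r[0].copy()
        u = self.Xty_r[0].copy()
        quad = self.yty_r[0]
        logdetV0 = 0.0
        for b in self.blocks:
            c = lam[b["vc"]] / (1.0 + b["m"] * lam[b["vc"]])
            S -= c * b["M"]
            u -= c * b["v"]
            quad -= c * b["s"]
            logdetV0 += b["q"] * np.log(1.0 + b["m"] * lam[b["vc"]])
        cf = cho_factor(S, lower=True)
        beta = cho_solve(cf, u)
        r2 = quad - u @ beta
        sigma2 = r2 / (n - p)
        logdetS = 2.0 * np.sum(np.log(np.diag(cf[0])))
        val = (n - p) * np.log(sigma2) + logdetV0 + logdetS + (n - p)
        return val, sigma2

    def solve_beta(self, theta):
        g = theta[: self.n_classes]
        s2 = theta[self.n_classes:]
        S, u, _, _ = self._assemble(g, s2)
        cf = cho_factor(S, lower=True)
        beta = cho_solve(cf, u)
        cov = cho_solve(cf, np.eye(self.p))
        return beta, 0.5 * (cov + cov.T)

    def contrast_var(self, theta, L):
        g = theta[: self.n_classes]
        s2 = theta[self.n_classes:]
        S, _, _, _ = self._assemble(g, s2)
        cf = cho_factor(S, lower=True)
        sol = cho_solve(cf, L.T)  # p x k
        return np.einsum("kp,pk->k", L, sol)


def _fd_hessian_step(fun, theta, scale):
    k = theta.size
    H = np.zeros((k, k))
    h = scale * (1.0 + np.abs(theta))
    f0 = fun(theta)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (fun(theta + ei) - 2 * f0 + fun(theta - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(theta + ei + ej) - fun(theta + ei - ej)
                - fun(theta - ei + ej) + fun(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _fd_hessian(fun, theta, scale=2e-4):
    """Central-difference Hessian with one Richardson extrapolation step.

    The step balances truncation against round-off in the REML criterion;
    Richardson extrapolation removes the leading O(h^2) truncation term.
    """
    H1 = _fd_hessian_step(fun, theta, scale)
    H2 = _fd_hessian_step(fun, theta, scale / 2.0)
    return (4.0 * H2 - H1) / 3.0


def fit_grouped_reml(
    X,
    y,
    groups,
    group_class,
    n_classes: int,
    *,
    residual_class=None,
    n_residual_classes: int = 1,
    tol: float = REML_TOL,
    max_iter: int = MAX_ITER,
) -> RemlFit:
    """Fit the grouped random-intercept model by REML.

    Parameters
    ----------
    X : (n, p) dense or sparse design of full column rank.
    y : (n,) response.
    groups : (n,) integer group index of each observation (0..q-1).
    group_class : (q,) variance class of each group (0..n_classes-1).
    residual_class : optional (n,) integer residual-variance class per row;
        default is a single shared residual variance.
    """
    core = _RemlCore(
        X, y, groups, group_class, residual_class, n_classes,
        n_residual_classes,
    )
    history: list[float] = []

    if core.n_resid == 1:
        rho0 = np.full(n_classes, np.log(0.1))
        def obj(rho):
            return core.profiled_neg2ll(rho)[0]
        history.append(obj(rho0))
        res = minimize(
            obj, rho0, method="L-BFGS-B",
            bounds=[(LOG_RATIO_MIN, LOG_RATIO_MAX)] * n_classes,
            callback=lambda xk: history.append(obj(xk)),
            options=dict(maxiter=max_iter, ftol=tol, gtol=1e-8),
        )
        if not res.success and "ABNORMAL" in str(res.message).upper():
            raise RuntimeError(f"REML optimizer failed: {res.message}; trace={history}")
        lam = np.exp(res.x)
        _, sigma2 = core.profiled_neg2ll(res.x)
        g = lam * sigma2
        boundary = res.x <= LOG_RATIO_MIN + 1e-6
        g = np.where(boundary, 0.0, g)
        theta = np.concatenate([g, [sigma2]])
        n_iter = int(res.nit)
        converged = bool(res.success) or res.nit < max_iter
    else:
        vary = max(float(np.var(np.asarray(y, dtype=float))), 1e-12)
        x0 = np.log(np.full(n_classes + core.n_resid, 0.5 * vary))
        lo, hi = np.log(vary) - 20.0, np.log(vary) + 20.0
        def obj(logtheta):
            return core.neg2ll(np.exp(logtheta))
        history.append(obj(x0))
        res = minimize(
            obj, x0, method="L-BFGS-B",
            bounds=[(lo, hi)] * x0.size,
            callback=lambda xk: history.append(obj(xk)),
            options=dict(maxiter=max_iter, ftol=tol, gtol=1e-8),
        )
        if not res.success and "ABNORMAL" in str(res.message).upper():
            raise RuntimeError(f"REML optimizer failed: {res.message}; trace={history}")
        theta = np.exp(res.x)
        g = theta[:n_classes]
        sigma2 = theta[n_classes:]
        boundary = res.x[:n_classes] <= lo + 1e-6
        n_iter = int(res.nit)
        converged = bool(res.success) or res.nit < max_iter

    beta, cov_beta = core.solve_beta(theta)
    loglik = -0.5 * core.neg2ll(theta)
    H = _fd_hessian(core.neg2ll, theta)
    info = 0.5 * H
    try:
        theta_cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        theta_cov = np.linalg.pinv(info)
    if not np.all(np.isfinite(theta_cov)):
        theta_cov = np.linalg.pinv(info)

    return RemlFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=np.atleast_1d(theta[n_classes:]),
        g=np.atleast_1d(theta[:n_classes]),
        loglik=float(loglik),
        converged=converged,
        n_iter=n_iter,
        n_obs=core.n,
        rank=core.p,
        boundary=np.atleast_1d(boundary),
        theta=theta,
        theta_cov=theta_cov,
        history=history,
        _core=core,
    )
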