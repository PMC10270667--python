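"""Estimation and testing for the pairwise-distance regression.

Three regression approaches share one model-matrix construction:

``fit_f_test``
    Ordinary least squares on the per-task covariate blocks.  Distances
    sharing a subject are correlated, so its F/t tests are anticonservative
    under repeated measures; it is provided for comparison.
``fit_f_test_sle``
    OLS with scan-level fixed effects (one indicator per scan, two 1s per
    row) absorbing scan-specific distance shifts.  Valid when each subject
    contributes a single scan; still anticonservative with repetitions.
``fit_3m_bantor``
    The mixed model: scan-level fixed effects plus one random intercept per
    (dyad, task) with task-specific variances, fitted by REML
    (:mod:`bantor.reml`); fixed-effect p-values use Satterthwaite degrees of
    freedom.

A permutation MDMR baseline operating on the complete per-task scan
distance matrix is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.linalg import solve_triangular

from .design import DesignTable
from .reml import RemlFit, fit_grouped_reml

__all__ = [
    "FixedEffectEstimate",
    "OlsFitResult",
    "MixedFitResult",
    "MdmrResult",
    "fit_f_test",
    "fit_f_test_sle",
    "fit_3m_bantor",
    "mdmr_permutation",
]


@dataclass(frozen=True)
class FixedEffectEstimate:
    task_id: str
    term: str
    estimate: float
    se: float
    df: float
    stat: float
    p: float


@dataclass
class OlsFitResult:
    """OLS fit (standard F test, optionally with scan-level effects)."""

    estimates: list[FixedEffectEstimate]
    scan_effects: pd.Series | None
    sigma2: float
    n_obs: int
    rank: int
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        return _estimates_frame(self.estimates)


@dataclass
class MixedFitResult:
    """3M_BANTOR fit: fixed effects, variance components, REML diagnostics."""

    estimates: list[FixedEffectEstimate]
    scan_effects: pd.Series | None
    g: dict[str, float]
    sigma2: float
    loglik: float
    converged: bool
    n_iter: int
    boundary: dict[str, bool]
    theta_cov: np.ndarray
    history: list = field(repr=False, default_factory=list)
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return _estimates_frame(self.estimates)


@dataclass(frozen=True)
class MdmrResult:
    predictor: str
    pseudo_f: float
    p: float
    n_perm: int


def _estimates_frame(estimates) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(task=e.task_id, term=e.term, estimate=e.estimate, se=e.se,
                 df=e.df, stat=e.stat, p=e.p)
            for e in estimates
        ]
    )


# ---------------------------------------------------------------------------
# model-matrix construction and identification
# ---------------------------------------------------------------------------

def build_model_matrix(design: DesignTable, *, scan_effects: bool):
    """Sparse model matrix with per-task covariate blocks.

    Columns are ordered covariates first, then scan indicators (with one
    reference scan per task pre-dropped), so that any remaining collinearity
    is resolved by dropping scan columns, never covariate columns.  Returns
    ``(X_csr, column_names, meta)``.
    """
    df = design.df
    n = len(df)
    terms = design.spec.terms
    tasks = design.tasks
    cols = []
    names = []
    task_codes = df["task"].to_numpy()
    for task in tasks:
        in_task = (task_codes == task).astype(float)
        for term in terms:
            base = np.ones(n) if term == "Intercept" else df[term].to_numpy(float)
            cols.append(sp.csc_matrix((base * in_task)[:, None]))
            names.append(f"{term}[{task}]")
    n_cov = len(names)

    scan_names = []
    if scan_effects:
        # reference scan per task: the lexicographically last one
        by_task: dict[str, list] = {}
        for key in design.scans:
            by_task.setdefault(key[1], []).append(key)
        keep = []
        for task in tasks:
            sc = sorted(by_task.get(task, []))
            keep.extend(sc[:-1])
        index = {k: i for i, k in enumerate(keep)}
        rows, colixs = [], []
        for which in (1, 2):
            keys = zip(
                df[f"subject_{which}"], df["task"], df[f"rep_{which}"]
            )
            for r, k in enumerate(keys):
                j = index.get(k)
                if j is not None:
                    rows.append(r)
                    colixs.append(j)
        S = sp.csc_matrix(
            (np.ones(len(rows)), (rows, colixs)), shape=(n, len(keep))
        )
        cols.append(S)
        scan_names = [f"scan[{'.'.join(k)}]" for k in keep]
        names.extend(scan_names)

    X = sp.hstack(cols, format="csc")
    return X.tocsr(), names, dict(n_covariate_cols=n_cov)


def _greedy_independent(XtX: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Indices of a maximal independent column set, scanning in order.

    In-order pivoted Cholesky: a column is kept iff its residual variance
    after projection on the already-kept columns exceeds ``tol`` times its
    own diagonal.  Earlier columns therefore always win ties, which makes
    the identification deterministic and keeps covariate columns (listed
    first) whenever possible.
    """
    p = XtX.shape[0]
    keep: list[int] = []
    L = np.zeros((p, p))
    d0 = np.diag(XtX)
    for j in range(p):
        if d0[j] <= 0:
            continue
        k = len(keep)
        if k:
            w = solve_triangular(L[:k, :k], XtX[keep, j], lower=True)
            resid = XtX[j, j] - w @ w
        else:
            w = np.empty(0)
            resid = XtX[j, j]
        if resid <= tol * d0[j]:
            continue
        L[k, :k] = w
        L[k, k] = np.sqrt(resid)
        keep.append(j)
    return np.array(keep, dtype=int)


def _identify_columns(X, names, n_cov):
    """Drop linearly dependent columns; covariates are protected.

    If a *covariate* column itself is dependent on the scan indicators the
    model is unidentifiable in a way the user must resolve, so that is an
    error naming the column.
    """
    XtX = np.asarray((X.T @ X).todense())
    # detection pass: scans first — a covariate dropped here is collinear
    # with the scan indicators
    order = list(range(n_cov, XtX.shape[0])) + list(range(n_cov))
    sub = XtX[np.ix_(order, order)]
    kept = set(np.asarray(order)[_greedy_independent(sub)])
    for j in range(n_cov):
        if j not in kept and XtX[j, j] > 0:
            raise ValueError(
                f"covariate column {names[j]!r} is collinear with the scan "
                "indicators (or other covariates); drop or recode it"
            )
    # identification pass: covariates first, drop redundant scan columns
    keep = _greedy_independent(XtX)
    return X[:, keep], [names[j] for j in keep], keep


def _covariate_estimates(design, names, beta, se, df_vec, note_terms=None):
    out = []
    for j, name in enumerate(names):
        if name.startswith("scan["):
            continue
        term, task = name[:-1].split("[")
        t = beta[j] / se[j] if se[j] > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(t), df_vec[j]) if se[j] > 0 else np.nan
        out.append(
            FixedEffectEstimate(task, term, float(beta[j]), float(se[j]),
                                float(df_vec[j]), float(t), float(p))
        )
    return out


def _scan_effect_series(names, beta) -> pd.Series:
    vals = {n[5:-1]: beta[j] for j, n in enumerate(names) if n.startswith("scan[")}
    return pd.Series(vals, dtype=float) if vals else pd.Series(dtype=float)


# ---------------------------------------------------------------------------
# OLS fits
# ---------------------------------------------------------------------------

def _ols(X, y):
    from scipy.linalg import cho_factor, cho_solve

    XtX = np.asarray((X.T @ X).todense())
    Xty = np.asarray(X.T @ y).ravel()
    cf = cho_factor(XtX, lower=True)
    beta = cho_solve(cf, Xty)
    resid = y - X @ beta
    rank = X.shape[1]
    dof = y.size - rank
    if dof <= 0:
        raise ValueError("design has no residual degrees of freedom")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * cho_solve(cf, np.eye(rank))
    return beta, cov, sigma2, dof


def fit_f_test(design: DesignTable) -> OlsFitResult:
    """Standard per-task OLS with classical t/F inference.

    Anticonservative under repeated measures: rows sharing a subject are
    correlated, which this model ignores.  Included for comparison.
    """
    X, names, meta = build_model_matrix(design, scan_effects=False)
    X, names, _ = _identify_columns(X, names, meta["n_covariate_cols"])
    y = design.df["distance"].to_numpy(float)
    beta, cov, sigma2, dof = _ols(X, y)
    se = np.sqrt(np.diag(cov))
    ests = _covariate_estimates(design, names, beta, se, np.full(len(names), dof))
    return OlsFitResult(ests, None, sigma2, y.size, len(names),
                        note="anticonservative under repeated measures")


def fit_f_test_sle(design: DesignTable) -> OlsFitResult:
    """OLS with scan-level fixed effects absorbing per-scan shifts."""
    X, names, meta = build_model_matrix(design, scan_effects=True)
    X, names, _ = _identify_columns(X, names, meta["n_covariate_cols"])
    y = design.df["distance"].to_numpy(float)
    beta, cov, sigma2, dof = _ols(X, y)
    se = np.sqrt(np.diag(cov))
    ests = _covariate_estimates(design, names, beta, se, np.full(len(names), dof))
    return OlsFitResult(ests, _scan_effect_series(names, beta), sigma2,
                        y.size, len(names),
                        note="anticonservative with repeated within-task comparisons")


# ---------------------------------------------------------------------------
# the mixed model
# ---------------------------------------------------------------------------

def fit_3m_bantor(
    design: DesignTable,
    *,
    pooled_dyad_variance: bool = False,
    task_specific_residual: bool = False,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixedFitResult:
    """Fit the multitask mixed model and test fixed effects.

    One random intercept per (dyad, task) with variance ``g_b`` per task
    (``pooled_dyad_variance`` collapses these to one), scan-level fixed
    effects, and a shared residual variance (``task_specific_residual``
    relaxes this).  If every (dyad, task) group contains a single row —
    one task and one repetition per subject — the random effects are
    unidentifiable and the fit falls back to :func:`fit_f_test_sle`.
    """
    df = design.df
    y = df["distance"].to_numpy(float)
    dyads, groups = np.unique(df["dyad"].to_numpy(), return_inverse=True)
    sizes = np.bincount(groups)
    if sizes.max() == 1:
        warnings.warn(
            "every dyad-task group has a single observation; random effects "
            "dropped — returning the scan-level fixed-effects fit",
            UserWarning,
            stacklevel=2,
        )
        sle = fit_f_test_sle(design)
        return MixedFitResult(
            estimates=sle.estimates, scan_effects=sle.scan_effects,
            g={t: 0.0 for t in design.tasks}, sigma2=sle.sigma2,
            loglik=np.nan, converged=True, n_iter=0,
            boundary={t: True for t in design.tasks},
            theta_cov=np.empty((0, 0)), degenerate=True,
        )

    X, names, meta = build_model_matrix(design, scan_effects=True)
    X, names, _ = _identify_columns(X, names, meta["n_covariate_cols"])

    tasks = design.tasks
    task_index = {t: i for i, t in enumerate(tasks)}
    dyad_task = np.array([d.rsplit("|", 1)[1] for d in dyads])
    if pooled_dyad_variance:
        group_class = np.zeros(len(dyads), dtype=int)
        n_classes = 1
    else:
        group_class = np.array([task_index[t] for t in dyad_task])
        n_classes = len(tasks)
    residual_class = None
    n_resid = 1
    if task_specific_residual:
        residual_class = np.array([task_index[t] for t in df["task"]])
        n_resid = len(tasks)

    fit = fit_grouped_reml(
        X, y, groups, group_class, n_classes,
        residual_class=residual_class, n_residual_classes=n_resid,
        tol=tol, max_iter=max_iter,
    )

    L = np.eye(len(names))
    dfs = fit.satterthwaite_df(L)
    ests = _covariate_estimates(design, names, fit.beta, fit.se, dfs)

    if pooled_dyad_variance:
        g = {t: float(fit.g[0]) for t in tasks}
        boundary = {t: bool(fit.boundary[0]) for t in tasks}
    else:
        g = {t: float(fit.g[task_index[t]]) for t in tasks}
        boundary = {t: bool(fit.boundary[task_index[t]]) for t in tasks}
    if any(boundary.values()):
        warnings.warn(
            "dyad variance pinned at the zero boundary for task(s) "
            + ", ".join(t for t, b in boundary.items() if b),
            UserWarning,
            stacklevel=2,
        )
    return MixedFitResult(
        estimates=ests,
        scan_effects=_scan_effect_series(names, fit.beta),
        g=g,
        sigma2=float(fit.sigma2[0]) if not task_specific_residual
        else float(np.mean(fit.sigma2)),
        loglik=fit.loglik,
        converged=fit.converged,
        n_iter=fit.n_iter,
        boundary=boundary,
        theta_cov=fit.theta_cov,
        history=fit.history,
    )


# ---------------------------------------------------------------------------
# permutation MDMR
# ---------------------------------------------------------------------------

def mdmr_permutation(
    D: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    n_perm: int = 5000,
    *,
    seed=None,
    add_intercept: bool = True,
) -> list[MdmrResult]:
    """Permutation multivariate distance matrix regression.

    Gower-centers ``G = -1/2 H (D*D) H`` and tests each predictor with a
    pseudo-F comparing the trace explained by that predictor (hat matrix of
    the full model minus the model without it) to the residual trace.
    P-values use the add-one permutation estimator, permuting rows and
    columns of ``G`` jointly.  Does not account for correlated observations.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if np.max(np.abs(D - D.T)) > 1e-10:
        raise ValueError("D must be symmetric")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    n = D.shape[0]

    if isinstance(X, pd.DataFrame):
        Xm, pred_names = _numeric_design(X)
    else:
        Xm = np.asarray(X, dtype=float)
        pred_names = [f"x{j}" for j in range(Xm.shape[1])]
    if add_intercept:
        Xm = np.column_stack([np.ones(n), Xm])
        cols = ["Intercept"] + pred_names
    else:
        cols = pred_names
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("predictor matrix is rank deficient")

    H = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * H @ (D * D) @ H

    def hat(M):
        Q, _ = np.linalg.qr(M)
        return Q @ Q.T

    H_full = hat(Xm)
    p_full = Xm.shape[1]
    resid_proj = np.eye(n) - H_full

    rng = np.random.default_rng(seed)
    results = []
    test_idx = [j for j, c in enumerate(cols) if c != "Intercept"]
    # trace(A @ G) = sum(A * G) for symmetric A: precompute per-predictor
    H_parts = []
    for j in test_idx:
        Xr = np.delete(Xm, j, axis=1)
        H_parts.append(H_full - hat(Xr))
    denom_proj = resid_proj

    obs_denom = float(np.sum(denom_proj * G)) / (n - p_full)
    obs_F = np.array(
        [float(np.sum(Hj * G)) / obs_denom for Hj in H_parts]
    )
    exceed = np.zeros(len(test_idx))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        den = float(np.sum(denom_proj * Gp)) / (n - p_full)
        for a, Hj in enumerate(H_parts):
            f = float(np.sum(Hj * Gp)) / den
            if f >= obs_F[a]:
                exceed[a] += 1
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    for a, j in enumerate(test_idx):
        results.append(MdmrResult(cols[j], float(obs_F[a]), float(pvals[a]), n_perm))
    return results


def _numeric_design(X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    out, names = [], []
    for c in X.columns:
        col = X[c]
        if np.issubdtype(col.dtype, np.number):
            out.append(col.to_numpy(float))
            names.append(str(c))
        else:
            levels = sorted(col.astype(str).unique())
            # one indicator per non-reference level
            for lev in levels[1:]:
                out.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{c}[{lev}]")
    return np.column_stack(out), names
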