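"""Simulator for symmetric positive-definite connectome matrices.

Emulates repeated-measures resting/task fMRI connectivity data with a known
covariate signal:

* Subjects get two fair-coin binary covariates (``SEX``, ``TRT``) and two
  rounded Normal(100, 15^2) continuous covariates (``IQ``, ``AGE``).  A
  signal parameter ``a = clip((IQ-100)*0.15 + 2*1{TRT=Treatment} -
  2*1{TRT=Placebo}, -5.95, 5.95)`` drives the strength of covariate-
  dependent connectivity; ``AGE`` and ``SEX`` never enter the generative
  process and serve as null covariates.
* A "low-connectivity noise" background correlation matrix ``Sigma1`` is
  built from a Haar-random orthogonal matrix: ``A = Q' D Q`` with
  ``D = diag(50 * Beta(34, 2))``, rescaled to unit diagonal and smoothed to
  be positive definite at tolerance 1e-6.
* Each task's network carries three 15-node regions with compound-symmetric
  (single-value) within-region correlation.  A region's per-scan level is a
  quantile-coupled draw: one latent 12-vector (3 tasks x 4 repetitions) per
  region from a Gaussian copula with 0.7 within-task and 0.3 within-
  repetition correlation is pushed through either the Beta(5, 5)
  high-connectivity noise distribution or the signal mixture
  ``(1-s_p) * F_pool^{-1}(u) + s_p * F_Beta(7+a, 7-a)^{-1}(u)``,
  where ``F_pool`` is the distribution of |off-diagonal(Sigma1)| and
  ``s_p`` the signal percentage.  At ``s_p = 0`` signal regions are
  indistinguishable from noise, so covariates carry no information.
* Each scan is realized as 2,500 time points of a multivariate normal with
  the region blocks overwritten, converted to a sample Pearson correlation
  matrix, and smoothed — the output is always a valid SPD correlation
  matrix, ready for the log-Euclidean metric.

Seeding is hierarchical (master seed -> per-subject -> per-scan streams) so
any scan can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import ConnectionMatrix, validate_connection_matrix

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_covariates",
    "signal_parameter",
    "make_sigma1",
    "smooth_correlation",
    "copula_matrix",
    "region_layout",
    "draw_region_levels",
    "simulate_scan",
    "simulate_dataset",
]

A_CLAMP = 5.95
REGION_SIZE = 15
N_REGIONS = 3


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one simulated dataset."""

    n_subjects: int = 100
    n_nodes: int = 268
    n_tasks: int = 3
    n_reps: int = 4
    n_timepoints: int = 2500
    signal_percent: float = 0.0      # s_p as a fraction in [0, 1]
    smooth_tol: float = 1e-6
    seed: int = 0
    mixture: str = "comonotone"      # or "mixture-cdf"

    def __post_init__(self):
        if not (0.0 <= self.signal_percent <= 1.0):
            raise ValueError("signal_percent must be in [0, 1]")
        if self.n_nodes < N_REGIONS * REGION_SIZE + 1:
            raise ValueError(
                f"n_nodes must exceed {N_REGIONS * REGION_SIZE} to fit the regions"
            )
        if self.mixture not in ("comonotone", "mixture-cdf"):
            raise ValueError("mixture must be 'comonotone' or 'mixture-cdf'")


@dataclass
class SimulatedDataset:
    scans: list[ConnectionMatrix]
    covariates: pd.DataFrame
    sigma1: np.ndarray
    config: SimConfig


def signal_parameter(iq, trt):
    """Covariate-dependent signal parameter, clamped to [-5.95, 5.95]."""
    iq = np.asarray(iq, dtype=float)
    trt = np.asarray(trt)
    raw = (iq - 100.0) * 0.15 + np.where(trt == "Treatment", 2.0, -2.0)
    return np.clip(raw, -A_CLAMP, A_CLAMP)


def simulate_covariates(n_subjects: int, rng) -> pd.DataFrame:
    """Simulate the subject covariate table (SEX, TRT, IQ, AGE, a)."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(rng)
    sex = np.where(rng.random(n_subjects) < 0.5, "Female", "Male")
    trt = np.where(rng.random(n_subjects) < 0.5, "Treatment", "Placebo")
    iq = np.round(rng.normal(100.0, 15.0, n_subjects)).astype(int)
    age = np.round(rng.normal(100.0, 15.0, n_subjects)).astype(int)
    width = len(str(n_subjects))
    return pd.DataFrame(
        dict(
            subject=[f"s{i:0{width}d}" for i in range(1, n_subjects + 1)],
            SEX=sex,
            TRT=trt,
            IQ=iq,
            AGE=age,
            a=signal_parameter(iq, trt),
        )
    )


def smooth_correlation(M: np.ndarray, tol: float = 1e-6, *, max_pass: int = 5):
    """Make a unit-diagonal symmetric matrix positive definite.

    If the smallest eigenvalue is already >= ``tol`` the input is returned
    unchanged.  Otherwise eigenvalues are floored at ``tol``, the matrix is
    reconstructed and rescaled back to unit diagonal; this is repeated (at
    most ``max_pass`` times) until the floor holds.
    """
    M = np.asarray(M, dtype=float)
    if np.max(np.abs(M - M.T)) > 1e-10:
        raise ValueError("smooth_correlation requires a symmetric matrix")
    w = np.linalg.eigvalsh(M)
    if w[0] >= tol:
        return M
    out = M
    for _ in range(max_pass):
        w, v = np.linalg.eigh(out)
        w = np.maximum(w, tol)
        out = (v * w) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = 0.5 * (out + out.T)
        np.fill_diagonal(out, 1.0)
        if np.linalg.eigvalsh(out)[0] >= tol * (1.0 - 1e-6):
            return out
    raise RuntimeError("correlation smoothing failed to reach tolerance")


def make_sigma1(n_nodes: int, rng, tol: float = 1e-6):
    """Random background correlation matrix from a Haar orthogonal basis.

    ``Q`` is Haar-distributed (QR of a Gaussian matrix with the sign of R's
    diagonal absorbed), ``D = diag(50 * Beta(34, 2))``, ``A = Q' D Q`` and
    the result is ``A`` rescaled to unit diagonal, then smoothed.
    Returns ``(sigma1, offdiag_pool)`` with the pool holding the *absolute*
    off-diagonal values (sorted), the noise component of the signal mixture.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be at least 2")
    rng = np.random.default_rng(rng)
    Zm = rng.standard_normal((n_nodes, n_nodes))
    Q, R = np.linalg.qr(Zm)
    Q = Q * np.sign(np.diag(R))
    D = 50.0 * rng.beta(34.0, 2.0, n_nodes)
    A = (Q.T * D) @ Q
    d = np.sqrt(np.diag(A))
    sigma1 = A / np.outer(d, d)
    sigma1 = 0.5 * (sigma1 + sigma1.T)
    np.fill_diagonal(sigma1, 1.0)
    sigma1 = smooth_correlation(sigma1, tol)
    iu = np.triu_indices(n_nodes, k=1)
    pool = np.sort(np.abs(sigma1[iu]))
    return sigma1, pool


def copula_matrix(n_tasks: int = 3, n_reps: int = 4,
                  within_task: float = 0.7, within_rep: float = 0.3) -> np.ndarray:
    """Scan-coupling correlation over (task, repetition) cells.

    1 on the diagonal, ``within_task`` between repetitions of the same task,
    ``within_rep`` between the same repetition of different tasks, 0
    elsewhere.  Cells are ordered task-major: (t1 r1, t1 r2, ..., t3 r4).
    """
    It, Jt = np.eye(n_tasks), np.ones((n_tasks, n_tasks))
    Ir, Jr = np.eye(n_reps), np.ones((n_reps, n_reps))
    C = (
        np.kron(It, Ir)
        + within_task * np.kron(It, Jr - Ir)
        + within_rep * np.kron(Jt - It, Ir)
    )
    # at the default 0.7/0.3 the matrix is PSD but singular
    # (it equals 0.7 I(x)J + 0.3 J(x)I), so only semidefiniteness is required
    if np.linalg.eigvalsh(C)[0] < -1e-10:
        raise ValueError("scan-coupling matrix is not positive semidefinite")
    return C


def _psd_factor(C: np.ndarray) -> np.ndarray:
    """Factor ``L`` with ``L L' = C`` for a PSD (possibly singular) matrix."""
    w, v = np.linalg.eigh(C)
    return v * np.sqrt(np.maximum(w, 0.0))


def region_layout(n_tasks: int = 3) -> list[list[str]]:
    """Role ('noise'/'signal') of each 15-node region per task.

    Task ``j`` (1-based) has ``min(j, 3)`` signal regions, filled from the
    last region backwards: task 1 = [noise, noise, signal], task 2 =
    [noise, signal, signal], task 3 = [signal, signal, signal].
    """
    layout = []
    for t in range(n_tasks):
        n_sig = min(t + 1, N_REGIONS)
        layout.append(
            ["noise"] * (N_REGIONS - n_sig) + ["signal"] * n_sig
        )
    return layout


def _pool_quantile(pool_sorted: np.ndarray, u: np.ndarray) -> np.ndarray:
    return np.quantile(pool_sorted, u)


def _signal_level(u, a, s_p, pool_sorted, mixture):
    """Per-scan region level for a signal region at copula quantile u."""
    beta_q = stats.beta.ppf(u, 7.0 + a, 7.0 - a)
    if s_p == 0.0:
        return _pool_quantile(pool_sorted, u)
    if s_p == 1.0:
        return beta_q
    if mixture == "comonotone":
        return (1.0 - s_p) * _pool_quantile(pool_sorted, u) + s_p * beta_q
    # mixture-cdf: invert F(x) = (1-s) F_pool(x) + s F_beta(x) numerically
    grid = np.unique(
        np.concatenate(
            [pool_sorted, stats.beta.ppf(np.linspace(1e-6, 1 - 1e-6, 512), 7 + a, 7 - a)]
        )
    )
    Fp = np.searchsorted(pool_sorted, grid, side="right") / pool_sorted.size
    Fb = stats.beta.cdf(grid, 7.0 + a, 7.0 - a)
    F = (1.0 - s_p) * Fp + s_p * Fb
    return np.interp(u, F, grid)


def draw_region_levels(
    a: float,
    layout: list[list[str]],
    s_p: float,
    copula_chol: np.ndarray,
    pool_sorted: np.ndarray,
    rng,
    *,
    n_reps: int = 4,
    mixture: str = "comonotone",
) -> np.ndarray:
    """Coupled region correlation levels for one subject.

    Returns an array of shape ``(n_regions, n_tasks, n_reps)``.  Each
    region's 12 latent quantiles are pushed through the high-connectivity
    noise Beta(5, 5) or the covariate-dependent signal mixture according to
    the region's role in each task.
    """
    if not (0.0 <= s_p <= 1.0):
        raise ValueError("signal percent must be in [0, 1]")
    rng = np.random.default_rng(rng)
    n_tasks = len(layout)
    out = np.empty((N_REGIONS, n_tasks, n_reps))
    for region in range(N_REGIONS):
        z = copula_chol @ rng.standard_normal(copula_chol.shape[0])
        u = stats.norm.cdf(z).reshape(n_tasks, n_reps)
        for t in range(n_tasks):
            if layout[t][region] == "noise":
                out[region, t] = stats.beta.ppf(u[t], 5.0, 5.0)
            else:
                out[region, t] = _signal_level(u[t], a, s_p, pool_sorted, mixture)
    return out


def simulate_scan(
    levels: np.ndarray,
    sigma1_chol: np.ndarray,
    rng,
    config: SimConfig,
    *,
    subject_id="s", task_id="t", repetition_id="r",
) -> ConnectionMatrix:
    """Simulate one scan's time series and return its correlation network.

    ``levels`` holds this scan's per-region off-diagonal correlation value.
    The full node set is drawn from the background Normal(0, Sigma1); each
    region's columns are overwritten with an independent draw from the
    compound-symmetric region covariance.
    """
    rng = np.random.default_rng(rng)
    n = config.n_nodes
    T = config.n_timepoints
    series = rng.standard_normal((T, n)) @ sigma1_chol.T
    for region, r in enumerate(levels):
        if not (-1.0 / (REGION_SIZE - 1) < r < 1.0):
            raise ValueError(
                f"region correlation level {r:.4f} gives a non-PD region block"
            )
        block = (1.0 - r) * np.eye(REGION_SIZE) + r
        Lb = np.linalg.cholesky(block)
        cols = slice(region * REGION_SIZE, (region + 1) * REGION_SIZE)
        series[:, cols] = rng.standard_normal((T, REGION_SIZE)) @ Lb.T
    corr = np.corrcoef(series, rowvar=False)
    corr = smooth_correlation(corr, config.smooth_tol)
    return validate_connection_matrix(
        corr, subject_id, task_id, repetition_id
    )


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Simulate the full dataset: covariates plus one scan per
    (subject, task, repetition)."""
    master = np.random.SeedSequence(config.seed)
    ss_sigma1, ss_cov, ss_subjects = master.spawn(3)
    sigma1, pool = make_sigma1(config.n_nodes, np.random.default_rng(ss_sigma1),
                               config.smooth_tol)
    sigma1_chol = np.linalg.cholesky(sigma1)
    covariates = simulate_covariates(
        config.n_subjects, np.random.default_rng(ss_cov)
    )
    layout = region_layout(config.n_tasks)
    cop = copula_matrix(config.n_tasks, config.n_reps)
    cop_chol = _psd_factor(cop)

    scans: list[ConnectionMatrix] = []
    subject_streams = ss_subjects.spawn(config.n_subjects)
    for i, ss_subj in enumerate(subject_streams):
        row = covariates.iloc[i]
        level_stream, *scan_streams = ss_subj.spawn(
            1 + config.n_tasks * config.n_reps
        )
        levels = draw_region_levels(
            float(row["a"]), layout, config.signal_percent, cop_chol, pool,
            np.random.default_rng(level_stream),
            n_reps=config.n_reps, mixture=config.mixture,
        )
        k = 0
        for t in range(config.n_tasks):
            for r in range(config.n_reps):
                scans.append(
                    simulate_scan(
                        levels[:, t, r],
                        sigma1_chol,
                        np.random.default_rng(scan_streams[k]),
                        config,
                        subject_id=row["subject"],
                        task_id=f"task{t + 1}",
                        repetition_id=f"rep{r + 1}",
                    )
                )
                k += 1
    return SimulatedDataset(scans, covariates, sigma1, config)
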