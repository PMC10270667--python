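"""Network validation, thresholding, and pairwise distance metrics.

A *scan* is one weighted brain network: the matrix of Pearson correlations
between regional fMRI time series for one subject performing one task on one
repetition.  Distances between two scans' networks are the raw material of
the whole regression framework; five metrics are provided:

``KS``
    Natural log of the two-sample Kolmogorov–Smirnov statistic between the
    empirical distributions of the two networks' edge weights.
``JACCARD``
    Proportion of key edges (edges in either thresholded graph) that do not
    share key status; 0 = identical key sets, 1 = disjoint.
``EUC``
    Euclidean distance between the vectorized upper triangles.
``PCD``
    Pearson correlation distance ``(1 - r)/2`` between the vectorized upper
    triangles, mapping r in [-1, 1] onto [0, 1].
``LERM``
    Log-Euclidean Riemannian metric: Frobenius norm of the difference of the
    matrix logarithms.  Requires symmetric positive-definite inputs.

All metrics use the off-diagonal upper triangle only (the diagonal is
uninformative for correlation networks) and all but LERM also accept nodal
degree vectors in place of matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata  # noqa: F401  (re-exported convenience)

__all__ = [
    "ConnectionMatrix",
    "BinaryGraph",
    "DistanceValue",
    "METRICS",
    "validate_connection_matrix",
    "threshold_top_fraction",
    "degree_vector",
    "ks_distance",
    "jaccard_distance",
    "euclidean_distance",
    "pearson_correlation_distance",
    "lerm_distance",
    "pairwise_distance_table",
]

#: asymmetry / range / diagonal tolerance for validation
ASYM_TOL = 1e-8
#: eigenvalues at or below this are treated as non-SPD for the matrix log
SPD_EIG_TOL = 1e-10

METRICS = ("KS", "JACCARD", "EUC", "PCD", "LERM")


@dataclass(frozen=True)
class ConnectionMatrix:
    """One scan's validated weighted network.

    ``values`` is a symmetric ``n_n x n_n`` correlation matrix with unit
    diagonal and entries in [-1, 1].
    """

    subject_id: str
    task_id: str
    repetition_id: str
    values: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.task_id, self.repetition_id)


@dataclass(frozen=True)
class BinaryGraph:
    """Key-edge indicator graph produced by thresholding.

    ``values`` is either a square 0/1 matrix (zero diagonal) or, for the
    nodal-degree workflow, a 0/1 vector.  ``threshold_rule`` records how it
    was produced, e.g. ``("top_fraction", 0.2)``.
    """

    subject_id: str
    task_id: str
    repetition_id: str
    values: np.ndarray = field(repr=False)
    threshold_rule: tuple = ("top_fraction", None)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.task_id, self.repetition_id)


@dataclass(frozen=True)
class DistanceValue:
    """One metric value for an unordered pair of scans."""

    metric: str
    key1: tuple[str, str, str]
    key2: tuple[str, str, str]
    value: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# validation and elementary transforms
# ---------------------------------------------------------------------------

def validate_connection_matrix(
    raw: np.ndarray,
    subject_id: str = "s",
    task_id: str = "t",
    repetition_id: str = "r",
    *,
    tol: float = ASYM_TOL,
) -> ConnectionMatrix:
    """Validate a raw square matrix and package it as a :class:`ConnectionMatrix`.

    The matrix must be square with at least two nodes, have unit diagonal,
    entries in [-1, 1] (within ``tol``), and be symmetric within ``tol``;
    small asymmetries are repaired by averaging with the transpose.
    """
    values = np.asarray(raw, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"connection matrix must be square, got shape {values.shape}")
    n = values.shape[0]
    if n < 2:
        raise ValueError("connection matrix needs at least 2 nodes")
    if not np.all(np.isfinite(values)):
        raise ValueError("connection matrix contains non-finite entries")
    asym = np.max(np.abs(values - values.T))
    if asym > tol:
        raise ValueError(f"matrix asymmetry {asym:.3g} exceeds tolerance {tol:.3g}")
    values = 0.5 * (values + values.T)
    excess = np.max(np.abs(values)) - 1.0
    if excess > tol:
        raise ValueError("entry out of range: |value| exceeds 1 beyond tolerance")
    diag_err = np.max(np.abs(np.diag(values) - 1.0))
    if diag_err > tol:
        raise ValueError("diagonal entries must equal 1")
    values = np.clip(values, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    values.flags.writeable = False
    return ConnectionMatrix(str(subject_id), str(task_id), str(repetition_id), values)


def upper_triangle(values: np.ndarray) -> np.ndarray:
    """Off-diagonal upper-triangle entries in row-major (edge-index) order."""
    values = np.asarray(values)
    if values.ndim == 1:
        return values
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def degree_vector(C: ConnectionMatrix) -> np.ndarray:
    """Nodal (weighted) degrees: row sums of the matrix excluding the diagonal."""
    v = C.values
    return v.sum(axis=1) - np.diag(v)


def _top_fraction_mask(edge_values: np.ndarray, fraction: float) -> np.ndarray:
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    m = edge_values.size
    k = int(np.floor(fraction * m + 0.5))
    if k == 0:
        raise ValueError("empty key set: fraction rounds to zero edges")
    # ties broken by ascending edge index: stable sort of descending values
    order = np.argsort(-edge_values, kind="stable")
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask


def threshold_top_fraction(
    C: ConnectionMatrix | np.ndarray, fraction: float
) -> BinaryGraph:
    """Keep the top ``fraction`` of edges by signed weight as key edges.

    Exactly ``k = round(fraction * n_edges)`` upper-triangle entries are set
    to 1, selected by descending value with ties broken by ascending
    row-major edge index.  Also accepts a nodal degree vector, in which case
    the top ``round(fraction * n_n)`` entries are marked.
    """
    if isinstance(C, ConnectionMatrix):
        edge_values = upper_triangle(C.values)
        mask = _top_fraction_mask(edge_values, fraction)
        n = C.n_nodes
        out = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        out[iu] = mask
        out = out + out.T
        out.flags.writeable = False
        return BinaryGraph(
            C.subject_id, C.task_id, C.repetition_id, out, ("top_fraction", fraction)
        )
    vec = np.asarray(C, dtype=float)
    mask = _top_fraction_mask(vec, fraction).astype(float)
    mask.flags.writeable = False
    return BinaryGraph("s", "t", "r", mask, ("top_fraction", fraction))


# ---------------------------------------------------------------------------
# distance metrics
# ---------------------------------------------------------------------------

def _edge_samples(x) -> np.ndarray:
    if isinstance(x, ConnectionMatrix):
        return upper_triangle(x.values)
    return np.asarray(x, dtype=float).ravel()


def _pair_keys(x, y) -> tuple[tuple, tuple]:
    kx = x.key if isinstance(x, (ConnectionMatrix, BinaryGraph)) else ("s", "t", "r")
    ky = y.key if isinstance(y, (ConnectionMatrix, BinaryGraph)) else ("s", "t", "r")
    return kx, ky


def _check_same_size(a: np.ndarray, b: np.ndarray) -> None:
    if a.size != b.size:
        raise ValueError(f"dimension mismatch: {a.size} vs {b.size} edge values")


def _ks_sup(x1: np.ndarray, x2: np.ndarray) -> float:
    """Exact sup |F1 - F2| via both ECDFs evaluated at all pooled points."""
    s1 = np.sort(x1)
    s2 = np.sort(x2)
    pooled = np.concatenate([s1, s2])
    f1 = np.searchsorted(s1, pooled, side="right") / s1.size
    f2 = np.searchsorted(s2, pooled, side="right") / s2.size
    return float(np.max(np.abs(f1 - f2)))


def ks_distance(C1, C2) -> DistanceValue:
    """Natural log of the two-sample KS statistic between edge-weight ECDFs.

    If the two edge-weight multisets are identical the raw statistic is 0;
    the log value is then floored at ``log(1/n_edges)`` (the smallest
    achievable nonzero statistic at that sample size) and the pair is
    flagged degenerate.
    """
    x1, x2 = _edge_samples(C1), _edge_samples(C2)
    _check_same_size(x1, x2)
    sup = _ks_sup(x1, x2)
    if sup <= 0.0:
        return DistanceValue("KS", *_pair_keys(C1, C2), float(np.log(1.0 / x1.size)), True)
    return DistanceValue("KS", *_pair_keys(C1, C2), float(np.log(sup)))


def jaccard_distance(B1: BinaryGraph, B2: BinaryGraph) -> DistanceValue:
    """Jaccard distance between two key-edge sets: (M01 + M10) / (M11 + M01 + M10)."""
    if B1.threshold_rule != B2.threshold_rule:
        raise ValueError("binary graphs were produced by different threshold rules")
    a = _edge_samples_binary(B1)
    b = _edge_samples_binary(B2)
    _check_same_size(a, b)
    m11 = int(np.sum(a & b))
    m01 = int(np.sum(~a & b))
    m10 = int(np.sum(a & ~b))
    union = m11 + m01 + m10
    if union == 0:
        raise ValueError("both key-edge sets are empty; Jaccard distance undefined")
    return DistanceValue("JACCARD", *_pair_keys(B1, B2), (m01 + m10) / union)


def _edge_samples_binary(B: BinaryGraph) -> np.ndarray:
    v = B.values
    if v.ndim == 2:
        return upper_triangle(v).astype(bool)
    return v.astype(bool)


def euclidean_distance(C1, C2) -> DistanceValue:
    """Euclidean distance between the off-diagonal upper triangles."""
    x1, x2 = _edge_samples(C1), _edge_samples(C2)
    _check_same_size(x1, x2)
    return DistanceValue("EUC", *_pair_keys(C1, C2), float(np.linalg.norm(x1 - x2)))


def pearson_correlation_distance(C1, C2) -> DistanceValue:
    """Pearson correlation distance ``(1 - r)/2`` of the edge-weight vectors."""
    x1, x2 = _edge_samples(C1), _edge_samples(C2)
    _check_same_size(x1, x2)
    if np.ptp(x1) == 0.0 or np.ptp(x2) == 0.0:
        raise ValueError("constant edge weights: correlation undefined")
    r = float(np.corrcoef(x1, x2)[0, 1])
    return DistanceValue("PCD", *_pair_keys(C1, C2), (1.0 - r) / 2.0)


def _sym_logm(values: np.ndarray, name: str) -> np.ndarray:
    w, v = np.linalg.eigh(values)
    if np.min(w) <= SPD_EIG_TOL:
        raise ValueError(
            f"matrix for scan {name} is not positive definite "
            f"(min eigenvalue {np.min(w):.3g}); LERM undefined"
        )
    return (v * np.log(w)) @ v.T


def lerm_distance(C1: ConnectionMatrix, C2: ConnectionMatrix) -> DistanceValue:
    """Log-Euclidean Riemannian metric: ``||logm(C1) - logm(C2)||_F``."""
    if C1.n_nodes != C2.n_nodes:
        raise ValueError("dimension mismatch between connection matrices")
    l1 = _sym_logm(C1.values, "/".join(C1.key))
    l2 = _sym_logm(C2.values, "/".join(C2.key))
    return DistanceValue("LERM", *_pair_keys(C1, C2), float(np.linalg.norm(l1 - l2)))


# ---------------------------------------------------------------------------
# batch computation
# ---------------------------------------------------------------------------

def pairwise_distance_table(
    scans: Sequence[ConnectionMatrix],
    metric: str,
    *,
    threshold_fraction: float | None = None,
    include_within: bool = False,
    use_degree_vectors: bool = False,
) -> pd.DataFrame:
    """Compute one metric for every same-task pair of scans, vectorized.

    Returns a tidy frame with columns ``subject_1, task, rep_1, subject_2,
    rep_2, metric, value, degenerate``.  By default only pairs of *distinct*
    subjects are emitted (the regression design excludes within-individual
    comparisons); pass ``include_within=True`` to also emit same-subject
    pairs, as the MDMR distance matrix requires.
    """
    metric = metric.upper()
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "JACCARD" and threshold_fraction is None:
        raise ValueError("JACCARD requires threshold_fraction")
    if metric == "LERM" and use_degree_vectors:
        raise ValueError("LERM is only defined for SPD matrices, not degree vectors")

    by_task: dict[str, list[ConnectionMatrix]] = {}
    for s in scans:
        by_task.setdefault(s.task_id, []).append(s)

    rows = []
    for task, group in by_task.items():
        group = sorted(group, key=lambda s: (s.subject_id, s.repetition_id))
        if use_degree_vectors:
            E = np.stack([degree_vector(s) for s in group])
        else:
            E = np.stack([upper_triangle(s.values) for s in group])
        vals, flags = _pairwise_block(E, group, metric, threshold_fraction)
        n = len(group)
        idx = 0
        for i in range(n):
            for j in range(i + 1, n):
                si, sj = group[i], group[j]
                if not include_within and si.subject_id == sj.subject_id:
                    idx += 1
                    continue
                rows.append(
                    (
                        si.subject_id,
                        task,
                        si.repetition_id,
                        sj.subject_id,
                        sj.repetition_id,
                        metric,
                        vals[idx],
                        flags[idx],
                    )
                )
                idx += 1
    return pd.DataFrame(
        rows,
        columns=[
            "subject_1",
            "task",
            "rep_1",
            "subject_2",
            "rep_2",
            "metric",
            "value",
            "degenerate",
        ],
    )


def _pairwise_block(E, group, metric, threshold_fraction):
    """Condensed-form pairwise values for one task's scan block."""
    n = E.shape[0]
    npairs = n * (n - 1) // 2
    flags = np.zeros(npairs, dtype=bool)
    if metric == "EUC":
        vals = pdist(E, metric="euclidean")
    elif metric == "PCD":
        R = np.corrcoef(E)
        vals = squareform((1.0 - R) / 2.0, checks=False)
    elif metric == "LERM":
        logs = np.stack(
            [_sym_logm(s.values, "/".join(s.key)).ravel() for s in group]
        )
        vals = pdist(logs, metric="euclidean")
    elif metric == "JACCARD":
        K = np.stack(
            [_top_fraction_mask(E[i], threshold_fraction) for i in range(n)]
        )
        inter = (K.astype(np.int64) @ K.T.astype(np.int64)).astype(float)
        sizes = K.sum(axis=1).astype(float)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            jd = 1.0 - inter / union
        if np.any(union[np.triu_indices(n, k=1)] == 0):
            raise ValueError("both key-edge sets are empty; Jaccard distance undefined")
        vals = squareform(jd, checks=False)
    elif metric == "KS":
        m = E.shape[1]
        S = np.sort(E, axis=1)
        vals = np.empty(npairs)
        idx = 0
        for i in range(n):
            for j in range(i + 1, n):
                pooled = np.concatenate([S[i], S[j]])
                f1 = np.searchsorted(S[i], pooled, side="right")
                f2 = np.searchsorted(S[j], pooled, side="right")
                sup = np.max(np.abs(f1 - f2)) / m
                if sup <= 0.0:
                    vals[idx] = np.log(1.0 / m)
                    flags[idx] = True
                else:
                    vals[idx] = np.log(sup)
                idx += 1
    else:  # pragma: no cover
        raise AssertionError(metric)
    return np.asarray(vals, dtype=float), flags
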