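"""Build the long pairwise-distance regression design.

Each observation is a distance between two scans from *distinct* subjects on
the *same* task, one row per combination of the two subjects' repetitions.
Regressors are covariate differences: ``|x_a - x_d|`` for continuous
covariates and ``1{x_a != x_d}`` for categorical ones, with a separate
coefficient vector per task.  Every row also carries the identities of its
two scans (for scan-level effects) and of its dyad — the unordered subject
pair within the task — which indexes the mixed model's random intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .metrics import DistanceValue

__all__ = ["ModelSpec", "DesignTable", "build_design", "build_distance_matrix"]


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the regression and how.

    ``categorical`` lists the covariates compared with a difference
    indicator; any covariate not listed (and with a numeric column) is
    treated as continuous and compared with an absolute difference.  With
    ``per_task_intercept`` (the default) every task block gets its own
    intercept; there is no global intercept.
    """

    covariate_of_interest: str
    confounders: tuple[str, ...] = ()
    categorical: tuple[str, ...] = ()
    per_task_intercept: bool = True

    @property
    def terms(self) -> tuple[str, ...]:
        base = ("Intercept",) if self.per_task_intercept else ()
        return base + tuple(self.confounders) + (self.covariate_of_interest,)

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(self.confounders) + (self.covariate_of_interest,)


@dataclass
class DesignTable:
    """Long-format design: one row per same-task distinct-subject scan pair.

    ``df`` columns: ``task, subject_1, rep_1, subject_2, rep_2, scan_1,
    scan_2, dyad, distance`` plus one difference column per covariate.
    Task-specific expansion into a model matrix happens at fit time.
    """

    df: pd.DataFrame
    spec: ModelSpec
    metric: str
    tasks: tuple[str, ...]
    scans: tuple[tuple[str, str, str], ...]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_subjects(self) -> int:
        return len(
            set(self.df["subject_1"]).union(self.df["subject_2"])
        )


def _scan_key_frame(df: pd.DataFrame, which: int) -> pd.Series:
    return list(
        zip(df[f"subject_{which}"], df["task"], df[f"rep_{which}"])
    )


def _coerce_distances(distances) -> pd.DataFrame:
    if isinstance(distances, pd.DataFrame):
        return distances.copy()
    rows = []
    for d in distances:
        if not isinstance(d, DistanceValue):
            raise TypeError("distances must be DistanceValue objects or a DataFrame")
        (s1, t1, r1), (s2, t2, r2) = d.key1, d.key2
        if t1 != t2:
            raise ValueError("distance between different tasks cannot enter the design")
        rows.append((s1, t1, r1, s2, r2, d.metric, d.value, d.degenerate))
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


def build_design(
    distances,
    covariates: pd.DataFrame,
    spec: ModelSpec,
    *,
    subject_col: str = "subject",
) -> DesignTable:
    """Assemble the regression design from a distance table and covariates.

    ``distances`` is either an iterable of :class:`~bantor.metrics.DistanceValue`
    or the tidy frame from :func:`~bantor.metrics.pairwise_distance_table`.
    ``covariates`` has one row per subject.  Within-individual rows are
    dropped (the design compares distinct individuals only).
    """
    dist = _coerce_distances(distances)
    if dist["metric"].nunique() > 1:
        raise ValueError(f"mixed metrics in distance table: {sorted(dist['metric'].unique())}")
    metric = dist["metric"].iloc[0] if len(dist) else ""
    dist = dist[dist["subject_1"] != dist["subject_2"]].reset_index(drop=True)

    cov = covariates.copy()
    if subject_col not in cov.columns:
        raise ValueError(f"covariate table lacks a {subject_col!r} column")
    cov[subject_col] = cov[subject_col].astype(str)
    if cov[subject_col].duplicated().any():
        raise ValueError("duplicate subject ids in covariate table")
    cov = cov.set_index(subject_col)

    for c in spec.covariates:
        if c not in cov.columns:
            raise ValueError(f"covariate {c!r} missing from covariate table")
        if cov[c].isna().any():
            raise ValueError(f"covariate {c!r} has missing values")

    for side in ("subject_1", "subject_2"):
        dist[side] = dist[side].astype(str)
        missing = set(dist[side]) - set(cov.index)
        if missing:
            raise ValueError(f"subjects missing from covariate table: {sorted(missing)}")

    df = dist.rename(columns={"value": "distance"})[
        ["task", "subject_1", "rep_1", "subject_2", "rep_2", "distance"]
    ].copy()
    for col in ("task", "rep_1", "rep_2"):
        df[col] = df[col].astype(str)

    for c in spec.covariates:
        x1 = cov[c].reindex(df["subject_1"]).to_numpy()
        x2 = cov[c].reindex(df["subject_2"]).to_numpy()
        if c in spec.categorical or not np.issubdtype(cov[c].dtype, np.number):
            df[c] = (x1 != x2).astype(float)
        else:
            df[c] = np.abs(x1.astype(float) - x2.astype(float))

    lo = np.minimum(df["subject_1"], df["subject_2"])
    hi = np.maximum(df["subject_1"], df["subject_2"])
    df["dyad"] = lo + "|" + hi + "|" + df["task"]
    df["scan_1"] = df["subject_1"] + "." + df["task"] + "." + df["rep_1"]
    df["scan_2"] = df["subject_2"] + "." + df["task"] + "." + df["rep_2"]

    tasks = tuple(sorted(df["task"].unique()))
    scans = tuple(
        sorted(
            {
                (s, t, r)
                for s, t, r in zip(df["subject_1"], df["task"], df["rep_1"])
            }
            | {
                (s, t, r)
                for s, t, r in zip(df["subject_2"], df["task"], df["rep_2"])
            }
        )
    )
    return DesignTable(df=df, spec=spec, metric=metric, tasks=tasks, scans=scans)


def build_distance_matrix(
    distances, task_id, covariates: pd.DataFrame | None = None, *,
    subject_col: str = "subject",
):
    """Assemble the complete per-task scan distance matrix for MDMR.

    Unlike the regression design, MDMR needs a *complete* matrix, so
    within-individual scan pairs must be present in ``distances``.  Scans
    are ordered lexicographically by (subject, repetition).  Returns
    ``(D, scan_index)`` or ``(D, scan_index, X)`` when ``covariates`` is
    given, where ``X`` repeats each subject's covariate row once per
    repetition.
    """
    dist = _coerce_distances(distances)
    dist = dist[dist["task"].astype(str) == str(task_id)]
    if len(dist) == 0:
        raise ValueError(f"no distances for task {task_id!r}")
    for col in ("subject_1", "subject_2", "rep_1", "rep_2"):
        dist[col] = dist[col].astype(str)

    scans = sorted(
        {(s, r) for s, r in zip(dist["subject_1"], dist["rep_1"])}
        | {(s, r) for s, r in zip(dist["subject_2"], dist["rep_2"])}
    )
    index = {sc: i for i, sc in enumerate(scans)}
    n = len(scans)
    D = np.full((n, n), np.nan)
    np.fill_diagonal(D, 0.0)
    for s1, r1, s2, r2, v in zip(
        dist["subject_1"], dist["rep_1"], dist["subject_2"], dist["rep_2"], dist["value"]
    ):
        i, j = index[(s1, r1)], index[(s2, r2)]
        D[i, j] = v
        D[j, i] = v
    if np.isnan(D).any():
        ii, jj = np.where(np.isnan(D))
        missing = sorted({tuple(sorted((scans[i], scans[j]))) for i, j in zip(ii, jj)})
        raise ValueError(
            f"incomplete distance pairings for task {task_id!r}; "
            f"missing e.g. {missing[:5]} ({len(missing)} total)"
        )
    scan_index = pd.DataFrame(scans, columns=["subject", "repetition"])
    if covariates is None:
        return D, scan_index
    cov = covariates.copy()
    cov[subject_col] = cov[subject_col].astype(str)
    cov = cov.set_index(subject_col)
    X = cov.reindex(scan_index["subject"]).reset_index(drop=True)
    return D, scan_index, X
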