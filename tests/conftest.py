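import itertools

import numpy as np
import pandas as pd
import pytest

from bantor.metrics import ConnectionMatrix, validate_connection_matrix


def random_correlation(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random SPD correlation matrix (factor model + rescale)."""
    W = rng.standard_normal((n, max(2, n // 2)))
    A = W @ W.T + np.diag(rng.uniform(0.5, 1.5, n)) * n * 0.2
    d = np.sqrt(np.diag(A))
    C = A / np.outer(d, d)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    return C


def matrix_from_upper(upper, n, diag=1.0):
    """Symmetric matrix with the given row-major upper-triangle entries."""
    M = np.full((n, n), diag) * np.eye(n)
    iu = np.triu_indices(n, k=1)
    M[iu] = upper
    return M + np.triu(M, 1).T


def make_scan(values, subject="s", task="t", rep="r") -> ConnectionMatrix:
    return validate_connection_matrix(values, subject, task, rep)


def fake_distance_frame(n_p, n_t, n_r, rng, include_within=False):
    """Synthetic tidy distance table with random positive values."""
    subjects = [f"s{i}" for i in range(1, n_p + 1)]
    rows = []
    for t in range(1, n_t + 1):
        scans = [(s, f"rep{r}") for s in subjects for r in range(1, n_r + 1)]
        for (s1, r1), (s2, r2) in itertools.combinations(scans, 2):
            if not include_within and s1 == s2:
                continue
            rows.append((s1, f"task{t}", r1, s2, r2, "EUC",
                         float(rng.uniform(0.5, 2.0)), False))
    return pd.DataFrame(
        rows,
        columns=["subject_1", "task", "rep_1", "subject_2", "rep_2",
                 "metric", "value", "degenerate"],
    )


def fake_covariates(n_p, rng):
    subjects = [f"s{i}" for i in range(1, n_p + 1)]
    # deterministic alternation guarantees both levels are populated
    return pd.DataFrame(
        dict(
            subject=subjects,
            SEX=["Female" if i % 2 else "Male" for i in range(n_p)],
            TRT=["Treatment" if (i // 2) % 2 else "Placebo" for i in range(n_p)],
            IQ=np.round(rng.normal(100, 15, n_p)).astype(int),
            AGE=np.round(rng.normal(100, 15, n_p)).astype(int),
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset():
    """Small simulated dataset shared across tests (6 subjects, 48 nodes)."""
    from bantor.simulate import SimConfig, simulate_dataset

    # seed chosen so both SEX and TRT have at least two subjects per level
    # (a singleton level is genuinely collinear with that subject's scans)
    return simulate_dataset(
        SimConfig(n_subjects=6, n_nodes=48, n_timepoints=250, seed=1)
    )
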