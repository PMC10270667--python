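"""Factorial simulation study: type-I error and power across signal levels.

For every combination of signal percentage, distance metric and testing
method, the harness simulates a dataset, computes same-task pairwise
distances, fits the regression, and records whether each covariate's
p-value falls below the nominal level.  Rejection rates over replicates
estimate type-I error (for the null covariates ``AGE`` and ``SEX``) and
power (for ``IQ`` and ``TRT``, which drive the generative signal), together
with their binomial Monte-Carlo standard errors, and the smallest signal
percentage at which power reaches a threshold (default 80%).

The default configuration is a reduced profile (30 subjects, 60 nodes, 200
replicates) sized for desk runs; :meth:`StudyConfig.paper_scale` switches to
the full factorial design (100 subjects, 268 nodes, 2,500 replicates),
which needs long parallel runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import ModelSpec, build_design, build_distance_matrix
from .inference import fit_3m_bantor, fit_f_test, fit_f_test_sle, mdmr_permutation
from .metrics import pairwise_distance_table
from .simulate import SimConfig, simulate_dataset

__all__ = ["StudyConfig", "StudyResult", "run_study", "power_crossing"]

MODEL_SPEC = ModelSpec(
    covariate_of_interest="IQ",
    confounders=("AGE", "SEX", "TRT"),
    categorical=("SEX", "TRT"),
)

NULL_COVARIATES = ("AGE", "SEX")
SIGNAL_COVARIATES = ("IQ", "TRT")


@dataclass(frozen=True)
class StudyConfig:
    """Parameterization of the factorial simulation experiment.

    ``metrics`` entries are metric names, with Jaccard thresholds appended
    after a colon (``"JACCARD:0.005"`` = top 0.5% of edges).  ``signal_grid``
    is in percent.
    """

    replicates: int = 200
    signal_grid: tuple[float, ...] = tuple(range(0, 101, 10))
    metrics: tuple[str, ...] = ("EUC",)
    methods: tuple[str, ...] = ("f_test", "f_test_sle", "3m_bantor")
    alpha: float = 0.05
    power_threshold: float = 0.80
    sim: SimConfig = field(default_factory=lambda: SimConfig(n_subjects=30, n_nodes=60))
    mdmr_permutations: int = 5000
    n_jobs: int = 1
    seed: int = 0

    @classmethod
    def paper_scale(cls, seed: int = 0, n_jobs: int = 1) -> "StudyConfig":
        """The full factorial design (cluster-scale compute)."""
        return cls(
            replicates=2500,
            signal_grid=tuple(range(0, 101, 10)),
            metrics=("KS", "JACCARD:0.2", "JACCARD:0.005", "EUC", "PCD", "LERM"),
            methods=("f_test", "f_test_sle", "3m_bantor", "mdmr"),
            sim=SimConfig(n_subjects=100, n_nodes=268),
            n_jobs=n_jobs,
            seed=seed,
        )


@dataclass
class StudyResult:
    """Tidy rejection-rate records plus the raw per-replicate p-values."""

    rates: pd.DataFrame
    pvalues: pd.DataFrame
    config: StudyConfig
    failures: list = field(default_factory=list)

    def crossing_table(self, threshold: float | None = None) -> pd.DataFrame:
        return power_crossing(self, threshold or self.config.power_threshold)


def _parse_metric(spec: str):
    if ":" in spec:
        name, frac = spec.split(":", 1)
        return name.upper(), float(frac)
    return spec.upper(), None


def _replicate_seed(master: int, signal_idx: int, rep: int) -> int:
    ss = np.random.SeedSequence([int(master), int(signal_idx), int(rep)])
    return int(ss.generate_state(1)[0])


def _run_replicate(config: StudyConfig, signal_idx: int, rep: int) -> list[tuple]:
    sp = config.signal_grid[signal_idx] / 100.0
    sim = replace(
        config.sim,
        signal_percent=sp,
        seed=_replicate_seed(config.seed, signal_idx, rep),
    )
    ds = simulate_dataset(sim)
    need_within = "mdmr" in config.methods
    rows = []
    for mspec in config.metrics:
        metric, frac = _parse_metric(mspec)
        dist = pairwise_distance_table(
            ds.scans, metric, threshold_fraction=frac, include_within=need_within
        )
        design = build_design(dist, ds.covariates, MODEL_SPEC)
        for method in config.methods:
            if method == "mdmr":
                for task in design.tasks:
                    D, _, Xp = build_distance_matrix(dist, task, ds.covariates)
                    res = mdmr_permutation(
                        D,
                        Xp[list(MODEL_SPEC.covariates)],
                        config.mdmr_permutations,
                        seed=_replicate_seed(config.seed, signal_idx, rep) + 1,
                    )
                    for r in res:
                        term = r.predictor.split("[")[0]
                        rows.append(
                            (config.signal_grid[signal_idx], rep, task, mspec,
                             method, term, r.p)
                        )
                continue
            if method == "f_test":
                fit = fit_f_test(design)
            elif method == "f_test_sle":
                fit = fit_f_test_sle(design)
            elif method == "3m_bantor":
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_3m_bantor(design)
            else:
                raise ValueError(f"unknown method {method!r}")
            for e in fit.estimates:
                if e.term == "Intercept":
                    continue
                rows.append(
                    (config.signal_grid[signal_idx], rep, e.task_id, mspec,
                     method, e.term, e.p)
                )
    return rows


def run_study(config: StudyConfig) -> StudyResult:
    """Run the factorial experiment and aggregate rejection rates.

    Per-replicate seeds derive from (master seed, signal level, replicate),
    so the result is deterministic and any cell can be reproduced alone.
    Individual replicate failures are recorded and tolerated up to 5% of
    the total, beyond which the study aborts.
    """
    cells = [
        (si, rep)
        for si in range(len(config.signal_grid))
        for rep in range(config.replicates)
    ]
    all_rows: list[tuple] = []
    failures: list = []

    if config.n_jobs != 1:
        from joblib import Parallel, delayed

        outs = Parallel(n_jobs=config.n_jobs)(
            delayed(_safe_replicate)(config, si, rep) for si, rep in cells
        )
    else:
        outs = [_safe_replicate(config, si, rep) for si, rep in cells]

    for (si, rep), (rows, err) in zip(cells, outs):
        if err is not None:
            failures.append((config.signal_grid[si], rep, err))
        else:
            all_rows.extend(rows)
    if len(failures) > 0.05 * len(cells):
        raise RuntimeError(
            f"{len(failures)} of {len(cells)} replicates failed; first: {failures[0]}"
        )

    pvals = pd.DataFrame(
        all_rows,
        columns=["signal", "replicate", "task", "metric", "method", "term", "p"],
    )
    grp = pvals.groupby(["signal", "task", "metric", "method", "term"], sort=True)
    rates = grp["p"].agg(
        rate=lambda p: float(np.mean(p < config.alpha)), n="count"
    ).reset_index()
    rates["mc_se"] = np.sqrt(rates["rate"] * (1 - rates["rate"]) / rates["n"])
    return StudyResult(rates=rates, pvalues=pvals, config=config, failures=failures)


def _safe_replicate(config, si, rep):
    try:
        return _run_replicate(config, si, rep), None
    except Exception as exc:  # recorded; study continues
        return None, repr(exc)


def power_crossing(result: StudyResult, threshold: float = 0.80) -> pd.DataFrame:
    """First signal percentage with rejection rate >= threshold.

    ``crossing`` is NaN ("never") when the threshold is not reached;
    ``dips_after_crossing`` flags non-monotone curves that fall back below
    the threshold after first crossing it.
    """
    rows = []
    for key, sub in result.rates.groupby(["task", "metric", "method", "term"]):
        sub = sub.sort_values("signal")
        above = sub["rate"].to_numpy() >= threshold
        if above.any():
            first = int(np.argmax(above))
            crossing = float(sub["signal"].iloc[first])
            dips = bool((~above[first:]).any())
        else:
            crossing, dips = float("nan"), False
        rows.append((*key, crossing, dips))
    return pd.DataFrame(
        rows,
        columns=["task", "metric", "method", "term", "crossing", "dips_after_crossing"],
    )
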