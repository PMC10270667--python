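"""Tests for the three regression fits, REML internals, and MDMR."""

import subprocess
import shutil
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from bantor.design import ModelSpec, build_design
from bantor.inference import (
    build_model_matrix,
    fit_3m_bantor,
    fit_f_test,
    fit_f_test_sle,
    mdmr_permutation,
)
from bantor.reml import fit_grouped_reml

from conftest import fake_covariates, fake_distance_frame

SPEC = ModelSpec("IQ", ("AGE", "SEX", "TRT"), ("SEX", "TRT"))


def make_design(n_p, n_t, n_r, rng, cov=None):
    dist = fake_distance_frame(n_p, n_t, n_r, rng)
    cov = fake_covariates(n_p, rng) if cov is None else cov
    return build_design(dist, cov, SPEC), cov


def inject_linear_signal(design, cov, slope=2.0, noise=0.0, rng=None):
    """Overwrite distances with an exact (or noisy) linear function of IQ diff."""
    y = 1.0 + slope * design.df["IQ"].to_numpy()
    if noise:
        y = y + noise * rng.standard_normal(len(y))
    design.df["distance"] = y
    return design


def simulate_from_mixed_model(design, beta_iq, g_by_task, sigma2, rng):
    """Generate distances from the mixed model itself (scan effects zero)."""
    df = design.df
    y = 0.5 + beta_iq * df["IQ"].to_numpy()
    dyads, inv = np.unique(df["dyad"].to_numpy(), return_inverse=True)
    task_of_dyad = np.array([d.rsplit("|", 1)[1] for d in dyads])
    sd = np.sqrt([g_by_task[t] for t in task_of_dyad])
    b = rng.standard_normal(len(dyads)) * sd
    y = y + b[inv] + np.sqrt(sigma2) * rng.standard_normal(len(df))
    out = design.df.copy()
    new = design.__class__(df=out, spec=design.spec, metric=design.metric,
                           tasks=design.tasks, scans=design.scans)
    new.df["distance"] = y
    return new


class TestFTest:
    def test_exact_linear_recovery(self, rng):
        design, cov = make_design(8, 2, 2, rng)
        inject_linear_signal(design, cov, slope=2.0)
        fit = fit_f_test(design)
        est = fit.to_frame()
        iq = est[est.term == "IQ"]
        np.testing.assert_allclose(iq["estimate"], 2.0, atol=1e-8)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_null_pvalues_uniform(self, rng):
        # single-scan single-task design: iid noise really is the truth
        design, cov = make_design(10, 1, 1, rng)
        pvals = []
        for _ in range(1000):
            design.df["distance"] = rng.standard_normal(len(design))
            est = fit_f_test(design).to_frame()
            pvals.append(float(est.loc[est.term == "IQ", "p"].iloc[0]))
        stat = scipy.stats.kstest(pvals, "uniform")
        assert stat.pvalue > 1e-3

    def test_single_task_block_separability(self, rng):
        design, cov = make_design(6, 2, 2, rng)
        full = fit_f_test(design).to_frame()
        sub_dist = fake_distance_frame(6, 2, 2, rng)
        # refit task1 alone from the same distances
        d1 = design.df[design.df.task == "task1"]
        only = design.__class__(
            df=d1.reset_index(drop=True), spec=design.spec,
            metric=design.metric, tasks=("task1",),
            scans=tuple(k for k in design.scans if k[1] == "task1"),
        )
        alone = fit_f_test(only).to_frame()
        merged = full[full.task == "task1"].merge(alone, on=["task", "term"],
                                                 suffixes=("_full", "_alone"))
        np.testing.assert_allclose(
            merged["estimate_full"], merged["estimate_alone"], atol=1e-10
        )


class TestSLE:
    def test_scan_offset_absorbed(self, rng):
        design, cov = make_design(6, 1, 2, rng)
        base = fit_f_test_sle(design)
        target = design.scans[0]
        sub, task, rep = target
        hit = (
            ((design.df.subject_1 == sub) & (design.df.rep_1 == rep))
            | ((design.df.subject_2 == sub) & (design.df.rep_2 == rep))
        )
        design.df.loc[hit, "distance"] += 5.0
        bumped = fit_f_test_sle(design)
        b0 = base.to_frame().set_index(["task", "term"])
        b1 = bumped.to_frame().set_index(["task", "term"])
        np.testing.assert_allclose(b0["estimate"], b1["estimate"], atol=1e-8)
        key = ".".join(target)
        if key in base.scan_effects.index:
            assert bumped.scan_effects[key] - base.scan_effects[key] == pytest.approx(
                5.0, abs=1e-6
            )

    def test_known_beta_recovered_with_scan_offsets(self, rng):
        design, cov = make_design(12, 2, 2, rng)
        df = design.df
        scan_alpha = {".".join(k): rng.normal(0, 0.5) for k in design.scans}
        y = (
            1.0
            + 0.1 * df["IQ"].to_numpy()
            + np.array([scan_alpha[s] for s in df["scan_1"]])
            + np.array([scan_alpha[s] for s in df["scan_2"]])
            + 0.2 * rng.standard_normal(len(df))
        )
        df["distance"] = y
        est = fit_f_test_sle(design).to_frame()
        iq = est[est.term == "IQ"]
        for _, row in iq.iterrows():
            assert abs(row.estimate - 0.1) < 3 * row.se

    def test_subject_relabeling_invariance(self, rng):
        # relabeling changes which scan is the dropped reference; covariate
        # inference must not change
        dist = fake_distance_frame(6, 1, 2, rng)
        cov = fake_covariates(6, rng)
        d1 = build_design(dist, cov, SPEC)
        y = rng.standard_normal(len(d1))
        d1.df["distance"] = y
        mapping = {f"s{i}": f"z{7-i}" for i in range(1, 7)}
        dist2 = dist.copy()
        dist2["subject_1"] = dist2["subject_1"].map(mapping)
        dist2["subject_2"] = dist2["subject_2"].map(mapping)
        cov2 = cov.copy()
        cov2["subject"] = cov2["subject"].map(mapping)
        d2 = build_design(dist2, cov2, SPEC)
        # transfer the responses by matching scan pairs across the relabeling
        inverse = {v: k for k, v in mapping.items()}
        d2.df["sort_key"] = [
            "|".join(sorted([f"{a}.{r1}", f"{b}.{r2}"]))
            for a, r1, b, r2 in zip(
                d2.df.subject_1.map(inverse), d2.df.rep_1,
                d2.df.subject_2.map(inverse), d2.df.rep_2)
        ]
        d1.df["sort_key"] = [
            "|".join(sorted([f"{a}.{r1}", f"{b}.{r2}"]))
            for a, r1, b, r2 in zip(d1.df.subject_1, d1.df.rep_1,
                                    d1.df.subject_2, d1.df.rep_2)
        ]
        d2.df = d2.df.set_index("sort_key")
        d2.df["distance"] = d1.df.set_index("sort_key")["distance"]
        d2.df = d2.df.reset_index(drop=True)
        e1 = fit_f_test_sle(d1).to_frame().set_index(["task", "term"])
        e2 = fit_f_test_sle(d2).to_frame().set_index(["task", "term"])
        # the intercept trades off against whichever reference scan was
        # dropped; covariate inference must be identification-invariant
        e1 = e1[e1.index.get_level_values("term") != "Intercept"]
        e2 = e2[e2.index.get_level_values("term") != "Intercept"]
        np.testing.assert_allclose(e1["estimate"], e2["estimate"], atol=1e-8)
        np.testing.assert_allclose(e1["se"], e2["se"], atol=1e-8)

    def test_collinear_covariate_errors(self, rng):
        dist = fake_distance_frame(5, 1, 2, rng)
        cov = fake_covariates(5, rng)
        cov["SEX"] = ["Male", "Female", "Female", "Female", "Female"]
        design = build_design(dist, cov, SPEC)
        with pytest.raises(ValueError, match="SEX.*collinear"):
            fit_f_test_sle(design)


class TestMixedModel:
    def test_degenerate_equals_sle(self, rng):
        design, cov = make_design(8, 1, 1, rng)
        design.df["distance"] = rng.standard_normal(len(design)) + 1.0
        with pytest.warns(UserWarning, match="random effects"):
            mm = fit_3m_bantor(design)
        assert mm.degenerate
        sle = fit_f_test_sle(design)
        m1 = mm.to_frame().set_index(["task", "term"])
        m2 = sle.to_frame().set_index(["task", "term"])
        pd.testing.assert_frame_equal(m1, m2)

    def test_reml_objective_monotone(self, rng):
        design, cov = make_design(8, 2, 2, rng)
        design = simulate_from_mixed_model(
            design, 0.05, {"task1": 0.3, "task2": 0.1}, 0.2, rng
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_3m_bantor(design)
        hist = np.asarray(fit.history)
        assert np.all(np.diff(hist) <= 1e-8)
        assert fit.converged

    def test_parameter_recovery_small(self, rng):
        truth_g = {"task1": 0.3, "task2": 0.15, "task3": 0.05}
        sigma2 = 0.1
        beta_iq = 0.05
        design, cov = make_design(12, 3, 2, rng)
        n_rep = 40
        iq_hat, g_hat, s2_hat = [], [], []
        for _ in range(n_rep):
            d = simulate_from_mixed_model(design, beta_iq, truth_g, sigma2, rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_3m_bantor(d)
            est = fit.to_frame()
            iq_hat.append(est.loc[est.term == "IQ", "estimate"].mean())
            g_hat.append([fit.g[t] for t in ("task1", "task2", "task3")])
            s2_hat.append(fit.sigma2)
        iq_hat = np.array(iq_hat)
        assert abs(iq_hat.mean() - beta_iq) < 3 * iq_hat.std(ddof=1) / np.sqrt(n_rep)
        g_hat = np.array(g_hat)
        for k, t in enumerate(("task1", "task2", "task3")):
            se = g_hat[:, k].std(ddof=1) / np.sqrt(n_rep)
            assert abs(g_hat[:, k].mean() - truth_g[t]) < 3 * se + 1e-3
        s2_hat = np.array(s2_hat)
        assert abs(s2_hat.mean() - sigma2) < 3 * s2_hat.std(ddof=1) / np.sqrt(n_rep)

    def test_task_specific_residual_option(self, rng):
        design, cov = make_design(8, 2, 2, rng)
        design = simulate_from_mixed_model(
            design, 0.03, {"task1": 0.2, "task2": 0.1}, 0.15, rng
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shared = fit_3m_bantor(design)
            tsr = fit_3m_bantor(design, task_specific_residual=True)
        assert tsr.converged
        # the richer model can only improve the restricted likelihood
        assert tsr.loglik >= shared.loglik - 1e-6
        e1 = shared.to_frame().set_index(["task", "term"])["estimate"]
        e2 = tsr.to_frame().set_index(["task", "term"])["estimate"]
        np.testing.assert_allclose(e1, e2, atol=0.05)

    def test_row_order_invariance(self, rng):
        design, cov = make_design(8, 2, 2, rng)
        design.df["distance"] = rng.standard_normal(len(design)) + 2.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e1 = fit_3m_bantor(design).to_frame().set_index(["task", "term"])
            shuffled = design.__class__(
                df=design.df.sample(frac=1.0, random_state=0).reset_index(drop=True),
                spec=design.spec, metric=design.metric,
                tasks=design.tasks, scans=design.scans,
            )
            e2 = fit_3m_bantor(shuffled).to_frame().set_index(["task", "term"])
        # estimates agree tightly; p-values inherit small optimizer-path
        # differences through the finite-difference Satterthwaite step
        np.testing.assert_allclose(e1["estimate"], e2["estimate"], atol=1e-6)
        np.testing.assert_allclose(e1["p"], e2["p"], atol=1e-3)


class TestSatterthwaite:
    def test_balanced_two_group_toy_matches_classical_df(self):
        # balanced one-way random-intercept design with a group-level binary
        # covariate: the classical df for its t test is (#groups - 2)
        rng = np.random.default_rng(5)
        q, m = 10, 6
        x_group = np.repeat([0.0, 1.0], q // 2)
        groups = np.repeat(np.arange(q), m)
        X = np.column_stack([np.ones(q * m), x_group[groups]])
        g_true, s2_true = 1.0, 0.25
        y = (
            0.3 * X[:, 1]
            + np.sqrt(g_true) * rng.standard_normal(q)[groups]
            + np.sqrt(s2_true) * rng.standard_normal(q * m)
        )
        fit = fit_grouped_reml(X, y, groups, np.zeros(q, dtype=int), 1)
        assert not fit.boundary.any()
        df = fit.satterthwaite_df(np.array([[0.0, 1.0]]))[0]
        assert df == pytest.approx(q - 2, abs=1e-6)

    def test_boundary_variance_gives_residual_df(self, rng):
        design, cov = make_design(8, 1, 2, rng)
        # pure iid noise: dyad variance should pin at zero
        design.df["distance"] = rng.standard_normal(len(design))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_3m_bantor(design)
        if all(fit.boundary.values()):
            est = fit.to_frame()
            sle = fit_f_test_sle(design)
            resid_df = sle.n_obs - sle.rank
            assert est["df"].max() == pytest.approx(resid_df, rel=0.05)


class TestAgainstReferenceImplementations:
    def test_matches_lme4_lmerTest(self, tmp_path, small_dataset):
        """Estimates, SEs, variance components, REML logLik and
        Satterthwaite p-values agree with lme4/lmerTest on a small fit."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; lme4 oracle cannot run")
        from bantor.metrics import pairwise_distance_table
        from bantor.inference import _identify_columns

        dist = pairwise_distance_table(small_dataset.scans, "EUC")
        design = build_design(dist, small_dataset.covariates, SPEC)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_3m_bantor(design)
        X, names, meta = build_model_matrix(design, scan_effects=True)
        X, names, _ = _identify_columns(X, names, meta["n_covariate_cols"])
        df = pd.DataFrame(np.asarray(X.todense()),
                          columns=[f"c{i}" for i in range(len(names))])
        df["y"] = design.df["distance"].to_numpy()
        df["dyad"] = design.df["dyad"].to_numpy()
        df["task"] = design.df["task"].to_numpy()
        data_csv = tmp_path / "d.csv"
        df.to_csv(data_csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            """
            suppressMessages({library(lme4); library(lmerTest)})
            a <- commandArgs(trailingOnly=TRUE)
            d <- read.csv(a[1])
            xcols <- grep("^c", names(d), value=TRUE)
            for (t in unique(d$task)) d[[paste0("I", t)]] <- as.numeric(d$task == t)
            re <- paste(sprintf("(0+I%s|dyad)", unique(d$task)), collapse=" + ")
            form <- as.formula(paste("y ~ 0 +", paste(xcols, collapse="+"), "+", re))
            m <- lmerTest::lmer(form, data=d, REML=TRUE,
                control=lmerControl(check.nobs.vs.nlev="ignore",
                                    check.nobs.vs.nRE="ignore"))
            s <- as.data.frame(summary(m)$coefficients)
            s$col <- rownames(s)
            write.csv(s, a[2], row.names=FALSE)
            vc <- as.data.frame(VarCorr(m))
            write.csv(vc, a[3], row.names=FALSE)
            cat(as.numeric(logLik(m)), "\\n")
            """
        )
        out_est = tmp_path / "est.csv"
        out_vc = tmp_path / "vc.csv"
        res = subprocess.run(
            ["Rscript", str(rscript), str(data_csv), str(out_est), str(out_vc)],
            capture_output=True, text=True, timeout=600,
        )
        assert res.returncode == 0, res.stderr
        r_ll = float(res.stdout.strip().split()[-1])
        assert fit.loglik == pytest.approx(r_ll, abs=1e-3)

        r_est = pd.read_csv(out_est)
        r_est["name"] = [names[int(c[1:])] for c in r_est["col"]]
        mine = fit.to_frame()
        mine["name"] = mine["term"] + "[" + mine["task"] + "]"
        merged = mine.merge(r_est, on="name")
        assert len(merged) == len(mine)
        np.testing.assert_allclose(merged["estimate"], merged["Estimate"],
                                   rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(merged["se"], merged["Std. Error"],
                                   rtol=1e-3)
        np.testing.assert_allclose(merged["p"], merged["Pr(>|t|)"],
                                   rtol=0.02, atol=1e-4)
        r_vc = pd.read_csv(out_vc)
        r_resid = float(r_vc.loc[r_vc["grp"] == "Residual", "vcov"].iloc[0])
        assert fit.sigma2 == pytest.approx(r_resid, rel=1e-3)
        for t in ("task1", "task2", "task3"):
            r_g = float(r_vc.loc[r_vc["var1"] == f"I{t}", "vcov"].iloc[0])
            assert fit.g[t] == pytest.approx(r_g, rel=5e-3, abs=1e-4)

    def test_pooled_variance_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.formula.api as smf

        design, cov = make_design(8, 2, 2, rng)
        design = simulate_from_mixed_model(
            design, 0.03, {"task1": 0.2, "task2": 0.2}, 0.15, rng
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_3m_bantor(design, pooled_dyad_variance=True)
        df = design.df.copy()
        import statsmodels.api as sm
        from bantor.inference import _identify_columns

        X, names, meta = build_model_matrix(design, scan_effects=True)
        X, names, _ = _identify_columns(X, names, meta["n_covariate_cols"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(df["distance"].to_numpy(), np.asarray(X.todense()),
                            groups=df["dyad"].to_numpy())
            sm_fit = md.fit(reml=True, method="lbfgs", maxiter=500)
        mine = fit.to_frame()
        mine["name"] = mine["term"] + "[" + mine["task"] + "]"
        for _, row in mine.iterrows():
            j = names.index(row["name"])
            assert row["estimate"] == pytest.approx(sm_fit.fe_params[j], abs=1e-5)
            assert row["se"] == pytest.approx(sm_fit.bse_fe[j], rel=1e-3)
        g_sm = float(np.asarray(sm_fit.cov_re)[0, 0])
        assert fit.g["task1"] == pytest.approx(g_sm, rel=5e-3, abs=1e-5)
        assert fit.sigma2 == pytest.approx(float(sm_fit.scale), rel=5e-3)


class TestMDMR:
    def test_univariate_euclidean_matches_classical_f(self, rng):
        n = 40
        x = rng.standard_normal(n)
        y = 0.7 * x + rng.standard_normal(n)
        D = np.abs(y[:, None] - y[None, :])
        res = mdmr_permutation(D, x[:, None], n_perm=999, seed=1)
        # classical F for the univariate regression
        import scipy.stats as st

        X = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ssr = np.sum((X @ beta - y.mean()) ** 2)
        f_classical = ssr / (resid @ resid / (n - 2))
        assert res[0].pseudo_f == pytest.approx(f_classical, rel=1e-10)
        p_classical = st.f.sf(f_classical, 1, n - 2)
        assert abs(res[0].p - p_classical) < 0.05

    def test_single_permutation_boundary(self, rng):
        n = 12
        y = rng.standard_normal(n)
        D = np.abs(y[:, None] - y[None, :])
        res = mdmr_permutation(D, rng.standard_normal((n, 1)), n_perm=1, seed=0)
        assert res[0].p in (0.5, 1.0)

    def test_null_pvalues_roughly_uniform(self, rng):
        n = 25
        pvals = []
        for _ in range(60):
            y = rng.standard_normal(n)
            D = np.abs(y[:, None] - y[None, :])
            res = mdmr_permutation(D, rng.standard_normal((n, 1)), n_perm=99,
                                   seed=int(rng.integers(2**31)))
            pvals.append(res[0].p)
        assert 0.3 < np.mean(pvals) < 0.7

    def test_input_validation(self, rng):
        D = np.abs(rng.standard_normal((5, 5)))
        with pytest.raises(ValueError, match="symmetric"):
            mdmr_permutation(D, rng.standard_normal((5, 1)), 10)
        Ds = D + D.T
        np.fill_diagonal(Ds, 0)
        with pytest.raises(ValueError, match="n_perm"):
            mdmr_permutation(Ds, rng.standard_normal((5, 1)), 0)
        X = np.ones((5, 2))
        with pytest.raises(ValueError, match="rank"):
            mdmr_permutation(Ds, X, 10)
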