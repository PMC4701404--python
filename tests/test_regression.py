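import json
import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from metaepi import coding, pooling, regression
from metaepi.accuracy import accuracy_from_table
from metaepi.core_data import MetaAnalysisSet, TwoByTwoTable
from .conftest import make_study


def wls_oracle(X, y, w):
    """Independent normal-equations solver built element-by-element."""
    n, p = X.shape
    A = np.zeros((p, p))
    b = np.zeros(p)
    for i in range(n):
        for j in range(p):
            b[j] += w[i] * X[i, j] * y[i]
            for k in range(p):
                A[j, k] += w[i] * X[i, j] * X[i, k]
    beta = np.linalg.solve(A, b)
    cov = np.linalg.inv(A)
    q = sum(w[i] * (y[i] - X[i] @ beta) ** 2 for i in range(n))
    return beta, np.sqrt(np.diag(cov)), q


def _stats(ma_set):
    acc = [accuracy_from_table(st.table) for st in ma_set.studies]
    return (
        np.array([a.d for a in acc]),
        np.array([a.s for a in acc]),
        np.array([a.var_ln_dor for a in acc]),
    )


class TestFitAgainstOracle:
    def test_fixed_effect_matches_normal_equations(self, six_study_set):
        schemes = coding.multivariable_scheme()
        matrix, _ = coding.drop_invariant_covariates(
            coding.encode(six_study_set, schemes)
        )
        f = regression.fit(six_study_set, matrix, weighting="fixed_effect")
        d, s, v = _stats(six_study_set)
        X = np.column_stack([np.ones(6), s, matrix.to_numpy(float)])
        beta, se, _ = wls_oracle(X, d, 1.0 / v)
        np.testing.assert_allclose(f.beta, beta, atol=1e-10)
        np.testing.assert_allclose(f.se, se, atol=1e-10)

    def test_random_effects_matches_moment_oracle(self, six_study_set):
        schemes = coding.multivariable_scheme()
        matrix, _ = coding.drop_invariant_covariates(
            coding.encode(six_study_set, schemes)
        )
        f = regression.fit(six_study_set, matrix, weighting="random_effects")
        d, s, v = _stats(six_study_set)
        X = np.column_stack([np.ones(6), s, matrix.to_numpy(float)])
        w = 1.0 / v
        beta_fe, _, q = wls_oracle(X, d, w)
        W = np.diag(w)
        H = W @ X @ np.linalg.inv(X.T @ W @ X) @ X.T @ W
        tr_p = np.trace(W - H)
        tau2 = max(0.0, (q - (6 - X.shape[1])) / tr_p)
        assert f.tau2_reg == pytest.approx(tau2, abs=1e-10)
        beta_re, se_re, _ = wls_oracle(X, d, 1.0 / (v + tau2))
        np.testing.assert_allclose(f.beta, beta_re, atol=1e-10)
        np.testing.assert_allclose(f.se, se_re, atol=1e-10)


class TestFitExactCases:
    def test_noiseless_group_offset_recovered_exactly(self):
        # Two groups, each with the same two S values; group B's ln DOR is
        # exactly ln 4 above group A at every threshold: the fit interpolates.
        counts = [
            (20, 20, 20, 20),  # d=0,   s=0
            (30, 30, 10, 10),  # d=0,   s=2 logit(.75)
            (40, 20, 20, 40),  # d=ln4, s=0
            (60, 6, 10, 4),    # d=ln4, s=2 logit(.75)
        ]
        studies = tuple(
            make_study(f"s{i}", "m", *c) for i, c in enumerate(counts)
        )
        ma = MetaAnalysisSet("m", studies)
        matrix = pd.DataFrame(
            {"flaw": [0, 0, 1, 1]}, index=[f"s{i}" for i in range(4)]
        )
        for mode in ("fixed_effect", "random_effects", "unweighted"):
            f = regression.fit(ma, matrix, weighting=mode)
            assert f.gamma("flaw") == pytest.approx(math.log(4), abs=1e-10)
            assert f.slope_s == pytest.approx(0.0, abs=1e-10)
            assert f.intercept == pytest.approx(0.0, abs=1e-10)

    def test_threshold_only_model_without_s_is_ivw_mean(self, six_study_set):
        """No covariates, no S term: the fit is the FE pooled mean of ln DOR."""
        f = regression.fit(
            six_study_set, None, weighting="fixed_effect", include_threshold=False
        )
        d, _, v = _stats(six_study_set)
        eff = pooling.pool(list(zip(d, np.sqrt(v))), model="fixed_effect")
        assert f.intercept == pytest.approx(eff.theta, rel=1e-12)
        assert float(f.se[0]) == pytest.approx(eff.se, rel=1e-12)

    def test_df_below_one_refused(self):
        studies = tuple(
            make_study(f"s{i}", "m", 10 + i, 5, 5, 20) for i in range(2)
        )
        with pytest.raises(regression.DegreesOfFreedomError):
            regression.fit(MetaAnalysisSet("m", studies), None)

    def test_collinear_design_names_columns(self, six_study_set):
        matrix = coding.encode(six_study_set, coding.multivariable_scheme())
        # keep a constant column: collinear with the intercept
        with pytest.raises(regression.CollinearityError):
            regression.fit(six_study_set, matrix)


class TestFitProperties:
    def test_random_effects_se_not_below_fixed(self, six_study_set):
        matrix, _ = coding.drop_invariant_covariates(
            coding.encode(six_study_set, coding.multivariable_scheme())
        )
        fe = regression.fit(six_study_set, matrix, weighting="fixed_effect")
        re = regression.fit(six_study_set, matrix, weighting="random_effects")
        assert np.all(re.se >= fe.se - 1e-12)

    def test_shift_in_d_moves_only_intercept(self, rng):
        n = 10
        d = rng.normal(2.0, 0.5, n)
        s = rng.normal(0, 1, n)
        v = rng.uniform(0.1, 0.5, n)
        z = rng.integers(0, 2, n).astype(float)
        f0 = regression.fit_arrays(d, s, v, z[:, None], ["z"], "random_effects")
        f1 = regression.fit_arrays(d + 1.7, s, v, z[:, None], ["z"], "random_effects")
        assert f1.intercept - f0.intercept == pytest.approx(1.7, abs=1e-9)
        assert f1.slope_s == pytest.approx(f0.slope_s, abs=1e-9)
        assert f1.gamma("z") == pytest.approx(f0.gamma("z"), abs=1e-9)

    def test_mean_gamma_recovers_injected_effect(self, rng):
        """Parameter recovery of the stage-1 estimator alone."""
        true_gamma = 0.9
        est = []
        for _ in range(300):
            n = 14
            z = rng.integers(0, 2, n).astype(float)
            s = rng.normal(0, 1, n)
            v = rng.uniform(0.1, 0.4, n)
            d = 2.0 + 0.1 * s + true_gamma * z + rng.normal(0, np.sqrt(v))
            f = regression.fit_arrays(d, s, v, z[:, None], ["z"], "fixed_effect")
            est.append(f.gamma("z"))
        mean = np.mean(est)
        mc_err = np.std(est) / np.sqrt(len(est))
        assert abs(mean - true_gamma) < 4 * mc_err + 1e-3


class TestRdor:
    def test_closed_form_ci(self):
        fit_ = regression.MetaRegressionFit(
            meta_id="m",
            names=["intercept", "s", "flaw"],
            beta=np.array([0.0, 0.0, 0.7885]),
            se=np.array([0.1, 0.1, 0.3]),
            cov=np.eye(3),
            n_studies=6,
            df=3,
            tau2_reg=0.0,
            weighting="fixed_effect",
        )
        res = regression.rdor(fit_, "flaw", level=0.95)
        z = norm.ppf(0.975)
        assert res.rdor == pytest.approx(math.exp(0.7885), rel=1e-12)
        assert res.rdor == pytest.approx(2.2, abs=0.01)
        assert res.ci_low == pytest.approx(math.exp(0.7885 - z * 0.3), rel=1e-12)
        assert res.ci_high == pytest.approx(math.exp(0.7885 + z * 0.3), rel=1e-12)
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (1.22, 3.96)

    def test_zero_gamma_gives_unit_rdor(self):
        fit_ = regression.MetaRegressionFit(
            "m", ["intercept", "flaw"], np.zeros(2), np.array([0.1, 0.0]),
            np.eye(2), 5, 3, 0.0, "fixed_effect",
        )
        res = regression.rdor(fit_, "flaw")
        assert res.rdor == pytest.approx(1.0)
        assert res.ci_low == res.ci_high == pytest.approx(1.0)

    def test_dropped_covariate_not_estimable(self):
        fit_ = regression.MetaRegressionFit(
            "m", ["intercept"], np.zeros(1), np.ones(1), np.eye(1), 5, 4,
            0.0, "fixed_effect", dropped=["flaw"],
        )
        res = regression.rdor(fit_, "flaw")
        assert isinstance(res, regression.NotEstimable)
        assert "constant" in res.reason


class TestAgainstMetafor:
    def test_dl_meta_regression_matches_metafor(self):
        d = [2.1, 4.9, 0.7, 3.4, 1.5, 4.0, 2.8, 0.9]
        s = [0.3, -0.5, 1.1, 0.2, -0.8, 0.6, 1.4, -1.1]
        v = [0.25, 0.4, 0.3, 0.5, 0.2, 0.35, 0.3, 0.45]
        z = [0, 1, 0, 1, 1, 0, 1, 0]
        f = regression.fit_arrays(
            np.array(d), np.array(s), np.array(v),
            np.array(z, float)[:, None], ["flaw"], "random_effects",
        )
        script = textwrap.dedent(f"""
            suppressMessages(library(metafor))
            suppressMessages(library(jsonlite))
            yi <- c({','.join(map(str, d))})
            si <- c({','.join(map(str, s))})
            vi <- c({','.join(map(str, v))})
            z  <- c({','.join(map(str, z))})
            re <- rma(yi, vi, mods = ~ si + z, method="DL")
            cat(toJSON(list(b=as.numeric(re$beta), se=as.numeric(re$se),
                            tau2=re$tau2), digits=14))
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        np.testing.assert_allclose(f.beta, ref["b"], rtol=1e-8)
        np.testing.assert_allclose(f.se, ref["se"], rtol=1e-8)
        assert f.tau2_reg == pytest.approx(ref["tau2"][0], rel=1e-8)
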