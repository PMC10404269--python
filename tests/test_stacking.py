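"""Stacking models: penalized solver, covariate base, trees, simplification."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from multipgs import stacking as st
from multipgs._glmnet import cv_enet, enet_path


@pytest.fixture(scope="module")
def toy_library():
    rng = np.random.default_rng(100)
    n, k = 5000, 50
    scores = pd.DataFrame(rng.standard_normal((n, k)),
                          columns=[f"s{i}" for i in range(k)])
    cov = pd.DataFrame({"sex": rng.integers(0, 2, n).astype(float),
                        "age": rng.uniform(10, 40, n)})
    y = (0.5 * scores["s0"] - 0.4 * scores["s7"] + 0.3 * scores["s23"]
         + 0.2 * cov["sex"] + rng.standard_normal(n)).to_numpy()
    return scores, cov, y


class TestEnetSolver:
    def test_matches_r_glmnet(self, tmp_path):
        """Independent oracle: R glmnet at the same penalty level."""
        rng = np.random.default_rng(7)
        n, p = 400, 12
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[:3] = [1.0, -0.8, 0.5]
        y = X @ beta + rng.standard_normal(n) + 0.3
        pf = np.r_[np.zeros(2), np.ones(p - 2)]
        fit = cv_enet(X, y, penalty=pf, family="gaussian", seed=1)

        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "y.csv", y)
        # glmnet rescales penalty factors to sum to nvars
        lam_adj = float(fit.lambda_ * pf.sum() / p)
        script = textwrap.dedent(f"""
            suppressMessages(library(glmnet))
            X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))
            y <- scan("{tmp_path}/y.csv", quiet=TRUE)
            pf <- c(0,0,rep(1,ncol(X)-2))
            f <- glmnet(X, y, alpha=1, penalty.factor=pf,
                        lambda={lam_adj!r}, standardize=FALSE, thresh=1e-12)
            write.csv(as.numeric(coef(f)), "{tmp_path}/coef.csv",
                      row.names=FALSE)
        """)
        (tmp_path / "check.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "check.R")], check=True,
                       capture_output=True)
        r_coef = pd.read_csv(tmp_path / "coef.csv")["x"].to_numpy()
        assert fit.intercept == pytest.approx(r_coef[0], abs=2e-3)
        np.testing.assert_allclose(fit.coef, r_coef[1:], atol=5e-3)

    def test_path_sparsity_monotone_in_penalty(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((300, 20))
        y = X[:, 0] - X[:, 1] + rng.standard_normal(300)
        fits = enet_path(X, y, family="gaussian", n_lambda=30)
        nz = [int((np.abs(f.coef) > 1e-8).sum()) for f in fits]
        lam = [f.lambda_ for f in fits]
        assert lam == sorted(lam, reverse=True)
        # non-decreasing support as lambda decreases (small numerical slack)
        assert all(b >= a - 1 for a, b in zip(nz, nz[1:]))
        assert nz[0] == 0

    def test_huge_penalty_keeps_unpenalized_features(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((500, 5))
        y = 2.0 * X[:, 0] + 0.5 * X[:, 1] + 0.1 * rng.standard_normal(500)
        pf = np.array([0.0, 1.0, 1.0, 1.0, 1.0])
        fits = enet_path(X, y, penalty=pf, lambdas=[1e6], family="gaussian")
        assert abs(fits[0].coef[0]) > 1.5          # unpenalized survives
        np.testing.assert_allclose(fits[0].coef[1:], 0.0, atol=1e-10)


class TestCovariateBase:
    def test_matches_normal_equations_on_toy(self):
        X = pd.DataFrame({"x1": [0.0, 1.0, 2.0, 3.0, 4.0],
                          "x2": [1.0, 0.0, 1.0, 0.0, 1.0]})
        y = np.array([0.5, 1.0, 2.1, 2.9, 4.2])
        model = st.fit_covariate_base(X, y, family="gaussian")
        A = np.column_stack([np.ones(5), X.to_numpy()])
        ref = np.linalg.solve(A.T @ A, A.T @ y)
        assert model.intercept == pytest.approx(ref[0], abs=1e-8)
        np.testing.assert_allclose(model.coef, ref[1:], atol=1e-8)

    def test_independent_outcome_near_zero_r2(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"a": rng.standard_normal(5000)})
        y = rng.standard_normal(5000)
        model = st.fit_covariate_base(X, y, family="gaussian")
        pred = model.predict(None, X)
        assert np.corrcoef(pred, y)[0, 1] ** 2 < 0.01

    def test_perfect_separation_triggers_fallback(self):
        sex = np.r_[np.zeros(50), np.ones(50)]
        X = pd.DataFrame({"sex": sex})
        model = st.fit_covariate_base(X, sex.copy(), family="binomial")
        assert model.flags.get("ridge_fallback", False)

    def test_missing_covariates_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(ValueError, match="missing"):
            st.fit_covariate_base(X, np.array([0.0, 1.0]))


class TestLassoStack:
    def test_recovers_true_support(self, toy_library):
        scores, cov, y = toy_library
        model = st.fit_lasso_stack(scores, cov, y, seed=1)
        w = model.score_weights(list(scores.columns))
        top3 = set(w.abs().nlargest(3).index)
        assert top3 == {"s0", "s7", "s23"}

    def test_covariates_never_penalized_away(self, toy_library):
        scores, cov, y = toy_library
        model = st.fit_lasso_stack(scores, cov, y, seed=1)
        pf = pd.Series(model.penalty_factors, index=model.feature_names)
        assert pf["sex"] == 0.0 and pf["age"] == 0.0
        assert (pf[list(scores.columns)] == 1.0).all()

    def test_duplicated_score_prediction_invariant(self, toy_library):
        scores, cov, y = toy_library
        sub = scores.iloc[:, :10]
        dup = sub.copy()
        dup["s0_copy"] = sub["s0"]
        m1 = st.fit_lasso_stack(sub, cov, y, seed=2)
        m2 = st.fit_lasso_stack(dup, cov, y, seed=2)
        p1 = m1.predict(sub, cov)
        p2 = m2.predict(dup, cov)
        assert np.corrcoef(p1, p2)[0, 1] > 0.999

    def test_all_zero_score_weights_is_valid(self):
        rng = np.random.default_rng(11)
        scores = pd.DataFrame(rng.standard_normal((400, 5)),
                              columns=[f"s{i}" for i in range(5)])
        cov = pd.DataFrame({"sex": rng.integers(0, 2, 400).astype(float)})
        y = cov["sex"].to_numpy() + 0.1 * rng.standard_normal(400)
        model = st.fit_lasso_stack(scores, cov, y, seed=3)
        assert model.n_nonzero_scores(list(scores.columns)) <= 1


class TestXgbStack:
    def test_constant_outcome_constant_prediction(self):
        rng = np.random.default_rng(12)
        scores = pd.DataFrame({"s0": rng.standard_normal(200)})
        cov = pd.DataFrame({"sex": rng.integers(0, 2, 200).astype(float)})
        y = np.full(200, 3.7)
        model = st.fit_xgb_stack(scores, cov, y, family="gaussian")
        pred = model.predict(scores, cov)
        assert np.ptp(pred) < 1e-6

    def test_fixed_seed_identical_predictions(self, toy_library):
        scores, cov, y = toy_library
        a = st.fit_xgb_stack(scores, cov, y, seed=5, nrounds=20)
        b = st.fit_xgb_stack(scores, cov, y, seed=5, nrounds=20)
        np.testing.assert_array_equal(a.predict(scores, cov),
                                      b.predict(scores, cov))

    def test_captures_sex_age_interaction_better_than_glm(self):
        # non-linear covariate truth: boosted covariate-only model beats the
        # logistic covariate-only model out-of-sample
        rng = np.random.default_rng(13)
        n = 8000
        cov = pd.DataFrame({"sex": rng.integers(0, 2, n).astype(float),
                            "age": rng.uniform(10, 40, n)})
        inter = (cov["sex"] - 0.5) * (cov["age"] - 25) / 8.0
        eta = 1.5 * inter.to_numpy() - 0.5
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
        tr = np.arange(n) < n // 2
        glm = st.fit_covariate_base(cov[tr], y[tr], family="binomial")
        xgb = st.fit_xgb_stack(None, cov[tr].reset_index(drop=True), y[tr],
                               family="binomial", eta=0.3, nrounds=100, seed=6)
        te = ~tr
        from multipgs.evaluation import auc

        auc_glm = auc(glm.predict(None, cov[te].reset_index(drop=True)), y[te])
        auc_xgb = auc(xgb.predict(None, cov[te].reset_index(drop=True)), y[te])
        assert auc_xgb > auc_glm + 0.05


class TestMixedStack:
    def test_linear_truth_mixed_close_to_lasso(self, toy_library):
        scores, cov, y = toy_library
        tr = np.arange(len(y)) < 4000
        te = ~tr
        lasso = st.fit_lasso_stack(scores[tr], cov[tr], y[tr], seed=7)
        mixed = st.fit_mixed_stack(scores[tr].reset_index(drop=True),
                                   cov[tr].reset_index(drop=True), y[tr],
                                   eta=0.1, nrounds=50, seed=7)
        r2_l = np.corrcoef(lasso.predict(scores[te], cov[te]), y[te])[0, 1] ** 2
        r2_m = np.corrcoef(mixed.predict(scores[te].reset_index(drop=True),
                                         cov[te].reset_index(drop=True)),
                           y[te])[0, 1] ** 2
        assert r2_m == pytest.approx(r2_l, abs=0.05)

    def test_constant_stage1_reduces_to_score_lasso(self):
        rng = np.random.default_rng(14)
        scores = pd.DataFrame(rng.standard_normal((500, 5)),
                              columns=[f"s{i}" for i in range(5)])
        cov = pd.DataFrame({"c": np.ones(500)})
        y = scores["s0"].to_numpy() + 0.5 * rng.standard_normal(500)
        model = st.fit_mixed_stack(scores, cov, y, seed=8)
        assert model.flags.get("constant_stage1", False)
        pred = model.predict(scores, cov)
        assert np.corrcoef(pred, y)[0, 1] ** 2 > 0.5


class TestSimplify:
    def test_threshold_rule_counts(self):
        model = st.StackModel(
            kind="lasso", family="gaussian",
            feature_names=["s0", "s1", "s2", "sex"],
            coef=np.array([0.02, -0.011, 0.009, 0.3]),
            penalty_factors=np.array([1.0, 1.0, 1.0, 0.0]))
        rng = np.random.default_rng(15)
        scores = pd.DataFrame(rng.standard_normal((300, 3)),
                              columns=["s0", "s1", "s2"])
        cov = pd.DataFrame({"sex": rng.integers(0, 2, 300).astype(float)})
        y = scores["s0"].to_numpy() + rng.standard_normal(300)
        out = st.simplify_stack(model, scores, cov, y, threshold=0.01)
        assert sorted(out.flags["selected_scores"]) == ["s0", "s1"]

    def test_empty_selection_falls_back_to_covariates(self, toy_library):
        scores, cov, y = toy_library
        model = st.fit_lasso_stack(scores.iloc[:500], cov.iloc[:500], y[:500],
                                   seed=9)
        out = st.simplify_stack(model, scores.iloc[:500], cov.iloc[:500],
                                y[:500], threshold=1e9)
        assert out.kind == "covariates_only"
        assert out.flags.get("empty_selection", False)

    def test_simplified_performance_close_to_full(self, toy_library):
        scores, cov, y = toy_library
        tr = np.arange(len(y)) < 4000
        te = ~tr
        full = st.fit_lasso_stack(scores[tr], cov[tr], y[tr], seed=10)
        simple = st.simplify_stack(full, scores[tr].reset_index(drop=True),
                                   cov[tr].reset_index(drop=True), y[tr],
                                   threshold=0.01, seed=10)
        r2_f = np.corrcoef(full.predict(scores[te], cov[te]), y[te])[0, 1] ** 2
        feats = simple.flags.get("selected_scores", [])
        r2_s = np.corrcoef(
            simple.predict(scores[te][feats].reset_index(drop=True),
                           cov[te].reset_index(drop=True)), y[te])[0, 1] ** 2
        assert r2_s == pytest.approx(r2_f, abs=0.02)
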