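import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.linear_model import LogisticRegression

from phenodisc.classify import (
    assess_accuracy,
    fit_glm_importance,
    fit_glmnet_importance,
    fit_multiglm_importance,
    fit_rf_importance,
    group_summaries,
    scale_to_100,
)
from phenodisc.tabular_io import TYPE_QUAL
from tests.conftest import make_table


def planted_binary(rng, n=200, p_noise=9):
    X = pd.DataFrame(rng.normal(size=(n, p_noise + 1)),
                     columns=["x1"] + [f"n{i}" for i in range(p_noise)])
    y = pd.Series(np.where(X["x1"] > 0, "pos", "neg"))
    return X, y


def _rank(table):
    return table.frame.groupby("variable")["scaled"].mean().sort_values(ascending=False)


class TestScaling:
    def test_max_is_exactly_100(self):
        s = scale_to_100(pd.Series([0.2, 1.7, 0.9]))
        assert s.max() == 100.0

    def test_all_zero_stays_zero(self):
        s = scale_to_100(pd.Series([0.0, 0.0]))
        assert (s == 0).all()

    @pytest.mark.parametrize("fitter", ["glm", "multiglm", "glmnet", "rf"])
    def test_every_classifier_obeys_invariant(self, rng, fitter):
        X, y = planted_binary(rng, n=120, p_noise=4)
        fit = {
            "glm": lambda: fit_glm_importance(X, y),
            "multiglm": lambda: fit_multiglm_importance(X, y),
            "glmnet": lambda: fit_glmnet_importance(
                X, y, alphas=(0.5,), lambdas=(1e-3,), seed=1),
            "rf": lambda: fit_rf_importance(X, y, n_trees=50, seed=1),
        }[fitter]()
        for cls, sub in fit.frame.groupby("class"):
            assert sub["scaled"].max() == pytest.approx(100.0)
            assert (sub["scaled"] >= 0).all() and (sub["scaled"] <= 100).all()


class TestGLM:
    def test_single_predictor_scores_100(self, rng):
        X = pd.DataFrame({"only": rng.normal(size=80)})
        y = pd.Series(np.where(X["only"] + rng.normal(scale=2, size=80) > 0, "a", "b"))
        fit = fit_glm_importance(X, y)
        assert (fit.frame["scaled"] == 100.0).all()

    def test_planted_signal_tops_ranking(self, rng):
        X, y = planted_binary(rng)
        fit = fit_glm_importance(X, y)
        assert _rank(fit).index[0] == "x1"
        assert _rank(fit)["x1"] == 100.0

    def test_null_data_no_systematic_winner_and_chance_accuracy(self):
        winners = set()
        for seed in (0, 1, 2, 3, 4):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(500, 5)),
                             columns=[f"v{i}" for i in range(5)])
            y = pd.Series(rng.choice(["a", "b"], size=500))
            winners.add(_rank(fit_glm_importance(X, y)).index[0])
            acc, _ = assess_accuracy(
                lambda: LogisticRegression(max_iter=500), X, y,
                resampling=("bootstrap", 10), seed=seed)
            majority = y.value_counts(normalize=True).max()
            assert abs(acc - majority) < 0.05
        assert len(winners) > 1

    def test_three_levels_routes_to_multinomial(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=90)})
        y = pd.Series(np.repeat(["a", "b", "c"], 30))
        fit = fit_glm_importance(X, y)
        assert fit.classifier == "multiglm"
        assert fit.tuning["routed_from"] == "glm"

    def test_perfect_separation_falls_back_flagged(self, rng):
        X = pd.DataFrame({"x": np.concatenate([rng.normal(-5, 0.1, 30),
                                               rng.normal(5, 0.1, 30)]),
                          "z": rng.normal(size=60)})
        y = pd.Series(np.repeat(["lo", "hi"], 30))
        fit = fit_glm_importance(X, y)
        assert fit.tuning["regularized_fallback"] is True
        assert _rank(fit).index[0] == "x"


class TestMultiGLM:
    def test_binary_agrees_with_glm_ranking(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 6)),
                         columns=[f"v{i}" for i in range(6)])
        logits = X @ np.array([2.0, -1.5, 1.0, 0.5, 0.0, 0.0])
        y = pd.Series(np.where(logits + rng.logistic(size=300) > 0, "a", "b"))
        r_glm = _rank(fit_glm_importance(X, y))
        r_mglm = _rank(fit_multiglm_importance(X, y))
        rho = stats.spearmanr(r_glm[r_glm.index], r_mglm[r_glm.index]).statistic
        assert rho > 0.8

    def test_ordinal_signal_tops_outer_classes(self, rng):
        n = 300
        cls = np.repeat(["lo", "mid", "hi"], n // 3)
        means = {"lo": -1.0, "mid": 0.0, "hi": 1.0}
        X = pd.DataFrame({"x": [means[c] for c in cls] + rng.normal(scale=0.7, size=n),
                          "n1": rng.normal(size=n), "n2": rng.normal(size=n)})
        fit = fit_multiglm_importance(X, pd.Series(cls))
        piv = fit.scaled_matrix()
        assert piv.loc["x", "lo"] == pytest.approx(100.0)
        assert piv.loc["x", "hi"] == pytest.approx(100.0)

    def test_constant_predictor_zero_importance(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=90), "flat": np.ones(90)})
        y = pd.Series(np.where(X["x"] > 0, "a", "b"))
        fit = fit_multiglm_importance(X, y)
        assert (fit.frame.loc[fit.frame["variable"] == "flat", "raw"]
                < 1e-6).all()


class TestGLMNet:
    def test_huge_lambda_zeroes_everything(self, rng):
        X, y = planted_binary(rng, n=100, p_noise=3)
        fit = fit_glmnet_importance(X, y, alphas=(1.0,), lambdas=(1e6,), seed=0)
        assert (fit.frame["raw"] == 0.0).all()
        assert (fit.frame["scaled"] == 0.0).all()

    def test_ridge_limit_matches_multinomial_ranking(self, rng):
        X = pd.DataFrame(rng.normal(size=(250, 5)),
                         columns=[f"v{i}" for i in range(5)])
        logits = X @ np.array([2.0, 1.0, 0.5, 0.0, 0.0])
        y = pd.Series(np.where(logits + rng.logistic(size=250) > 0, "a", "b"))
        net = _rank(fit_glmnet_importance(X, y, alphas=(1e-4,), lambdas=(1e-6,), seed=0))
        mglm = _rank(fit_multiglm_importance(X, y))
        assert list(net.index[:3]) == list(mglm.index[:3])

    def test_planted_three_signals_recovered(self, rng):
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 8)),
                         columns=[f"v{i}" for i in range(8)])
        logits = 2.0 * X["v0"] - 2.0 * X["v1"] + 2.0 * X["v2"]
        y = pd.Series(np.where(logits + rng.logistic(size=n) > 0, "a", "b"))
        fit = fit_glmnet_importance(X, y, alphas=(0.5, 1.0),
                                    lambdas=(1e-3, 1e-2), seed=0)
        assert set(_rank(fit).index[:3]) == {"v0", "v1", "v2"}

    def test_degenerate_grid_rejected(self, rng):
        X, y = planted_binary(rng, n=60, p_noise=2)
        with pytest.raises(Exception):
            fit_glmnet_importance(X, y, alphas=(), lambdas=(1.0,), seed=0)


class TestRandomForest:
    def test_pure_nonlinear_signal_rf_vs_glm(self, rng):
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=["x1"] + [f"n{i}" for i in range(9)])
        y = pd.Series(np.where(X["x1"] ** 2 > np.median(X["x1"] ** 2), "in", "out"))
        rf = _rank(fit_rf_importance(X, y, n_trees=200, seed=0))
        glm = _rank(fit_glm_importance(X, y))
        assert rf.index[0] == "x1" and rf["x1"] == 100.0
        assert list(glm.index).index("x1") > 2  # linear model is blind to x^2

    def test_duplicated_top_predictor_shares_importance(self, rng):
        n = 300
        X = pd.DataFrame({"a": rng.normal(size=n)})
        X["a_copy"] = X["a"] + rng.normal(scale=0.01, size=n)
        for i in range(4):
            X[f"n{i}"] = rng.normal(size=n)
        y = pd.Series(np.where(X["a"] > 0, "p", "q"))
        rank = _rank(fit_rf_importance(X, y, n_trees=200, seed=0))
        assert set(rank.index[:2]) == {"a", "a_copy"}

    def test_importance_stabilizes_with_more_trees(self, rng):
        X, y = planted_binary(rng, n=150, p_noise=5)

        def spread(n_trees):
            # the planted variable pins the max at 100, so stability is
            # measured on a noise variable's scaled importance
            vals = [
                fit_rf_importance(X, y, n_trees=n_trees, seed=s)
                .frame.query("variable == 'n0'")["scaled"].iloc[0]
                for s in range(6)
            ]
            return np.std(vals)

        assert spread(200) < spread(2)

    def test_oob_accuracy_reported(self, rng):
        X, y = planted_binary(rng, n=150, p_noise=3)
        fit = fit_rf_importance(X, y, n_trees=100, seed=0)
        assert 0.5 < fit.accuracy <= 1.0


class TestAssessAccuracy:
    def test_separable_data_perfect(self, rng):
        X = pd.DataFrame({"x": np.concatenate([rng.normal(-8, 0.3, 40),
                                               rng.normal(8, 0.3, 40)])})
        y = pd.Series(np.repeat(["a", "b"], 40))
        acc, _ = assess_accuracy(lambda: LogisticRegression(), X, y,
                                 resampling=("bootstrap", 10), seed=0)
        assert acc == pytest.approx(1.0)

    def test_permuted_three_class_chance_level(self):
        rng = np.random.default_rng(5)
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("wxyz"))
        y = pd.Series(rng.permutation(np.repeat(["a", "b", "c"], n // 3)))
        acc, _ = assess_accuracy(lambda: LogisticRegression(max_iter=500), X, y,
                                 resampling=("bootstrap", 25), seed=0)
        assert abs(acc - 1 / 3) < 0.05

    def test_same_seed_bit_identical(self, rng):
        X, y = planted_binary(rng, n=100, p_noise=3)
        a = assess_accuracy(lambda: LogisticRegression(), X, y, seed=9)
        b = assess_accuracy(lambda: LogisticRegression(), X, y, seed=9)
        assert a == b

    def test_kfold_scheme(self, rng):
        X, y = planted_binary(rng, n=100, p_noise=3)
        acc, sd = assess_accuracy(lambda: LogisticRegression(), X, y,
                                  resampling=("kfold", 5), seed=1)
        assert 0.5 <= acc <= 1.0 and sd >= 0


class TestGroupSummaries:
    def _cohort(self, values):
        frame = pd.DataFrame({
            "Geno": ["WT"] * len(values), "Sex": ["F"] * len(values), "x": values})
        return make_table(frame, dependent="Geno", conditioning=("Sex",),
                          types={"Geno": TYPE_QUAL})

    def test_basic_arithmetic(self):
        frame = pd.DataFrame({"Geno": ["WT", "WT", "WT", "KO", "KO", "KO"],
                              "Sex": ["F"] * 6,
                              "x": [1.0, 2.0, 3.0, 5.0, 5.0, 5.0]})
        t = make_table(frame, dependent="Geno", conditioning=("Sex",))
        summ = group_summaries(t).frame.set_index("stratum")
        wt = summ.loc["WT|F"]
        assert wt["mean"] == 2.0
        assert wt["sd"] == pytest.approx(1.0)
        assert wt["se"] == pytest.approx(1 / np.sqrt(3))

    def test_constant_stratum_zero_width_ci(self):
        frame = pd.DataFrame({"Geno": ["WT"] * 3 + ["KO"] * 3, "Sex": ["F"] * 6,
                              "x": [4.0] * 6})
        t = make_table(frame, dependent="Geno", conditioning=("Sex",))
        summ = group_summaries(t).frame
        assert (summ["ci_high"] - summ["ci_low"] == 0).all()

    def test_singleton_stratum_missing_sd(self):
        frame = pd.DataFrame({"Geno": ["WT", "KO", "KO"], "Sex": ["F"] * 3,
                              "x": [1.0, 2.0, 3.0]})
        t = make_table(frame, dependent="Geno", conditioning=("Sex",))
        summ = group_summaries(t).frame.set_index("stratum")
        assert np.isnan(summ.loc["WT|F", "sd"])

    def test_ci_coverage_simulation(self):
        """500 replicates of n=30 normal(5, 1): the reported t-based 95% CI
        covers the true mean about 95% of the time."""
        rng = np.random.default_rng(17)
        covered = 0
        n_rep = 500
        base = pd.DataFrame({"Geno": ["WT"] * 30 + ["KO"] * 2, "Sex": ["F"] * 32,
                             "x": 0.0})
        t = make_table(base, dependent="Geno", conditioning=("Sex",))
        for _ in range(n_rep):
            t.values["x"] = np.concatenate(
                [rng.normal(5.0, 1.0, size=30), rng.normal(0.0, 1.0, size=2)])
            summ = group_summaries(t).frame.set_index("stratum")
            covered += summ.loc["WT|F", "ci_low"] <= 5.0 <= summ.loc["WT|F", "ci_high"]
        assert abs(covered / n_rep - 0.95) < 0.03
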