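import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from phenodisc.errors import FactorError
from phenodisc.factor_core import (
    FactorInput,
    cosine_similarity,
    cumulative_variance,
    mfamix,
    pcamix,
)

TOL = 1e-8


def quant_input(X: pd.DataFrame, groups=None) -> FactorInput:
    return FactorInput(quantitative=X, qualitative=pd.DataFrame(index=X.index),
                       groups=groups or {})


def qual_input(Q: pd.DataFrame) -> FactorInput:
    return FactorInput(quantitative=pd.DataFrame(index=Q.index), qualitative=Q)


def mca_oracle(Q: pd.DataFrame) -> np.ndarray:
    """Correspondence analysis of the indicator matrix, scaled to the
    mixed-PCA metric (eigenvalues multiplied by the number of variables)."""
    G = pd.get_dummies(Q.astype(str)).to_numpy(dtype=float)
    n, q = len(Q), Q.shape[1]
    P = G / G.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = np.diag(1 / np.sqrt(r)) @ (P - np.outer(r, c)) @ np.diag(1 / np.sqrt(c))
    sv = linalg.svdvals(S)
    lam = (sv**2) * q
    return lam[lam > 1e-10]


class TestPcamixQuantitative:
    def test_two_variables_closed_form(self, rng):
        """Correlated pair -> eigenvalues {1+r, 1-r}."""
        x = rng.normal(size=50)
        y = 0.6 * x + 0.8 * rng.normal(size=50)
        X = pd.DataFrame({"x": x, "y": y})
        r = abs(np.corrcoef(
            (x - x.mean()) / x.std(), (y - y.mean()) / y.std())[0, 1])
        res = pcamix(quant_input(X))
        np.testing.assert_allclose(sorted(res.eigenvalues, reverse=True),
                                   [1 + r, 1 - r], rtol=1e-10)

    def test_matches_eigendecomposition_oracle_50_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(8, 30))
            p = int(rng.integers(2, 6))
            X = pd.DataFrame(rng.normal(size=(n, p)),
                             columns=[f"v{j}" for j in range(p)])
            res = pcamix(quant_input(X))
            Z = (X - X.mean()) / X.std(ddof=0)
            C = Z.T @ Z / n
            ev = np.sort(linalg.eigvalsh(C))[::-1]
            ev = ev[ev > 1e-10]
            np.testing.assert_allclose(res.eigenvalues, ev, rtol=1e-7, atol=1e-9)

    def test_scores_match_direct_pca_up_to_sign(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        res = pcamix(quant_input(X))
        Z = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        C = Z.T @ Z / len(X)
        w, V = linalg.eigh(C)
        order = np.argsort(w)[::-1]
        direct = Z @ V[:, order]
        np.testing.assert_allclose(np.abs(res.scores.to_numpy()), np.abs(direct),
                                   atol=1e-8)


class TestPcamixQualitative:
    def test_single_balanced_three_level_inertia(self):
        Q = pd.DataFrame({"g": ["a", "b", "c"] * 4})
        res = pcamix(qual_input(Q))
        assert res.eigenvalues.sum() == pytest.approx(2.0)

    def test_matches_mca_oracle_50_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(12, 40))
            q = int(rng.integers(1, 4))
            Q = pd.DataFrame({
                f"g{j}": rng.choice(list("uvw")[: int(rng.integers(2, 4))], size=n)
                for j in range(q)
            })
            res = pcamix(qual_input(Q))
            oracle = mca_oracle(Q)
            np.testing.assert_allclose(res.eigenvalues, oracle, rtol=1e-7, atol=1e-8)


class TestMixedInvariants:
    @pytest.fixture
    def mixed(self, rng):
        n = 40
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("xyz"))
        Q = pd.DataFrame({"g": rng.choice(["a", "b", "c"], n),
                          "h": rng.choice(["u", "v"], n)}, index=X.index)
        return FactorInput(quantitative=X, qualitative=Q)

    def test_total_inertia(self, mixed):
        res = pcamix(mixed)
        m = mixed.qualitative.nunique().sum()
        q = mixed.qualitative.shape[1]
        assert res.eigenvalues.sum() == pytest.approx(3 + (m - q), rel=1e-10)

    def test_eigenvalues_descending_nonnegative(self, mixed):
        res = pcamix(mixed)
        assert (np.diff(res.eigenvalues) <= TOL).all()
        assert (res.eigenvalues >= -TOL).all()

    def test_squared_loadings_bounded_and_sum_to_eigenvalues(self, mixed):
        res = pcamix(mixed)
        sq = res.squared_loadings.to_numpy()
        assert (sq >= -TOL).all() and (sq <= 1 + 1e-8).all()
        np.testing.assert_allclose(sq.sum(axis=0), res.eigenvalues, rtol=1e-8)

    def test_scores_uncorrelated_with_variance_lambda(self, mixed):
        res = pcamix(mixed)
        S = res.scores.to_numpy()
        G = S.T @ S / len(S)
        np.testing.assert_allclose(G, np.diag(res.eigenvalues), atol=1e-8)

    def test_eta_squared_is_correlation_ratio(self, mixed):
        res = pcamix(mixed)
        f = res.scores["Dim1"].to_numpy()
        g = mixed.qualitative["g"].to_numpy()
        between = sum((f[g == lv].mean()) ** 2 * (g == lv).sum() for lv in set(g))
        eta2 = between / (f**2).sum()
        assert res.squared_loadings.loc["g", "Dim1"] == pytest.approx(eta2, rel=1e-8)

    def test_quant_correlation_squared_equals_loading(self, mixed):
        res = pcamix(mixed)
        np.testing.assert_allclose(
            res.quant_correlations.loc[list("xyz")].astype(float).to_numpy() ** 2,
            res.squared_loadings.loc[list("xyz")].to_numpy(), atol=1e-8)

    def test_deterministic_sign_convention(self, mixed):
        a = pcamix(mixed)
        b = pcamix(mixed)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_cumulative_variance_reaches_100(self, mixed):
        res = pcamix(mixed)
        cv = cumulative_variance(res, res.rank)
        assert cv["cumulative_pct"].iloc[-1] == pytest.approx(100.0)
        assert (np.diff(cv["cumulative_pct"]) >= -TOL).all()

    def test_too_few_rows(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(FactorError):
            pcamix(quant_input(X))

    def test_missing_cells_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1.0, 0.5, 2.0]})
        with pytest.raises(FactorError):
            pcamix(quant_input(X))


class TestMFA:
    def test_single_group_normalizes_first_eigenvalue(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        plain = pcamix(quant_input(X))
        res = mfamix(quant_input(X, groups={c: "only" for c in "abcd"}))
        assert res.eigenvalues[0] == pytest.approx(1.0)
        np.testing.assert_allclose(res.eigenvalues,
                                   plain.eigenvalues / plain.eigenvalues[0], rtol=1e-8)

    def test_identical_groups_split_contribution_evenly(self, rng):
        base = rng.normal(size=(30, 2))
        X = pd.DataFrame(np.hstack([base, base]), columns=["a1", "a2", "b1", "b2"])
        res = mfamix(quant_input(X, groups={"a1": "G1", "a2": "G1",
                                            "b1": "G2", "b2": "G2"}))
        share = res.group_contributions["Dim1"] / res.eigenvalues[0]
        np.testing.assert_allclose(share, [0.5, 0.5], atol=1e-8)

    def test_within_group_first_eigenvalue_is_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(35, 4)), columns=list("abcd"))
        Q = pd.DataFrame({"g": rng.choice(["x", "y", "z"], 35)}, index=X.index)
        fi = FactorInput(quantitative=X, qualitative=Q,
                         groups={"a": "G1", "b": "G1", "c": "G2", "d": "G2", "g": "G3"})
        res = mfamix(fi)
        for gname, w in res.group_weights.items():
            members = [v for v in fi.variables if fi.groups[v] == gname]
            sub = fi.subset(members)
            reweighted = pcamix(sub, variable_weights={v: w for v in members})
            assert reweighted.eigenvalues[0] == pytest.approx(1.0, abs=1e-8)

    def test_group_contributions_sum_to_eigenvalues(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        res = mfamix(quant_input(X, groups={"a": "G1", "b": "G1", "c": "G2", "d": "G2"}))
        np.testing.assert_allclose(res.group_contributions.sum(axis=0),
                                   res.eigenvalues, rtol=1e-8)

    def test_partial_coordinates_average_to_global(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        res = mfamix(quant_input(X, groups={"a": "G1", "b": "G1", "c": "G2", "d": "G2"}))
        avg = sum(res.partial_coordinates.values()) / len(res.partial_coordinates)
        np.testing.assert_allclose(avg.to_numpy(), res.scores.to_numpy(), atol=1e-8)

    def test_partial_axes_are_correlations(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        res = mfamix(quant_input(X, groups={"a": "G1", "b": "G1", "c": "G2", "d": "G2"}))
        assert (res.partial_axes.abs().to_numpy() <= 1 + 1e-8).all()


class TestCumulativeVariance:
    def test_arithmetic(self):
        class Fake:
            eigenvalues = np.array([2.0, 1.0, 1.0])
            variance_pct = 100 * eigenvalues / 4.0
            cumulative_pct = np.cumsum(variance_pct)
            rank = 3
            scores = pd.DataFrame(columns=["Dim1", "Dim2", "Dim3"])

        cv = cumulative_variance(Fake(), 3)
        np.testing.assert_allclose(cv["cumulative_pct"], [50.0, 75.0, 100.0])

    def test_n_dims_capped_at_rank(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        res = pcamix(quant_input(X))
        cv = cumulative_variance(res, 10)
        assert len(cv) == res.rank


class TestCosineSimilarity:
    @pytest.fixture
    def result(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        X["d"] = X["a"] * 2.0  # identical direction to a
        return pcamix(quant_input(X))

    def test_identical_vectors_give_one(self, result):
        sim = cosine_similarity(result, 2, ["a", "d"])
        assert sim.loc["a", "d"] == pytest.approx(1.0, abs=1e-8)

    def test_unit_diagonal_and_symmetry(self, result):
        sim = cosine_similarity(result, 3, ["a", "b", "c"])
        np.testing.assert_allclose(np.diag(sim), 1.0)
        np.testing.assert_allclose(sim.to_numpy(), sim.to_numpy().T)

    def test_orthogonal_and_scale_invariance_from_definition(self):
        # direct contract cases on hand-built coordinate vectors
        res = pcamix(quant_input(pd.DataFrame(
            np.random.default_rng(0).normal(size=(20, 2)), columns=["u", "v"])))
        res.quant_correlations.loc["u"] = [1.0, 0.0]
        res.quant_correlations.loc["v"] = [0.0, 1.0]
        sim = cosine_similarity(res, 2, ["u", "v"])
        assert sim.loc["u", "v"] == pytest.approx(0.0, abs=1e-12)
        res.quant_correlations.loc["v"] = [2.0, 2.0]
        res.quant_correlations.loc["u"] = [1.0, 1.0]
        sim = cosine_similarity(res, 2, ["u", "v"])
        assert sim.loc["u", "v"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_norm_reported_missing(self, result):
        result.quant_correlations.loc["b"] = [0.0, 0.0, 0.0]
        sim = cosine_similarity(result, 3, ["a", "b"])
        assert np.isnan(sim.loc["a", "b"])

    def test_dims_beyond_rank_rejected(self, result):
        with pytest.raises(FactorError):
            cosine_similarity(result, 99, ["a"])


class TestHypothesisProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.integers(min_value=5, max_value=25),
           st.integers(min_value=2, max_value=5),
           st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_inertia_and_orthogonality_hold_for_random_instances(self, n, p, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"v{j}" for j in range(p)])
        if (X.std(ddof=0) == 0).any():
            return
        res = pcamix(quant_input(X))
        assert res.eigenvalues.sum() == pytest.approx(res.total_inertia, rel=1e-6)
        S = res.scores.to_numpy()
        G = S.T @ S / n
        np.testing.assert_allclose(G, np.diag(res.eigenvalues), atol=1e-7)
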