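import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cladepath.pathmodels import (
    CausalDAG,
    Claim,
    PathModel,
    PathModelError,
    basis_set,
    c_statistic,
    ci_test,
    cicc,
    compare_models,
    decompose_effects,
    fit_path_model,
    quantile_normalize,
    QuantileNormalizer,
)
from cladepath.synth import simulate_sem


def random_dag(rng, n_nodes, p_edge=0.4):
    names = [f"v{i}" for i in range(n_nodes)]
    edges = [
        (names[i], names[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p_edge
    ]
    return CausalDAG(names, edges)


class TestCausalDAG:
    def test_cycle_rejected(self):
        with pytest.raises(PathModelError):
            CausalDAG(["a", "b"], [("a", "b"), ("b", "a")])

    def test_text_roundtrip(self):
        text = "X -> Y\nY -> Z\nU ~~ X\nU -> Z\n"
        dag = CausalDAG.from_text(text)
        dag2 = CausalDAG.from_text(dag.to_text())
        assert set(dag.edges) == set(dag2.edges)
        assert dag.correlations == dag2.correlations

    def test_correlation_requires_exogenous(self):
        with pytest.raises(PathModelError):
            CausalDAG(["a", "b", "c"], [("a", "b")], [("b", "c")])


class TestBasisSet:
    def test_chain(self):
        dag = CausalDAG(["X", "Y", "Z"], [("X", "Y"), ("Y", "Z")])
        assert basis_set(dag) == [Claim("X", "Z", ("Y",))]

    def test_collider(self):
        dag = CausalDAG(["X", "Y", "Z"], [("X", "Z"), ("Y", "Z")])
        assert basis_set(dag) == [Claim("X", "Y", ())]

    def test_claims_are_valid_d_separations(self, rng):
        """Every basis claim d-separates its pair in the DAG, and the set
        covers exactly the non-adjacent pairs (brute-force graph oracle,
        200 random DAGs up to 6 nodes)."""
        for _ in range(200):
            dag = random_dag(rng, int(rng.integers(3, 7)))
            claims = basis_set(dag)
            # coverage oracle: adjacency from explicit edge scan
            nonadj = {
                frozenset((a, b))
                for i, a in enumerate(dag.nodes)
                for b in dag.nodes[i + 1 :]
                if (a, b) not in dag.edges and (b, a) not in dag.edges
            }
            assert {frozenset((c.x, c.y)) for c in claims} == nonadj
            for c in claims:
                assert nx.is_d_separator(dag.graph, {c.x}, {c.y}, set(c.given))


class TestCITest:
    def test_exact_dependence_p_zero(self, rng):
        x = rng.normal(size=200)
        data = pd.DataFrame({"X": x, "Y": x})
        p = ci_test(Claim("X", "Y", ()), data, mode="ols")
        assert p < 1e-12

    def test_contrasts_matches_through_origin_closed_form(self, rng):
        """contrasts-OLS p equals the textbook through-origin t-test."""
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        data = pd.DataFrame({"X": x, "Y": y})
        p = ci_test(Claim("X", "Y", ()), data, mode="contrasts-ols")
        b = (x @ y) / (x @ x)
        resid = y - b * x
        s2 = resid @ resid / (60 - 1)
        t = b / np.sqrt(s2 / (x @ x))
        p_oracle = 2 * stats.t.sf(abs(t), 60 - 1)
        assert p == pytest.approx(p_oracle, rel=1e-10)

    def test_null_p_uniform(self, rng):
        """Independent normals give uniform p across 300 replicates."""
        ps = []
        for _ in range(300):
            data = pd.DataFrame(rng.normal(size=(60, 2)), columns=["X", "Y"])
            ps.append(ci_test(Claim("X", "Y", ()), data, mode="ols"))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_gls_bm_needs_tree(self):
        data = pd.DataFrame({"X": [1.0, 2, 3, 4], "Y": [1.0, 2, 3, 5]})
        with pytest.raises(PathModelError):
            ci_test(Claim("X", "Y", ()), data, mode="gls-bm")


class TestCStatistic:
    def test_known_values(self):
        assert c_statistic([1.0, 1.0])[0] == pytest.approx(0.0)
        assert c_statistic([np.exp(-1)])[0] == pytest.approx(2.0)
        C, df, p = c_statistic([0.5, 0.5])
        assert C == pytest.approx(2.7726, abs=1e-4)
        assert df == 4

    def test_empty_is_saturated(self):
        assert c_statistic([]) == (0.0, 0, 1.0)

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            C, _, _ = c_statistic([0.0])
        assert np.isfinite(C)


class TestCicc:
    def test_arithmetic(self):
        assert cicc(0.0, 1, 3) == pytest.approx(6.0)
        assert cicc(10.0, 4, 100) == pytest.approx(10 + 800 / 95)

    def test_monotone_in_q(self):
        vals = [cicc(5.0, q, 50) for q in range(1, 10)]
        assert all(np.diff(vals) > 0)

    def test_small_n_raises(self):
        with pytest.raises(PathModelError):
            cicc(1.0, 5, 6)


class TestNormalize:
    def test_monotone_and_gaussianizes(self, rng):
        x = rng.lognormal(size=1000)
        z = quantile_normalize(x)
        assert stats.spearmanr(x, z).statistic == pytest.approx(1.0)
        assert abs(stats.skew(z)) < 0.1

    def test_constant_raises(self):
        with pytest.raises(PathModelError):
            quantile_normalize([1.0, 1.0, 1.0])

    def test_transformer_reproduces_function_in_sample(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50)})
        qn = QuantileNormalizer().fit(X)
        assert np.allclose(qn.transform(X)["a"], quantile_normalize(X["a"]))

    def test_sklearn_params_roundtrip(self):
        qn = QuantileNormalizer()
        assert qn.get_params() == {}
        from cladepath.pathmodels import PathModel

        pm = PathModel(mode="ols")
        assert pm.get_params()["mode"] == "ols"
        pm.set_params(mode="contrasts-ols")
        assert pm.mode == "contrasts-ols"


class TestPathModelFit:
    def chain(self):
        return CausalDAG(["X", "Y", "Z"], [("X", "Y"), ("Y", "Z")], name="chain")

    def test_chain_recovery(self, rng):
        data = simulate_sem(self.chain(), {("X", "Y"): 0.7, ("Y", "Z"): 0.5}, 2000, rng)
        fit = fit_path_model(self.chain(), data, mode="ols")
        cm = fit.coefficient_map()
        se = dict(zip(zip(fit.coefficients_["from"], fit.coefficients_["to"]), fit.coefficients_["se"]))
        assert abs(cm[("X", "Y")] - 0.7) < 3 * se[("X", "Y")]
        assert abs(cm[("Y", "Z")] - 0.5) < 3 * se[("Y", "Z")]

    def test_saturated_model_df_zero(self, rng):
        dag = CausalDAG(["X", "Y", "Z"], [("X", "Y"), ("X", "Z"), ("Y", "Z")])
        data = pd.DataFrame(rng.normal(size=(100, 3)), columns=["X", "Y", "Z"])
        fit = fit_path_model(dag, data, mode="ols")
        assert fit.chi2_df_ == 0
        assert fit.chi2_ == pytest.approx(0.0, abs=1e-8)
        assert fit.c_statistic_ == 0.0  # no basis claims

    def test_null_chi2_p_uniform(self, rng):
        """Correct (empty) model on independent data: GOF p roughly uniform."""
        dag = CausalDAG(["X", "Y"])
        ps = []
        for _ in range(200):
            data = pd.DataFrame(rng.normal(size=(150, 2)), columns=["X", "Y"])
            ps.append(fit_path_model(dag, data, mode="ols").chi2_p_)
        assert stats.kstest(ps, "uniform").pvalue > 0.005

    def test_coefficient_product_tracks_implied_correlation(self, rng):
        """Path tracing: for a chain on standardized data the product of
        fitted coefficients equals the model-implied endpoint correlation."""
        data = simulate_sem(self.chain(), {("X", "Y"): 0.6, ("Y", "Z"): 0.4}, 500, rng)
        fit = fit_path_model(self.chain(), data, mode="ols")
        cm = fit.coefficient_map()
        implied = fit.implied_cov_.loc["X", "Z"] / np.sqrt(
            fit.implied_cov_.loc["X", "X"] * fit.implied_cov_.loc["Z", "Z"]
        )
        assert cm[("X", "Y")] * cm[("Y", "Z")] == pytest.approx(implied, abs=1e-8)

    def test_degenerate_variable_raises(self):
        data = pd.DataFrame({"X": np.arange(10.0), "Y": 1.0, "Z": np.arange(10.0)})
        with pytest.raises(PathModelError):
            fit_path_model(self.chain(), data, mode="ols")

    def test_correlated_exogenous_pair(self, rng):
        dag = CausalDAG(["A", "B", "Z"], [("A", "Z"), ("B", "Z")], [("A", "B")])
        data = simulate_sem(
            dag, {("A", "Z"): 0.4, ("B", "Z"): 0.3}, 1500, rng,
            exog_correlations={("A", "B"): 0.5},
        )
        fit = fit_path_model(dag, data, mode="ols")
        assert fit.sample_cov_.loc["A", "B"] == pytest.approx(0.5, abs=0.08)
        assert basis_set(dag) == []  # correlated pair is adjacent


class TestEffects:
    def test_arithmetic_and_order_invariance(self):
        dag = CausalDAG(
            ["a", "b", "c", "d"],
            [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("b", "d")],
        )
        coef = {("a", "b"): 0.5, ("b", "c"): 0.4, ("a", "c"): 0.2, ("c", "d"): 0.3, ("b", "d"): 0.1}
        eff = decompose_effects(dag, coef).set_index(["from", "to"])
        # a->d: paths a-b-d (0.05), a-b-c-d (0.06), a-c-d (0.06)
        assert eff.loc[("a", "d"), "indirect"] == pytest.approx(0.17)
        assert np.allclose(eff["total"], eff["direct"] + eff["indirect"], atol=1e-12)

    def test_unknown_pair_raises(self):
        dag = CausalDAG(["a", "b"], [("a", "b")])
        with pytest.raises(PathModelError):
            decompose_effects(dag, {("a", "b"): 0.5}, pairs=[("a", "zzz")])


class TestCompare:
    def test_delta_column(self, rng):
        chain = CausalDAG(["X", "Y", "Z"], [("X", "Y"), ("Y", "Z")], name="chain")
        collider = CausalDAG(["X", "Y", "Z"], [("X", "Z"), ("Y", "Z")], name="collider")
        data = simulate_sem(chain, {("X", "Y"): 0.7, ("Y", "Z"): 0.5}, 400, rng)
        fits = [fit_path_model(d, data, mode="ols") for d in (chain, collider)]
        tab = compare_models(fits, criterion="cicc")
        assert tab["delta"].iloc[0] == 0.0
        assert tab["name"].iloc[0] == "chain"
        assert tab["delta"].iloc[1] > 0

    def test_mixed_n_raises(self, rng):
        chain = CausalDAG(["X", "Y", "Z"], [("X", "Y"), ("Y", "Z")], name="chain")
        d1 = pd.DataFrame(rng.normal(size=(50, 3)), columns=["X", "Y", "Z"])
        d2 = pd.DataFrame(rng.normal(size=(60, 3)), columns=["X", "Y", "Z"])
        f1 = fit_path_model(chain, d1, mode="ols")
        f2 = fit_path_model(chain, d2, mode="ols")
        with pytest.raises(PathModelError):
            compare_models([f1, f2])
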