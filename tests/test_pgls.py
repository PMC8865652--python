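"""Phylogenetic GLS: covariance, Pagel transform, fitting, pruning."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from mpmrisk.pgls import (
    PGLSError,
    _patristic_matrix,
    build_design,
    consensus_tree,
    fit_pgls,
    pagel_transform,
    phylo_covariance,
    prune_interactions,
    variance_explained_values,
)
from mpmrisk.simulate import simulate_yule_tree


def tree_from(newick, tns=None):
    return dendropy.Tree.get(
        data=newick, schema="newick",
        taxon_namespace=tns or dendropy.TaxonNamespace(),
    )


class TestPhyloCovariance:
    def test_star_tree_diagonal(self):
        t = tree_from("(A:2,B:2,C:2);")
        C, labels = phylo_covariance(t, ["A", "B", "C"])
        assert np.allclose(C, 2 * np.eye(3))

    def test_cherry_shared_stem(self):
        t = tree_from("((A:1,B:1):2,C:3);")
        C, _ = phylo_covariance(t, ["A", "B", "C"])
        assert C[0, 0] == pytest.approx(3)
        assert C[0, 1] == pytest.approx(2)
        assert C[0, 2] == pytest.approx(0)

    def test_ultrametric_constant_diagonal(self):
        t = simulate_yule_tree(20, 1.0, seed=4)
        C, _ = phylo_covariance(t)
        assert np.ptp(np.diag(C)) < 1e-9

    def test_negative_branch_rejected(self):
        t = tree_from("((A:1,B:-0.5):2,C:3);")
        with pytest.raises(PGLSError, match="negative branch"):
            phylo_covariance(t, ["A", "B", "C"])


class TestPagelTransform:
    def setup_method(self):
        self.C = np.array([[3.0, 2.0], [2.0, 3.0]])

    def test_identity_at_one(self):
        assert np.allclose(pagel_transform(self.C, 1.0), self.C)

    def test_diagonal_at_zero(self):
        assert np.allclose(pagel_transform(self.C, 0.0), np.diag([3.0, 3.0]))

    def test_halves_off_diagonal(self):
        assert pagel_transform(self.C, 0.5)[0, 1] == pytest.approx(1.0)


class TestFitPGLS:
    def test_identity_covariance_reduces_to_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 1.5 - 0.7 * X[:, 1] + rng.normal(size=n)
        res = fit_pgls(X, y, np.eye(n), method="REML")
        ols = sm.OLS(y, X).fit()
        assert np.allclose(res.beta, ols.params, atol=1e-8)
        assert np.allclose(res.se, ols.bse, atol=1e-8)
        assert np.allclose(res.t, ols.tvalues, atol=1e-8)

    def test_exact_linear_response(self):
        rng = np.random.default_rng(1)
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 2.0 + 3.0 * X[:, 1]
        res = fit_pgls(X, y, np.eye(n))
        assert res.var_explained == pytest.approx(1.0)
        assert res.p[1] < 1e-12

    def test_likelihood_peak_at_estimate(self):
        # optimizer sanity: profiled likelihood at lambda_hat beats endpoints
        rng = np.random.default_rng(2)
        tree = simulate_yule_tree(80, 1.0, seed=9)
        C, _ = phylo_covariance(tree)
        x = rng.normal(size=80)
        X = np.column_stack([np.ones(80), x])
        V = pagel_transform(C, 0.6)
        y = 1 + 0.5 * x + rng.multivariate_normal(np.zeros(80), V,
                                                  method="cholesky")
        res = fit_pgls(X, y, C)
        from mpmrisk.pgls import _gls_profile

        ll_hat = res.loglik
        for lam in (0.0, 1.0):
            ll = _gls_profile(X, y, pagel_transform(C, lam), "REML")[3]
            assert ll_hat >= ll - 1e-8

    def test_singular_design_rejected(self):
        X = np.ones((20, 2))
        with pytest.raises(PGLSError, match="singular"):
            fit_pgls(X, np.arange(20.0), np.eye(20))

    def test_too_few_observations_rejected(self):
        X = np.column_stack([np.ones(3), np.arange(3.0)])
        with pytest.raises(PGLSError, match="too small"):
            fit_pgls(X, np.arange(3.0), np.eye(3))


class TestVarianceExplained:
    def test_hand_example(self):
        assert variance_explained_values(
            [1, 2, 3, 4], [1, 2, 3, 3]
        ) == pytest.approx(0.85)

    def test_intercept_only_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        assert variance_explained_values(y, np.full(4, y.mean())) == (
            pytest.approx(0.0)
        )

    def test_shift_invariance_through_intercept(self):
        rng = np.random.default_rng(3)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 1 + 0.8 * X[:, 1] + rng.normal(scale=0.5, size=n)
        r1 = fit_pgls(X, y, np.eye(n))
        r2 = fit_pgls(X, y + 100.0, np.eye(n))
        assert r1.var_explained == pytest.approx(r2.var_explained, abs=1e-8)

    def test_constant_response_rejected(self):
        with pytest.raises(PGLSError):
            variance_explained_values([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestConsensusTree:
    def test_identical_trees_preserve_distances(self):
        tns = dendropy.TaxonNamespace()
        trees = [
            tree_from("((A:1,B:1):1,(C:1,D:1):1);", tns) for _ in range(5)
        ]
        ct = consensus_tree(trees)
        D = _patristic_matrix(ct, ["A", "B", "C", "D"])
        D0 = _patristic_matrix(trees[0], ["A", "B", "C", "D"])
        assert np.allclose(D, D0, atol=1e-8)

    def test_mean_of_scaled_branch_lengths(self):
        tns = dendropy.TaxonNamespace()
        t1 = tree_from("((A:1,B:1):1,(C:1,D:1):1);", tns)
        t2 = tree_from("((A:3,B:3):3,(C:3,D:3):3);", tns)
        ct = consensus_tree([t1, t2])
        D = _patristic_matrix(ct, ["A", "B", "C", "D"])
        assert D[0, 1] == pytest.approx(4.0, abs=1e-8)  # mean of 2 and 6
        assert D[0, 2] == pytest.approx(8.0, abs=1e-8)  # mean of 4 and 12

    def test_single_tree_returned_unchanged(self):
        t = tree_from("((A:1,B:1):1,C:2);")
        assert consensus_tree([t]) is t

    def test_mismatched_tips_rejected(self):
        tns = dendropy.TaxonNamespace()
        t1 = tree_from("(A:1,B:1);", tns)
        t2 = tree_from("(A:1,C:1);", tns)
        with pytest.raises(PGLSError, match="mismatched"):
            consensus_tree([t1, t2])


class TestPruneInteractions:
    def make(self, seed=0, n=80, interaction=0.0):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            {f"x{j}": rng.normal(size=n) for j in (1, 2, 3)}
        )
        y = (
            data.x1
            - data.x2
            + interaction * data.x1 * data.x2
            + rng.normal(scale=0.5, size=n)
        )
        return data, np.asarray(y)

    def test_only_significant_interactions_survive(self):
        # without a true interaction the model usually prunes to additive;
        # any retained interaction must itself be significant and every
        # removed one was not at the time of removal
        additive = 0
        for seed in range(5):
            data, y = self.make(seed=seed)
            design = build_design(data, ["x1", "x2", "x3"])
            res = prune_interactions(design, y, np.eye(len(y)))
            pmap = dict(zip(res.terms, res.p))
            kept = [t for t in res.terms if ":" in t]
            additive += not kept
            for t in kept:
                protected = any(
                    set(t.split(":")) < set(h.split(":")) for h in kept
                )
                assert pmap[t] < 0.05 or protected
            for d in res.pruning_trace:
                if d["action"] == "remove":
                    assert d["p"] >= 0.05
        assert additive >= 3

    def test_true_interaction_retained(self):
        data, y = self.make(seed=6, interaction=1.5)
        design = build_design(data, ["x1", "x2", "x3"])
        res = prune_interactions(design, y, np.eye(len(y)))
        assert "x1:x2" in res.terms

    def test_three_way_removed_before_two_way(self):
        data, y = self.make(seed=7)
        design = build_design(data, ["x1", "x2", "x3"])
        res = prune_interactions(design, y, np.eye(len(y)))
        removed = [d["term"] for d in res.pruning_trace
                   if d["action"] == "remove"]
        if "x1:x2:x3" in removed:
            three = removed.index("x1:x2:x3")
            for t in removed[:three]:
                assert t.count(":") >= 2

    def test_main_effects_never_removed(self):
        data, y = self.make(seed=8)
        design = build_design(data, ["x1", "x2", "x3"])
        res = prune_interactions(design, y, np.eye(len(y)))
        for t in ("x1", "x2", "x3", "(Intercept)"):
            assert t in res.terms

    def test_inestimable_orders_trimmed(self):
        data, y = self.make(seed=9, n=8)
        design = build_design(data, ["x1", "x2", "x3"])
        res = prune_interactions(design, y, np.eye(len(y)))
        assert any(d["action"] == "trim_inestimable"
                   for d in res.pruning_trace)


class TestBuildDesign:
    def test_standardization_and_columns(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame({"a": rng.normal(2, 5, 50),
                             "b": rng.normal(-1, 0.1, 50)})
        d = build_design(data, ["a", "b"])
        assert list(d.columns) == ["(Intercept)", "a", "b", "a:b"]
        assert d["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert d["a"].std(ddof=1) == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        data = pd.DataFrame({"a": np.ones(10)})
        with pytest.raises(PGLSError, match="constant"):
            build_design(data, ["a"])
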