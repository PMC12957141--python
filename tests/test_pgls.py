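import numpy as np
import pandas as pd
import pytest

from nichebreadth import simulate, trees
from nichebreadth.pgls import (
    ComparativeData,
    brownian_cov,
    gls_fit,
    maybe_drop_intercept,
    pgls_ml,
    transform_cov,
)


def random_tree(n, seed):
    return simulate._pure_birth_tree(n, 1.0, seed, "T")


def make_cd(tree, y, x, intercept=True):
    taxa = sorted(trees.tip_labels(tree))
    X = pd.DataFrame(index=taxa)
    if intercept:
        X["intercept"] = 1.0
    X["x"] = x
    return ComparativeData(taxa=taxa, y=y, X=X, tree=tree)


class TestBrownianCov:
    def test_star_tree_is_scaled_identity(self):
        t = trees.read_newick("(A:4,B:4,C:4);")
        np.testing.assert_allclose(brownian_cov(t, ["A", "B", "C"]), 4 * np.eye(3))

    def test_three_tip_shared_paths(self, three_tip_tree):
        V = brownian_cov(three_tip_tree, ["A", "B", "C"])
        expected = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        np.testing.assert_allclose(V, expected)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_cophenetic_identity(self, seed):
        # independent oracle: V_ij = (depth_i + depth_j - d_ij)/2
        t = random_tree(10, seed)
        taxa = sorted(trees.tip_labels(t))
        V = brownian_cov(t, taxa)
        d = trees.cophenetic_matrix(t).loc[taxa, taxa].values
        depths = np.diag(V)
        expected = (depths[:, None] + depths[None, :] - d) / 2
        np.testing.assert_allclose(V, expected, atol=1e-12)

    def test_taxa_mismatch(self, three_tip_tree):
        with pytest.raises(ValueError, match="absent"):
            brownian_cov(three_tip_tree, ["A", "Z"])


class TestTransformCov:
    def test_identity_parameters(self, three_tip_tree):
        V0 = brownian_cov(three_tip_tree, ["A", "B", "C"])
        V1 = transform_cov(three_tip_tree, 1.0, 1.0, 1.0, taxa=["A", "B", "C"])
        np.testing.assert_allclose(V0, V1)

    def test_lambda_zero_is_diagonal(self, three_tip_tree):
        V = transform_cov(three_tip_tree, lam=0.0, taxa=["A", "B", "C"])
        np.testing.assert_allclose(V, np.diag(np.diag(V)))

    def test_kappa_zero_unit_branches(self):
        # kappa=0 turns every positive branch into length 1 (punctuational)
        t = trees.read_newick("((A:1,B:1):1,C:2);")
        V = transform_cov(t, kappa=0.0, taxa=["A", "B", "C"])
        tk = trees.read_newick("((A:1,B:1):1,C:1);")
        np.testing.assert_allclose(V, brownian_cov(tk, ["A", "B", "C"]))

    def test_delta_preserves_max_diagonal(self, three_tip_tree):
        V = transform_cov(three_tip_tree, delta=2.5, taxa=["A", "B", "C"])
        assert V.diagonal().max() == pytest.approx(2.0)

    def test_delta_requires_ultrametric(self):
        t = trees.read_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            transform_cov(t, delta=0.5, taxa=["A", "B", "C"])

    def test_invalid_lambda(self, three_tip_tree):
        with pytest.raises(ValueError):
            transform_cov(three_tip_tree, lam=1.5, taxa=["A", "B", "C"])


class TestGlsFit:
    def test_identity_covariance_equals_ols(self):
        tree = random_tree(12, 1)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 12)
        y = 1.0 + 0.5 * x + rng.normal(0, 1, 12)
        cd = make_cd(tree, y, x)
        fit = gls_fit(cd, np.eye(12))
        bols = np.linalg.lstsq(np.c_[np.ones(12), x], y, rcond=None)[0]
        np.testing.assert_allclose(fit.coef.values, bols, atol=1e-10)

    def test_star_tree_equals_ols(self):
        t = trees.read_newick("(" + ",".join(f"T{i}:1" for i in range(10)) + ");")
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 10)
        y = 2.0 - 0.7 * x + rng.normal(0, 1, 10)
        cd = make_cd(t, y, x)
        V = brownian_cov(t, cd.taxa)
        fit = gls_fit(cd, V)
        bols = np.linalg.lstsq(np.c_[np.ones(10), x], y, rcond=None)[0]
        np.testing.assert_allclose(fit.coef.values, bols, atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_explicit_inverse_oracle(self, seed):
        tree = random_tree(12, 100 + seed)
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 12)
        y = 0.3 + 0.8 * x + rng.normal(0, 1, 12)
        cd = make_cd(tree, y, x)
        V = transform_cov(tree, lam=0.6, taxa=cd.taxa)
        fit = gls_fit(cd, V)
        X = cd.X.to_numpy(dtype=float)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ cd.y)
        np.testing.assert_allclose(fit.coef.values, beta, atol=1e-8)

    def test_whitened_residuals_orthogonal_to_design(self):
        from scipy import linalg

        tree = random_tree(15, 7)
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 15)
        y = 0.4 * x + rng.normal(0, 1, 15)
        cd = make_cd(tree, y, x)
        V = brownian_cov(tree, cd.taxa)
        fit = gls_fit(cd, V)
        L = linalg.cholesky(V + 1e-10 * np.eye(15), lower=True)
        Xw = linalg.solve_triangular(L, cd.X.to_numpy(), lower=True)
        yw = linalg.solve_triangular(L, cd.y, lower=True)
        resid = yw - Xw @ fit.coef.values
        assert np.abs(Xw.T @ resid).max() <= 1e-8

    def test_singular_design_rejected(self):
        tree = random_tree(8, 2)
        taxa = sorted(trees.tip_labels(tree))
        X = pd.DataFrame({"intercept": 1.0, "x": 2.0}, index=taxa)  # collinear
        cd = ComparativeData(taxa=taxa, y=np.arange(8.0), X=X, tree=tree)
        with pytest.raises(ValueError, match="singular"):
            gls_fit(cd, np.eye(8))


class TestPglsMl:
    def test_deterministic(self):
        tree = random_tree(30, 4)
        taxa = sorted(trees.tip_labels(tree))
        V = brownian_cov(tree, taxa)
        L = np.linalg.cholesky(V + 1e-10 * np.eye(30))
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = 0.5 * x + L @ rng.standard_normal(30)
        cd = make_cd(tree, y, x)
        f1 = pgls_ml(cd, seed=5)
        f2 = pgls_ml(cd, seed=5)
        assert f1.lam == f2.lam
        assert (f1.coef == f2.coef).all()

    def test_optimum_at_least_as_good_as_grid(self):
        tree = random_tree(25, 9)
        taxa = sorted(trees.tip_labels(tree))
        V = brownian_cov(tree, taxa)
        lamV = 0.5 * V
        np.fill_diagonal(lamV, np.diag(V))
        L = np.linalg.cholesky(lamV + 1e-10 * np.eye(25))
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 25)
        y = 0.5 * x + L @ rng.standard_normal(25)
        cd = make_cd(tree, y, x)
        fit = pgls_ml(cd, seed=0)
        for lam in np.linspace(0, 1, 11):
            Vl = transform_cov(tree, lam=lam, taxa=cd.taxa)
            assert fit.loglik >= gls_fit(cd, Vl).loglik - 1e-6

    def test_boundary_flagging(self):
        tree = random_tree(20, 3)
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 20)
        y = 0.5 * x + rng.normal(0, 0.1, 20)  # phylogeny-free noise
        cd = make_cd(tree, y, x)
        fit = pgls_ml(cd, seed=0)
        if fit.lam <= 1e-5:
            assert fit.boundary["lambda"]

    def test_unknown_parameter_rejected(self):
        tree = random_tree(10, 0)
        rng = np.random.default_rng(0)
        cd = make_cd(tree, rng.normal(0, 1, 10), rng.normal(0, 1, 10))
        with pytest.raises(ValueError, match="unknown transform"):
            pgls_ml(cd, optimize_params=("alpha",))


class TestMaybeDropIntercept:
    def _fit(self, y, x, tree):
        cd = make_cd(tree, y, x)
        V = brownian_cov(tree, cd.taxa)
        return gls_fit(cd, V), cd

    def test_insignificant_intercept_dropped(self):
        tree = random_tree(25, 6)
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 25)
        y = 2.0 * x + 0.05 * rng.normal(0, 1, 25)  # through the origin
        fit, cd = self._fit(y, x, tree)
        out = maybe_drop_intercept(fit, cd)
        assert not out.has_intercept
        assert out.alternative is fit

    def test_significant_intercept_kept(self):
        tree = random_tree(25, 8)
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 25)
        y = 10.0 + 0.5 * x + 0.1 * rng.normal(0, 1, 25)
        fit, cd = self._fit(y, x, tree)
        out = maybe_drop_intercept(fit, cd)
        assert out is fit

    def test_origin_data_selects_origin_model(self):
        # simulation check on a smaller replicate count than the generative
        # contract states; sign conventions identical
        tree = random_tree(30, 11)
        taxa = sorted(trees.tip_labels(tree))
        picked = 0
        n_sim = 50
        for s in range(n_sim):
            rng = np.random.default_rng(30_000 + s)
            x = rng.normal(0, 1, 30)
            y = 0.8 * x + rng.normal(0, 0.3, 30)
            cd = make_cd(tree, y, x)
            fit = gls_fit(cd, np.eye(30))
            if not maybe_drop_intercept(fit, cd).has_intercept:
                picked += 1
        assert picked >= 0.9 * n_sim
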