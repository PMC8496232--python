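"""Penalized regression: closed-form/KKT oracles, limit equivalences,
cross-validated tuning behavior."""

import numpy as np
import pytest

from gpqtl import gp_methods as gpm


@pytest.fixture
def toy(rng):
    X = rng.standard_normal((20, 50))
    y = X[:, :3] @ np.array([2.0, -1.0, 1.5]) + rng.standard_normal(20)
    return X, y


def _standardized(X, y):
    Z = (X - X.mean(0)) / X.std(0)
    return Z, y - y.mean()


class TestRidge:
    def test_matches_closed_form(self, rng):
        X = rng.standard_normal((10, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 0.3 * rng.standard_normal(10)
        lam = 0.7
        fit = gpm.fit_path(X, y, "RR", lambda_grid_values=[lam])[0]
        Z, yc = _standardized(X, y)
        oracle = np.linalg.solve(Z.T @ Z + 10 * lam * np.eye(3), Z.T @ yc)
        np.testing.assert_allclose(fit.beta[:, 0] * X.std(0), oracle,
                                   atol=1e-10)

    def test_selects_everything(self, toy):
        X, y = toy
        fit = gpm.fit_path(X, y, "RR", lambda_grid_values=[0.1])[0]
        assert fit.n_selected == X.shape[1]

    def test_lambda_zero_limit_equals_ols(self, rng):
        X = rng.standard_normal((30, 4))
        y = X @ np.array([1.0, 0.5, -1.0, 2.0]) + rng.standard_normal(30)
        fit = gpm.fit_path(X, y, "RR", lambda_grid_values=[1e-12])[0]
        pred = gpm.predict(fit, X)[:, 0]
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(30), X]), y, rcond=None
        )
        np.testing.assert_allclose(
            pred, np.column_stack([np.ones(30), X]) @ coef, atol=1e-6
        )


class TestLassoKkt:
    def test_kkt_conditions_along_path(self, toy):
        """The returned solutions are stationary points of the objective."""
        X, y = toy
        n = X.shape[0]
        fits = gpm.fit_path(X, y, "LASSO")
        Z, yc = _standardized(X, y)
        for fit in fits[::7]:
            b = fit.beta[:, 0] * X.std(0)
            c = Z.T @ (yc - Z @ b) / n
            active = b != 0
            if active.any():
                np.testing.assert_allclose(
                    c[active], fit.lam * np.sign(b[active]), atol=1e-5
                )
            if (~active).any():
                assert np.all(np.abs(c[~active]) <= fit.lam * (1 + 1e-4) + 1e-8)

    def test_matches_external_solver(self, toy):
        """Independent check against scikit-learn's coordinate descent."""
        from sklearn.linear_model import ElasticNet

        X, y = toy
        Z, yc = _standardized(X, y)
        for a in (1.0, 0.4):
            method = "LASSO" if a == 1.0 else "EN"
            lams = np.geomspace(0.4, 0.01, 6)
            fits = gpm.fit_path(X, y, method, alpha=a,
                                lambda_grid_values=lams)
            for fit in fits:
                sk = ElasticNet(alpha=fit.lam, l1_ratio=a,
                                fit_intercept=False, tol=1e-10,
                                max_iter=200_000).fit(Z, yc)
                np.testing.assert_allclose(
                    fit.beta[:, 0] * X.std(0), sk.coef_, atol=2e-4
                )

    def test_above_lambda_max_all_zero(self, toy):
        X, y = toy
        Z, yc = _standardized(X, y)
        lmax = gpm.lambda_max(Z, yc[:, None], 1.0, False)
        fit = gpm.fit_path(X, y, "LASSO",
                           lambda_grid_values=[lmax * 1.01])[0]
        assert fit.n_selected == 0
        np.testing.assert_allclose(gpm.predict(fit, X)[:, 0], y.mean())


class TestEnNesting:
    def test_alpha_limits_reproduce_rr_and_lasso(self, toy):
        X, y = toy
        lams = np.geomspace(0.5, 0.01, 8)
        lasso = gpm.fit_path(X, y, "LASSO", lambda_grid_values=lams)
        en1 = gpm.fit_path(X, y, "EN", alpha=1.0, lambda_grid_values=lams)
        for a, b in zip(lasso, en1):
            np.testing.assert_allclose(a.beta, b.beta, atol=1e-6)
        rr = gpm.fit_path(X, y, "RR", lambda_grid_values=lams)
        en0 = gpm.fit_path(X, y, "EN", alpha=0.0, lambda_grid_values=lams)
        for a, b in zip(rr, en0):
            np.testing.assert_allclose(a.beta, b.beta, atol=1e-6)

    def test_objective_not_worse_than_zero_or_ols(self, toy):
        X, y = toy
        for method, a in [("LASSO", 1.0), ("EN", 0.5), ("RR", 0.0)]:
            fit = gpm.fit_path(X, y, method, alpha=a,
                               lambda_grid_values=[0.2])[0]
            obj = gpm.objective_value(X, y, fit)
            zero = gpm.PenalizedFit(method, a, 0.2,
                                    np.array([y.mean()]),
                                    np.zeros((X.shape[1], 1)))
            assert obj <= gpm.objective_value(X, y, zero) + 1e-10

    def test_shrinkage_monotone_in_lambda(self, toy):
        # the penalized-scale L1 norm never shrinks as lambda decreases;
        # slack covers the near-degenerate saturated end of the path
        X, y = toy
        fits = gpm.fit_path(X, y, "LASSO")  # lams decreasing
        sd = X.std(0)
        norms = [np.abs(f.beta[:, 0] * sd).sum() for f in fits]
        assert all(b >= a - 1e-6 for a, b in zip(norms[:-1], norms[1:]))


class TestMultitask:
    def test_group_support_identical_across_traits(self, rng):
        X = rng.standard_normal((25, 40))
        Y = np.column_stack([
            X[:, :3] @ [1.0, -1.0, 0.5] + rng.standard_normal(25),
            X[:, :3] @ [0.5, 1.0, -0.5] + rng.standard_normal(25),
        ])
        for method in ("MTV_LASSO", "MTV_EN"):
            fits = gpm.fit_path(X, Y, method, alpha=0.6)
            for f in fits[::13]:
                nz = f.beta != 0
                np.testing.assert_array_equal(nz[:, 0], nz[:, 1])

    def test_matches_external_multitask_solver(self, rng):
        from sklearn.linear_model import MultiTaskElasticNet

        X = rng.standard_normal((30, 60))
        Y = np.column_stack([
            X[:, :4] @ [2, -1, 1.5, 1.0] + rng.standard_normal(30),
            X[:, :4] @ [1, 1, -1.0, 0.5] + rng.standard_normal(30),
        ])
        Z = (X - X.mean(0)) / X.std(0)
        Yc = Y - Y.mean(0)
        fits = gpm.fit_path(X, Y, "MTV_EN", alpha=0.6,
                            lambda_grid_values=np.geomspace(0.5, 0.02, 5))
        for fit in fits:
            sk = MultiTaskElasticNet(alpha=fit.lam, l1_ratio=0.6,
                                     fit_intercept=False, tol=1e-12,
                                     max_iter=200_000).fit(Z, Yc)
            np.testing.assert_allclose(fit.beta * X.std(0)[:, None],
                                       sk.coef_.T, atol=5e-4)


class TestPredict:
    def test_permutation_equivariance(self, toy, rng):
        X, y = toy
        fit = gpm.fit_path(X, y, "LASSO", lambda_grid_values=[0.05])[0]
        perm = rng.permutation(X.shape[0])
        np.testing.assert_allclose(
            gpm.predict(fit, X[perm]), gpm.predict(fit, X)[perm]
        )

    def test_column_mismatch_rejected(self, toy):
        X, y = toy
        fit = gpm.fit_path(X, y, "LASSO", lambda_grid_values=[0.05])[0]
        with pytest.raises(ValueError, match="columns"):
            gpm.predict(fit, X[:, :10])


class TestTuneByCv:
    def test_pure_noise_keeps_sparse_model(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((40, 80))
            y = r.standard_normal(40)
            fit = gpm.tune_by_cv(X, y, "LASSO", lambda_count=20,
                                 k_folds=5, seed=seed)
            if fit.n_selected <= 5:
                hits += 1
        assert hits >= 15  # null data: near-empty models in most seeds

    def test_strong_signal_recovered(self, small_design):
        import gpqtl

        gm, _, X = small_design
        found = 0
        for seed in range(10):
            cfg = gpqtl.SimulationConfig(s=2, h2=0.9, base_seed=100 + seed)
            panel = gpqtl.trait_sim.simulate_replicate(X, gm, cfg)
            fit = gpm.tune_by_cv(X.X, panel.Y[:, 0], "LASSO",
                                 lambda_count=20, seed=seed, tol=1e-4)
            sel_markers = set(
                X.marker_of_column()[np.flatnonzero(fit.selected)]
            )
            truth_idx = gm.marker_index(panel.effects.qtl_markers[0])
            cm = gm.df["pos_cM"].to_numpy()
            chrom = gm.df["chrom"].to_numpy()
            sel_idx = gm.marker_index(list(sel_markers))
            ok = all(
                any(
                    chrom[i] == chrom[j] and abs(cm[i] - cm[j]) <= 2.0
                    for j in sel_idx
                )
                for i in truth_idx
            )
            found += ok
        assert found >= 9

    def test_en_alpha1_equals_lasso_on_same_folds(self, toy):
        X, y = toy
        folds = gpm.cv_folds(len(y), 4, seed=5)
        f1 = gpm.tune_by_cv(X, y, "LASSO", lambda_count=15, folds=folds)
        f2 = gpm.tune_by_cv(X, y, "EN", alpha_grid=[1.0], lambda_count=15,
                            folds=folds)
        assert f1.lam == f2.lam
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-8)

    def test_constant_fold_response_rejected(self):
        X = np.random.default_rng(0).standard_normal((12, 5))
        y = np.r_[np.zeros(11), 1.0]
        with pytest.raises(ValueError):
            gpm.tune_by_cv(X, y, "LASSO", lambda_count=5, k_folds=6, seed=0)

    def test_constant_columns_preserved_with_zero_coef(self, toy):
        X, y = toy
        X = X.copy()
        X[:, 7] = 3.14
        fit = gpm.fit_path(X, y, "LASSO", lambda_grid_values=[0.05])[0]
        assert fit.beta.shape[0] == X.shape[1]
        assert fit.beta[7, 0] == 0.0
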