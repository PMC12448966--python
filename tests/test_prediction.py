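"""L1-penalized regression, LOO λ selection, and the validation battery."""

import numpy as np
import pytest

from sofnet.prediction import (
    feature_removal_test,
    final_fit_and_report,
    lambda_grid,
    lambda_max,
    lasso_path_fit,
    loo_validate,
    permutation_test,
    select_lambda_loo,
    vif,
)


def planted_problem(rng, n=33, p=45, k=3, noise=0.02):
    """y linear in k features plus noise; returns (X, y, support)."""
    k = min(k, p)
    X = rng.normal(size=(n, p))
    support = list(range(k))
    beta = np.array([0.04, 0.03, -0.035])[:k]
    y = 0.3 + X[:, support] @ beta + noise * rng.normal(size=n)
    return X, y, support


class TestLassoPathFit:
    def test_lambda_max_zeroes_everything(self, rng):
        X, y, _ = planted_problem(rng)
        beta, _ = lasso_path_fit(X, y, lambda_max(X, y) * 1.0001)
        assert (beta == 0).all()

    def test_lambda_zero_matches_ols(self, rng):
        X, y, _ = planted_problem(rng, n=60, p=10)
        beta, intercept = lasso_path_fit(X, y, 0.0)
        A = np.column_stack([np.ones(60), X])
        ols = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(beta.to_numpy(), ols[1:], atol=1e-6)
        assert intercept == pytest.approx(ols[0], abs=1e-6)

    def test_orthonormal_design_soft_thresholds(self, rng):
        """On an orthonormal (in the 1/n inner product) design the solution
        is exactly the soft-thresholded OLS coefficient."""
        n, p = 64, 6
        q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = q * np.sqrt(n)  # columns: mean≈0 removed below, ⟨x,x⟩/n = 1
        X = X - X.mean(axis=0)
        X = X / X.std(axis=0)
        # re-orthonormalize after standardization
        q, _ = np.linalg.qr(X)
        X = q * np.sqrt(n)
        y = rng.normal(size=n)
        lam = 0.05
        beta, _ = lasso_path_fit(X, y, lam)
        yc = y - y.mean()
        ols = X.T @ yc / n
        sd = X.std(axis=0)
        expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0) / sd
        np.testing.assert_allclose(beta.to_numpy(), expected, atol=1e-6)

    def test_kkt_conditions_hold(self, rng):
        X, y, _ = planted_problem(rng)
        lam = lambda_max(X, y) / 10
        beta, _ = lasso_path_fit(X, y, lam)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        beta_s = beta.to_numpy() * X.std(axis=0)
        yc = y - y.mean()
        grad = Xs.T @ (yc - Xs @ beta_s) / len(y)
        zero = beta_s == 0
        assert np.all(np.abs(grad[zero]) <= lam + 1e-5)
        nz = ~zero
        np.testing.assert_allclose(
            grad[nz], lam * np.sign(beta_s[nz]), atol=1e-5
        )

    def test_non_finite_inputs_rejected(self, rng):
        X, y, _ = planted_problem(rng)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            lasso_path_fit(X, y, 0.01)


class TestSelectLambdaLoo:
    def test_recovers_planted_support(self, rng):
        X, y, support = planted_problem(rng, noise=0.005)
        lam, cv = select_lambda_loo(X, y)
        beta, _ = lasso_path_fit(X, y, lam)
        selected = set(np.flatnonzero(beta.to_numpy() != 0))
        assert set(support) <= selected

    def test_cv_curve_covers_grid(self, rng):
        X, y, _ = planted_problem(rng)
        grid = lambda_grid(X, y)
        _, cv = select_lambda_loo(X, y, grid)
        assert len(cv) == len(grid)
        assert cv.notna().all()

    def test_degenerate_y_rejected(self, rng):
        X, _, _ = planted_problem(rng)
        with pytest.raises(ValueError):
            select_lambda_loo(X, np.full(33, 0.3))


class TestLooValidate:
    def test_empty_support_flagged(self, rng):
        X, y, _ = planted_problem(rng)
        preds, r = loo_validate(X, y, [])
        assert r is None
        assert np.isnan(preds).all()

    def test_constant_cohort_flagged(self):
        X = np.tile(np.array([[0.1, -0.2, 0.3]]), (10, 1))
        y = np.full(10, 0.3)
        preds, r = loo_validate(X, y, [0, 1])
        assert r is None

    def test_order_invariance(self, rng):
        X, y, support = planted_problem(rng)
        preds, _ = loo_validate(X, y, support)
        perm = rng.permutation(len(y))
        preds_p, _ = loo_validate(X[perm], y[perm], support)
        np.testing.assert_allclose(preds_p, preds[perm], atol=1e-10)

    def test_optimism_gap(self, rng):
        """Held-out correlation falls below the refit correlation on noisy
        planted problems (seeded repetition)."""
        gaps = []
        for seed in range(8):
            r = np.random.default_rng(seed)
            X, y, _ = planted_problem(r, noise=0.03)
            rep = final_fit_and_report(X, y)
            if rep.loo_r is not None and not rep.is_null:
                gaps.append(rep.fitted_r - rep.loo_r)
        assert len(gaps) >= 6
        assert np.mean([g > 0 for g in gaps]) >= 0.95


class TestFeatureRemoval:
    def test_removing_nothing_reproduces_final_fit(self, rng):
        X, y, _ = planted_problem(rng)
        names = [f"f{j}" for j in range(X.shape[1])]
        full = final_fit_and_report(X, y, names)
        removed = feature_removal_test(X, y, [], names)
        assert removed.lambda_selected == full.lambda_selected
        np.testing.assert_allclose(
            removed.beta.to_numpy(), full.beta.to_numpy()
        )

    def test_removing_all_signal_yields_null_model(self, rng):
        X, y, support = planted_problem(rng, noise=0.005)
        names = [f"f{j}" for j in range(X.shape[1])]
        reduced = feature_removal_test(
            X, y, [names[j] for j in support], names
        )
        assert reduced.is_null

    def test_removing_every_feature_rejected(self, rng):
        X, y, _ = planted_problem(rng, p=2)
        with pytest.raises(ValueError):
            feature_removal_test(X, y, ["f0", "f1"], ["f0", "f1"])


class TestVif:
    def test_orthogonal_columns_unit_vif(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(50, 4)))
        out = vif(q - q.mean(axis=0))
        for v in out.values():
            assert v == pytest.approx(1.0, abs=0.1)

    def test_duplicated_column_infinite(self, rng):
        x = rng.normal(size=50)
        out = vif(np.column_stack([x, x, rng.normal(size=50)]))
        assert out["x0"] == np.inf and out["x1"] == np.inf

    def test_r2_point_nine_gives_ten(self, rng):
        """x3 built so that R² against (x1, x2) is exactly 0.9 ⇒ VIF = 10."""
        n = 20000
        x1, x2 = rng.normal(size=(2, n))
        signal = (x1 + x2) / np.sqrt(2)  # unit variance
        noise = rng.normal(size=n)
        noise -= np.polyval(
            np.polyfit(signal, noise, 1), signal
        )  # orthogonalize
        noise /= noise.std()
        x3 = np.sqrt(0.9) * signal + np.sqrt(0.1) * noise
        out = vif(np.column_stack([x1, x2, x3]))
        assert out["x2"] == pytest.approx(10.0, rel=0.05)


class TestPermutationTest:
    def test_reproducible_and_add_one_corrected(self, rng):
        X, y, _ = planted_problem(rng, n=20, p=8, noise=0.01)
        a = permutation_test(X, y, n_shuffles=20, seed=5)
        b = permutation_test(X, y, n_shuffles=20, seed=5)
        assert a == b
        assert a.empirical_p >= 1 / 21  # add-one floor
        assert a.frac_null_models + a.frac_converged == pytest.approx(1.0)

    def test_unshuffled_outcome_classifies_as_comparable(self, rng):
        """Refitting the unpermuted phenotype reproduces the observed fit, so
        the identity permutation always lands in the comparable class."""
        X, y, _ = planted_problem(rng, n=20, p=8, noise=0.01)
        rep = final_fit_and_report(X, y)
        again = final_fit_and_report(X, y)
        assert not again.is_null
        assert again.fitted_r >= rep.fitted_r - 1e-12
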