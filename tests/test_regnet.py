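"""Coordinate-descent elastic net: closed-form oracles, reference
implementation equivalence, path/CV selection, and the published model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from elincnet import regnet
from elincnet.regnet import (
    PUBLISHED_MODEL,
    ConvergenceError,
    RegNetModel,
    classify,
    fit,
    lambda_grid,
    lambda_path_cv,
    prss,
    response_vector,
    score,
    select_alpha,
    soft_threshold,
    train,
)


def standardized_problem(seed, n=60, p=5, coefs=(1.5, -2.0, 0.0, 0.0, 0.5), noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    Xs = (X - X.mean(0)) / X.std(0)
    y = Xs @ np.asarray(coefs[:p]) + rng.normal(0, noise, n)
    return Xs, y


class TestSoftThreshold:
    @pytest.mark.parametrize("z,g,expected", [(3, 1, 2), (0.5, 1, 0), (-3, 1, -2)])
    def test_examples(self, z, g, expected):
        assert soft_threshold(z, g) == expected

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)

    @given(z=st.floats(-100, 100), g=st.floats(0, 50))
    def test_odd_and_shrinking(self, z, g):
        s = soft_threshold(z, g)
        assert s == pytest.approx(-soft_threshold(-z, g))
        assert abs(s) <= max(abs(z) - g, 0) + 1e-12


class TestPrss:
    def test_reduces_to_scaled_rss_without_penalty(self):
        Xs, y = standardized_problem(0)
        b = np.array([1.0, -1.0, 0.5, 0.0, 0.0])
        r = y - Xs @ b
        assert prss(b, 0.0, Xs, y, 0.5, 0.0) == pytest.approx(r @ r / (2 * len(y)))

    def test_zero_beta_gives_intercept_only_rss(self):
        Xs, y = standardized_problem(1)
        b0 = y.mean()
        assert prss(np.zeros(5), b0, Xs, y, 1.0, 0.3) == pytest.approx(
            np.sum((y - b0) ** 2) / (2 * len(y))
        )

    def test_alpha_limits_recover_lasso_and_ridge_penalties(self):
        Xs, y = standardized_problem(2)
        b = np.array([1.0, -2.0, 0.0, 3.0, 0.0])
        base = prss(b, 0.0, Xs, y, 0.5, 0.0)
        lam = 0.7
        assert prss(b, 0.0, Xs, y, 1.0, lam) == pytest.approx(
            base + lam * np.abs(b).sum()
        )
        assert prss(b, 0.0, Xs, y, 0.0, lam) == pytest.approx(
            base + lam * 0.5 * (b**2).sum()
        )

    def test_parameter_validation(self):
        Xs, y = standardized_problem(3)
        with pytest.raises(ValueError):
            prss(np.zeros(5), 0.0, Xs, y, 1.5, 0.1)
        with pytest.raises(ValueError):
            prss(np.zeros(5), 0.0, Xs, y, 0.5, -0.1)


class TestFitClosedForms:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ridge_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 3))
        Xs = (X - X.mean(0)) / X.std(0)
        y = rng.normal(size=10)
        lam = 0.4
        yc = y - y.mean()
        expected = np.linalg.solve(Xs.T @ Xs / 10 + lam * np.eye(3), Xs.T @ yc / 10)
        m = fit(Xs, y, alpha=0.0, lam=lam)
        np.testing.assert_allclose(m.betas.to_numpy(), expected, atol=1e-6)

    def test_lasso_on_orthonormal_design_soft_thresholds_ols(self):
        rng = np.random.default_rng(4)
        n, p = 40, 4
        raw = rng.normal(size=(n, p + 1))
        raw[:, 0] = 1.0
        q, _ = np.linalg.qr(raw)
        Xs = q[:, 1:] * np.sqrt(n)  # mean-0 columns, X'X/n = I, unit variance
        y = rng.normal(size=n)
        lam = 0.15
        m = fit(Xs, y, alpha=1.0, lam=lam)
        ols = Xs.T @ (y - y.mean()) / n
        expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0)
        np.testing.assert_allclose(m.betas.to_numpy(), expected, atol=1e-7)

    def test_zero_lambda_recovers_ols(self):
        Xs, y = standardized_problem(5)
        m = fit(Xs, y, alpha=1.0, lam=0.0)
        A = np.column_stack([np.ones(len(y)), Xs])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(m.betas.to_numpy(), coef[1:], atol=1e-6)
        assert m.beta0 == pytest.approx(coef[0], abs=1e-6)

    @pytest.mark.parametrize("alpha,lam", [(1.0, 0.1), (0.0, 0.3), (0.5, 0.05)])
    def test_matches_reference_elastic_net(self, alpha, lam):
        from sklearn.linear_model import ElasticNet

        Xs, y = standardized_problem(6)
        m = fit(Xs, y, alpha, lam)
        ref = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=True, tol=1e-12, max_iter=200_000
        ).fit(Xs, y)
        np.testing.assert_allclose(m.betas.to_numpy(), ref.coef_, atol=1e-4)
        assert m.beta0 == pytest.approx(ref.intercept_, abs=1e-4)

    def test_objective_monotone_nonincreasing(self):
        Xs, y = standardized_problem(7, n=100, p=8, coefs=(2, -1, 1, 0, 0, 0, 0, 0))
        for alpha in (0.0, 0.5, 1.0):
            m = fit(Xs, y, alpha, 0.05)
            diffs = np.diff(m.objective_path)
            assert np.all(diffs <= 1e-12)

    def test_coefficients_reported_on_original_scale(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 3)) * np.array([1.0, 10.0, 0.1]) + np.array([0, 5, -2])
        y = X @ np.array([1.0, 0.2, -3.0]) + rng.normal(0, 0.1, 50)
        m = fit(X, y, alpha=0.0, lam=1e-8)
        pred = m.beta0 + X @ m.betas.to_numpy()
        np.testing.assert_allclose(pred, y, atol=0.5)

    def test_constant_column_rejected(self):
        Xs, y = standardized_problem(9)
        Xbad = Xs.copy()
        Xbad[:, 2] = 7.0
        with pytest.raises(ValueError, match="constant"):
            fit(Xbad, y, 1.0, 0.1)

    def test_nonconvergence_raises_with_last_iterate(self):
        Xs, y = standardized_problem(10, n=80, p=5)
        with pytest.raises(ConvergenceError) as exc:
            fit(Xs, y, alpha=0.0, lam=1e-6, max_iter=1)
        assert isinstance(exc.value.model, RegNetModel)


class TestLambdaPath:
    def test_grid_starts_at_all_zero_model(self):
        Xs, y = standardized_problem(11)
        lams = lambda_grid(Xs, y, alpha=1.0, n_lambda=20)
        assert np.all(np.diff(lams) < 0)
        m = fit(Xs, y, 1.0, lams[0])
        assert np.all(np.abs(m.betas.to_numpy()) < 1e-8)

    def test_nonzero_count_monotone_in_lambda_at_lasso(self):
        Xs, y = standardized_problem(12, n=80, p=8, coefs=(2, -1, 0.5, 0, 0, 0, 0, 0))
        lams = lambda_grid(Xs, y, alpha=1.0, n_lambda=30)
        nnz = [len(fit(Xs, y, 1.0, l).nonzero_features(1e-9)) for l in lams]
        assert all(a <= b for a, b in zip(nnz[:-1], nnz[1:]))

    def test_planted_features_recovered_at_chosen_lambda(self):
        rng = np.random.default_rng(13)
        n, p = 120, 20
        X = rng.normal(size=(n, p))
        y = 1.2 * X[:, 3] - 1.5 * X[:, 11] + rng.normal(0, 0.4, n)
        path = lambda_path_cv(X, y, alpha=1.0, k=5, n_lambda=50, seed=14)
        m = fit(X, y, 1.0, path.chosen)
        nz = set(m.nonzero_features(1e-6))
        assert {"x3", "x11"} <= nz

    def test_pure_noise_shrinks_to_near_intercept(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(150, 10))
        y = rng.normal(size=150)
        path = lambda_path_cv(X, y, alpha=1.0, k=5, n_lambda=50, seed=16)
        m = fit(X, y, 1.0, path.chosen)
        assert np.all(np.abs(m.betas.to_numpy()) < 0.15)

    def test_deterministic_given_seed(self):
        Xs, y = standardized_problem(17, n=50)
        a = lambda_path_cv(Xs, y, 0.5, k=5, n_lambda=20, seed=18)
        b = lambda_path_cv(Xs, y, 0.5, k=5, n_lambda=20, seed=18)
        assert np.array_equal(a.cv_mse, b.cv_mse) and a.chosen == b.chosen

    def test_needs_enough_observations(self):
        Xs, y = standardized_problem(19, n=5)
        with pytest.raises(ValueError):
            lambda_path_cv(Xs, y, 1.0, k=10, seed=0)


class TestSelectAlpha:
    def test_single_value_grid(self):
        Xs, y = standardized_problem(20, n=50)
        a, path = select_alpha(Xs, y, [0.5], k=5, n_lambda=20, seed=0)
        assert a == 0.5 and path.alpha == 0.5

    def test_empty_or_invalid_grid(self):
        Xs, y = standardized_problem(21, n=50)
        with pytest.raises(ValueError):
            select_alpha(Xs, y, [], k=5, seed=0)
        with pytest.raises(ValueError):
            select_alpha(Xs, y, [0.5, 1.5], k=5, seed=0)

    def test_degenerate_constant_matrix_errors(self):
        X = np.ones((30, 3))
        y = np.arange(30.0)
        with pytest.raises(ValueError):
            select_alpha(X, y, [0.5, 1.0], k=5, seed=0)

    def test_picks_minimal_cv_mse(self):
        rng = np.random.default_rng(22)
        n, p = 100, 15
        X = rng.normal(size=(n, p))
        y = 2.0 * X[:, 0] + rng.normal(0, 0.3, n)
        a, path = select_alpha(X, y, [0.0, 0.5, 1.0], k=5, n_lambda=40, seed=23)
        mses = {
            al: lambda_path_cv(X, y, al, k=5, n_lambda=40, seed=23).best_mse
            for al in [0.0, 0.5, 1.0]
        }
        assert path.best_mse == pytest.approx(min(mses.values()))
        assert mses[a] == pytest.approx(path.best_mse)


class TestPublishedModelScoring:
    def test_intercept_at_zero_vector(self):
        assert score(PUBLISHED_MODEL, np.zeros(7)) == pytest.approx(2.0860)

    @pytest.mark.parametrize(
        "feature,coef",
        [
            ("TSS_DNAme", 5.79),
            ("TSS_H3K4me1", 3.16),
            ("Body_DNAme", 0.53),
            ("Body_H3K122ac", 0.46),
            ("Body_H3K36me3", -5.17),
            ("TSS_H3K9ac", -4.13),
            ("TSS_H3K4me3", -0.87),
        ],
    )
    def test_unit_step_contribution_equals_printed_coefficient(self, feature, coef):
        x = pd.Series(0.0, index=PUBLISHED_MODEL.feature_names)
        x[feature] = 1.0
        assert score(PUBLISHED_MODEL, x) - 2.0860 == pytest.approx(coef)

    def test_worked_classifications(self):
        x = pd.Series(0.0, index=PUBLISHED_MODEL.feature_names)
        x["Body_H3K36me3"] = 1.0
        assert score(PUBLISHED_MODEL, x) == pytest.approx(-3.084)
        assert classify(PUBLISHED_MODEL, x) == "canonical"
        x["Body_H3K36me3"], x["TSS_DNAme"] = 0.0, 1.0
        assert score(PUBLISHED_MODEL, x) == pytest.approx(7.876)
        assert classify(PUBLISHED_MODEL, x) == "elinc"

    def test_score_zero_is_indeterminate(self):
        m = RegNetModel(1.0, 0.0, 0.0, pd.Series({"a": 1.0}))
        assert classify(m, np.array([0.0])) == "indeterminate"

    def test_misaligned_feature_names_error(self):
        with pytest.raises(KeyError):
            score(PUBLISHED_MODEL, pd.Series({"TSS_DNAme": 1.0}))
        with pytest.raises(ValueError):
            score(PUBLISHED_MODEL, np.zeros(6))


class TestModelPlumbing:
    def test_response_vector_coding(self):
        np.testing.assert_array_equal(
            response_vector(["elinc", "canonical", "elinc"]), [1.0, -1.0, 1.0]
        )
        with pytest.raises(ValueError):
            response_vector(["elinc", "other"])

    def test_json_round_trip(self, tmp_path):
        Xs, y = standardized_problem(24)
        m = fit(Xs, y, 0.5, 0.1)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = RegNetModel.from_json(path)
        assert back.alpha == m.alpha and back.lam == m.lam
        np.testing.assert_allclose(back.betas.to_numpy(), m.betas.to_numpy())
        assert back.beta0 == pytest.approx(m.beta0)

    def test_train_auto_alpha_runs(self):
        rng = np.random.default_rng(25)
        X = rng.normal(size=(60, 6))
        y = np.where(X[:, 0] + 0.1 * rng.normal(size=60) > 0, 1.0, -1.0)
        model, path = train(X, y, alpha="auto", alphas=(0.0, 1.0), k=5, n_lambda=25, seed=26)
        assert model.alpha == path.alpha
        assert model.lam == path.chosen
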