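"""Gaussian-process engine: kernel, training, prediction, portable export."""

import numpy as np
import pytest
from scipy import linalg

import toatrait as tt
from toatrait.gpr import GPRHyperparams, GPRModel, kernel_matrix


def naive_predict(model, X_query):
    """Dense oracle: explicit matrix inversion, direct mean/variance formulas."""
    hyper = model.hyper
    Xn = model.Xn
    yn = (model.y_train - model.y_mean) / model.y_sd
    N = Xn.shape[0]
    K = kernel_matrix(Xn, Xn, hyper) + (hyper.sigma_n2 + model.jitter) * np.eye(N)
    Kinv = np.linalg.inv(K)
    Xq = (np.atleast_2d(X_query) - model.x_mean) / model.x_sd
    means, variances = [], []
    for x in Xq:
        k_star = np.array([tt.kernel(x, xi, hyper) for xi in Xn])
        c_star = tt.kernel(x, x, hyper) + hyper.sigma_n2
        means.append(k_star @ Kinv @ yn)
        variances.append(c_star - k_star @ Kinv @ k_star)
    mean = model.y_mean + model.y_sd * np.array(means)
    var = model.y_sd**2 * np.array(variances)
    return mean, var


@pytest.fixture(scope="module")
def toy_model():
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 1, (40, 3))
    y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2 + 0.1 * rng.standard_normal(40)
    return tt.train(X, y, tt.TrainConfig(n_restarts=2), seed=1)


class TestKernel:
    def test_zero_distance_is_signal_variance(self):
        h = GPRHyperparams(2.5, np.ones(4), 0.1)
        x = np.arange(4.0)
        assert tt.kernel(x, x, h) == pytest.approx(2.5)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        h = GPRHyperparams(1.3, rng.uniform(0.5, 2, 5), 0.01)
        for _ in range(10):
            a, b = rng.standard_normal(5), rng.standard_normal(5)
            assert tt.kernel(a, b, h) == pytest.approx(tt.kernel(b, a, h), rel=1e-14)

    def test_direct_formula_value(self):
        # D=1, sigma_s2=2, sigma_b=2, |xi-xj|=2 -> 2 exp(-1/2) ~ 1.21306
        h = GPRHyperparams(2.0, np.array([2.0]), 0.1)
        assert tt.kernel(np.array([0.0]), np.array([2.0]), h) == pytest.approx(
            2.0 * np.exp(-0.5), abs=1e-5)

    def test_dimension_mismatch(self):
        h = GPRHyperparams(1.0, np.ones(3), 0.1)
        with pytest.raises(ValueError):
            tt.kernel(np.zeros(2), np.zeros(3), h)

    def test_positive_hyperparameters_enforced(self):
        with pytest.raises(ValueError):
            GPRHyperparams(-1.0, np.ones(2), 0.1)


class TestTraining:
    def test_lengthscale_recovery(self):
        """Data from a known GP: recovered length-scales within a factor of 2."""
        rng = np.random.default_rng(4)
        N, D = 200, 2
        X = rng.uniform(-2, 2, (N, D))
        true = GPRHyperparams(1.0, np.array([0.5, 2.0]), 1e-4)
        K = kernel_matrix(X, X, true) + true.sigma_n2 * np.eye(N)
        y = linalg.cholesky(K, lower=True) @ rng.standard_normal(N)
        model = tt.train(X, y, tt.TrainConfig(n_restarts=3), seed=2)
        # undo the per-band z-scoring to compare in data units
        recovered = model.hyper.sigma_b * model.x_sd
        ratio = recovered / true.sigma_b
        assert np.all((ratio > 0.5) & (ratio < 2.0))

    def test_constant_targets(self):
        X = np.random.default_rng(1).uniform(0, 1, (20, 2))
        with pytest.warns(UserWarning, match="constant"):
            model = tt.train(X, np.full(20, 3.7), tt.TrainConfig(n_restarts=1), seed=0)
        res = tt.predict(model, X)
        np.testing.assert_allclose(res.mean, 3.7, atol=1e-6)

    def test_optimum_not_worse_than_starts(self, toy_model):
        """The returned optimum's log marginal likelihood beats a fresh refit
        at generic initial hyperparameters."""
        init = GPRHyperparams(1.0, np.ones(3), 1e-2)
        at_init = GPRModel.from_hyperparams(
            toy_model.X_train, toy_model.y_train, init)
        assert toy_model.log_marginal_likelihood >= at_init.log_marginal_likelihood - 1e-8

    def test_input_validation(self):
        with pytest.raises(ValueError):
            tt.train(np.ones((1, 2)), np.ones(1))
        X = np.ones((5, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            tt.train(X, np.ones(5))


class TestPrediction:
    def test_interpolation_limit(self):
        """Near-zero noise: the GP interpolates its training targets."""
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (15, 2))
        y = X[:, 0] + X[:, 1]
        h = GPRHyperparams(1.0, np.array([1.0, 1.0]), 1e-10)
        model = GPRModel.from_hyperparams(X, y, h)
        res = tt.predict(model, X[7])
        assert res.mean == pytest.approx(y[7], abs=1e-6)

    def test_prior_reversion_far_away(self, toy_model):
        far = np.full(3, 1e4)
        res = tt.predict(toy_model, far)
        assert res.mean == pytest.approx(float(toy_model.y_train.mean()), rel=1e-6)
        prior_var = toy_model.y_sd**2 * (
            toy_model.hyper.sigma_s2 + toy_model.hyper.sigma_n2)
        assert res.variance == pytest.approx(prior_var, rel=1e-6)

    def test_matches_naive_oracle(self, toy_model):
        """100 random queries equal the dense explicit-inverse oracle to 1e-8."""
        rng = np.random.default_rng(5)
        Xq = rng.uniform(0, 1, (100, 3))
        res = tt.predict(toy_model, Xq)
        mean_o, var_o = naive_predict(toy_model, Xq)
        np.testing.assert_allclose(res.mean, mean_o, atol=1e-8)
        np.testing.assert_allclose(res.variance, var_o, atol=1e-8)

    def test_variance_bounds(self, toy_model):
        rng = np.random.default_rng(6)
        res = tt.predict(toy_model, rng.uniform(-1, 2, (200, 3)))
        prior_var = toy_model.y_sd**2 * (
            toy_model.hyper.sigma_s2 + toy_model.hyper.sigma_n2)
        assert np.all(res.variance >= 0)
        assert np.all(res.variance <= prior_var + 1e-10)

    def test_adding_data_never_increases_variance(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (25, 2))
        y = rng.standard_normal(25)
        h = GPRHyperparams(1.0, np.array([0.7, 0.7]), 1e-3)
        small = GPRModel.from_hyperparams(X[:20], y[:20], h, normalize=False)
        big = GPRModel.from_hyperparams(X, y, h, normalize=False)
        Xq = rng.uniform(0, 1, (50, 2))
        v_small = tt.predict(small, Xq).variance
        v_big = tt.predict(big, Xq).variance
        assert np.all(v_big <= v_small + 1e-10)

    def test_affine_target_invariance(self):
        """Training on a y + b maps predictions through the same affine map."""
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, (60, 2))
        y = np.sin(4 * X[:, 0]) + X[:, 1]
        m1 = tt.train(X, y, tt.TrainConfig(n_restarts=1), seed=3)
        m2 = tt.train(X, 5.0 * y - 2.0, tt.TrainConfig(n_restarts=1), seed=3)
        Xq = rng.uniform(0, 1, (20, 2))
        p1 = tt.predict(m1, Xq)
        p2 = tt.predict(m2, Xq)
        np.testing.assert_allclose(p2.mean, 5.0 * p1.mean - 2.0, atol=1e-6)

    def test_against_sklearn_reference(self, toy_model):
        """Independent cross-check: sklearn's GP with the same fixed
        hyperparameters reproduces our predictive mean and SD."""
        sklearn_gp = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        m = toy_model
        k = ConstantKernel(m.hyper.sigma_s2, "fixed") * RBF(
            m.hyper.sigma_b, "fixed") + WhiteKernel(m.hyper.sigma_n2, "fixed")
        yn = (m.y_train - m.y_mean) / m.y_sd
        gp = GaussianProcessRegressor(kernel=k, alpha=0.0, optimizer=None).fit(m.Xn, yn)
        rng = np.random.default_rng(9)
        Xq = rng.uniform(0, 1, (30, 3))
        Xqn = (Xq - m.x_mean) / m.x_sd
        mu_sk, sd_sk = gp.predict(Xqn, return_std=True)
        res = tt.predict(m, Xq)
        np.testing.assert_allclose(res.mean, m.y_mean + m.y_sd * mu_sk, atol=1e-6)
        # the white-kernel term puts sigma_n2 on the self-covariance diagonal,
        # matching our c* = k(x*,x*) + sigma_n2 convention
        np.testing.assert_allclose(res.variance, m.y_sd**2 * sd_sk**2, atol=1e-6)


class TestPortable:
    def test_equivalence_with_full_model(self, toy_model):
        pm = tt.export_portable(toy_model)
        rng = np.random.default_rng(10)
        Xq = rng.uniform(0, 1, (100, 3))
        full = tt.predict(toy_model, Xq)
        port = tt.predict_portable(pm, Xq)
        np.testing.assert_allclose(port.mean, full.mean, atol=1e-8)
        np.testing.assert_allclose(port.variance, full.variance, atol=1e-8)

    def test_serialization_bit_exact(self, toy_model, tmp_path):
        pm = tt.export_portable(toy_model)
        p = tmp_path / "model.json"
        pm.save(p)
        back = tt.PortableModel.load(p)
        np.testing.assert_array_equal(back.alpha, pm.alpha)
        np.testing.assert_array_equal(back.K_inv, pm.K_inv)
        np.testing.assert_array_equal(back.Xn, pm.Xn)
        np.testing.assert_array_equal(back.hyper.sigma_b, pm.hyper.sigma_b)
        assert back.y_mean == pm.y_mean and back.y_sd == pm.y_sd

    def test_no_optimizer_state_in_document(self, toy_model):
        import json

        doc = json.loads(tt.export_portable(toy_model).to_json())
        assert set(doc) == {
            "schema_version", "trait", "units", "band_centers", "hyperparameters",
            "normalization", "X_train", "alpha", "K_inv", "provenance",
        }

    def test_corrupted_document_rejected(self, toy_model):
        pm = tt.export_portable(toy_model)
        with pytest.raises(ValueError, match="corrupted"):
            tt.PortableModel.from_json(pm.to_json()[:50])
        bad = pm.to_json().replace('"schema_version": 1', '"schema_version": 99')
        with pytest.raises(ValueError, match="schema version"):
            tt.PortableModel.from_json(bad)
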