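"""GP engine: kernels, marginal-likelihood fitting, prediction, persistence.

The exact-GP implementation is cross-checked against (a) a naive
direct-inversion predictor written here from the textbook equations and
(b) scikit-learn's GaussianProcessRegressor with frozen hyperparameters.
"""

import numpy as np
import pytest

import pedzscore as pz
from pedzscore.gp import GPZScore, GPZScoreResults, compute_metrics
from pedzscore.kernels import kernel_gradients, kernel_matrix
from pedzscore.types import OutOfRangeError, ValidationError


def naive_predict(spec, noise, X, t, Xstar):
    """Direct-inversion GP posterior mean/variance (independent oracle)."""
    K = kernel_matrix(spec, X, X) + noise * np.eye(len(X))
    Kinv = np.linalg.inv(K)
    ks = kernel_matrix(spec, Xstar, X)
    mean = ks @ Kinv @ t
    var = spec.signal_variance - np.einsum("ij,jk,ik->i", ks, Kinv, ks) + noise
    return mean, var


def random_inputs(n, d=3, seed=0):
    return np.random.default_rng(seed).normal(size=(n, d))


class TestKernels:
    @pytest.mark.parametrize("family", pz.FAMILIES)
    def test_zero_distance_gives_signal_variance(self, family):
        spec = pz.KernelSpec(family, signal_variance=2.5, length_scale=0.7,
                             alpha=1.3 if family == "rational_quadratic" else None)
        X = random_inputs(6)
        np.testing.assert_allclose(np.diag(kernel_matrix(spec, X, X)), 2.5)

    def test_squared_exponential_closed_form(self):
        spec = pz.KernelSpec("squared_exponential", signal_variance=2.0, length_scale=1.5)
        A = np.array([[0.0, 0.0, 0.0]])
        B = np.array([[1.5, 0.0, 0.0]])  # r = length scale
        assert kernel_matrix(spec, A, B)[0, 0] == pytest.approx(2.0 * np.exp(-0.5))

    @pytest.mark.parametrize("family", pz.FAMILIES)
    def test_symmetric_positive_semidefinite(self, family):
        spec = pz.KernelSpec(family, signal_variance=1.3, length_scale=0.9,
                             alpha=0.8 if family == "rational_quadratic" else None)
        X = random_inputs(40, seed=3)
        K = kernel_matrix(spec, X, X)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        np.linalg.cholesky(K + 1e-8 * np.eye(40))  # PSD up to jitter

    @pytest.mark.parametrize("family", pz.FAMILIES)
    @pytest.mark.parametrize("ard", [False, True])
    def test_gradients_match_finite_differences(self, family, ard):
        ls = (0.8, 1.2, 0.6) if ard else 0.9
        spec = pz.KernelSpec(family, signal_variance=1.4, length_scale=ls,
                             alpha=1.1 if family == "rational_quadratic" else None)
        X = random_inputs(8, seed=5)
        grads = kernel_gradients(spec, X)
        eps = 1e-6

        def perturbed(name, h):
            kw = {}
            if name == "signal_variance":
                kw["signal_variance"] = spec.signal_variance * np.exp(h)
            elif name == "alpha":
                kw["alpha"] = spec.alpha * np.exp(h)
            elif name == "length_scale":
                kw["length_scale"] = spec.length_scale * np.exp(h)
            else:
                d = int(name.rsplit("_", 1)[1])
                new = list(spec.length_scale)
                new[d] *= np.exp(h)
                kw["length_scale"] = tuple(new)
            return kernel_matrix(spec.with_params(**kw), X, X)

        for name, dK in grads.items():
            fd = (perturbed(name, eps) - perturbed(name, -eps)) / (2 * eps)
            np.testing.assert_allclose(dK, fd, atol=1e-6, err_msg=name)

    def test_dimension_mismatch_rejected(self):
        spec = pz.KernelSpec("squared_exponential")
        with pytest.raises(ValidationError):
            kernel_matrix(spec, np.zeros((3, 2)), np.zeros((3, 4)))


class TestFitting:
    def test_same_seed_same_hyperparameters(self, hfa_grid_coarse):
        a, _ = pz.gp_fit(hfa_grid_coarse, seed=11, n_restarts=2, maxiter=60)
        b, _ = pz.gp_fit(hfa_grid_coarse, seed=11, n_restarts=2, maxiter=60)
        assert a.kernel == b.kernel
        assert a.noise_variance == b.noise_variance

    def test_noiseless_toy_interpolates(self):
        rng = np.random.default_rng(2)
        ages = np.linspace(10, 200, 12)
        X = np.column_stack([np.zeros(12), ages, np.sin(ages / 40.0) * 5 + 20])
        t = np.cos(ages / 60.0)
        model = GPZScore(X, t, pz.MeasurementKind.HFA)
        res = model.fit(n_restarts=3, seed=0)
        np.testing.assert_allclose(res.fittedvalues(), t, atol=1e-4)

    def test_marginal_likelihood_improves_on_default_start(self, hfa_grid_coarse):
        model = GPZScore.from_grid(hfa_grid_coarse)
        res = model.fit(n_restarts=2, seed=0, maxiter=120)
        tvar = float(model.t.var())
        theta0 = np.log([tvar, 1.0, 1e-4 * tvar])
        assert res.log_marginal_likelihood >= model.loglike(theta0)

    def test_training_grid_rmse_small(self, gp_hfa_coarse):
        assert gp_hfa_coarse.metrics.rmse <= 0.05
        assert gp_hfa_coarse.metrics.r2_pct > 99.0


class TestPrediction:
    @pytest.mark.parametrize("family", pz.FAMILIES)
    def test_matches_naive_direct_inversion(self, family):
        """Cholesky-based predictor equals the O(n^3) inversion oracle, 1e-8."""
        rng = np.random.default_rng(7)
        n = 150
        X = np.column_stack(
            [rng.integers(0, 2, n), rng.uniform(0, 240, n), rng.uniform(5, 120, n)]
        )
        t = np.sin(X[:, 1] / 50.0) + 0.01 * rng.normal(size=n)
        model = GPZScore(X, t, pz.MeasurementKind.WFA, kernel=family)
        res = model.fit(n_restarts=1, seed=0, maxiter=60)
        m = 40
        sexes = ["male" if c == 0 else "female" for c in X[:m, 0]]
        mean, var = res.predict(sexes, X[:m, 1], X[:m, 2] + 0.37)
        Xstar = (np.column_stack([X[:m, 0], X[:m, 1], X[:m, 2] + 0.37]) -
                 model.shift) / model.scale
        mean0, var0 = naive_predict(res.kernel, res.noise_variance, model.Xs, t, Xstar)
        np.testing.assert_allclose(mean, mean0, atol=1e-8)
        np.testing.assert_allclose(var, var0, atol=1e-8)

    def test_matches_sklearn_frozen_hyperparameters(self):
        sklearn_gp = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        rng = np.random.default_rng(9)
        n = 60
        X = np.column_stack(
            [rng.integers(0, 2, n), rng.uniform(0, 240, n), rng.uniform(5, 120, n)]
        )
        t = np.cos(X[:, 1] / 70.0)
        model = GPZScore(X, t, pz.MeasurementKind.WFA)
        spec = pz.KernelSpec("squared_exponential", signal_variance=1.7, length_scale=0.8)
        res = GPZScoreResults(model, spec, noise_variance=1e-3)
        sk = sklearn_gp.GaussianProcessRegressor(
            kernel=ConstantKernel(1.7, "fixed") * RBF(0.8, "fixed"),
            alpha=1e-3, optimizer=None,
        ).fit(model.Xs, t)
        Xq = model.Xs[::3] * 1.05
        mean_sk = sk.predict(Xq)
        ks = kernel_matrix(spec, Xq, model.Xs)
        mean_us = ks @ res.dual_coefficients
        np.testing.assert_allclose(mean_us, mean_sk, atol=1e-8)

    def test_training_point_reproduced_with_tiny_noise(self):
        rng = np.random.default_rng(4)
        n = 30
        X = np.column_stack(
            [rng.integers(0, 2, n), rng.uniform(0, 240, n), rng.uniform(5, 120, n)]
        )
        t = np.sin(X[:, 1] / 40.0)
        model = GPZScore(X, t, pz.MeasurementKind.HFA)
        spec = pz.KernelSpec("squared_exponential", signal_variance=2.0, length_scale=0.5)
        res = GPZScoreResults(model, spec, noise_variance=1e-10)
        np.testing.assert_allclose(res.fittedvalues(), t, atol=1e-6)

    def test_prior_reversion_far_from_data(self, hfa_grid_coarse):
        model = GPZScore.from_grid(hfa_grid_coarse)
        spec = pz.KernelSpec("squared_exponential", signal_variance=2.0,
                             length_scale=0.3)
        res = GPZScoreResults(model, spec, noise_variance=1e-4)
        # a 240-month-old with an absurd 5 cm height is far from everything
        mean, var = res.predict(["male"], [240.0], [5.0])
        assert abs(mean[0]) < 1e-3
        assert var[0] == pytest.approx(2.0 + 1e-4, rel=1e-3)

    def test_kind_and_range_checks(self, gp_hfa_coarse):
        with pytest.raises(ValidationError):
            pz.gp_predict(
                gp_hfa_coarse,
                pz.Observation(pz.Sex.MALE, 24.0, 12.0, pz.MeasurementKind.WFA),
            )
        with pytest.raises(OutOfRangeError):
            gp_hfa_coarse.predict(["male"], [250.0], [100.0])


class TestPersistence:
    def test_save_load_predicts_identically(self, tmp_path, gp_hfa_coarse):
        path = tmp_path / "model.json"
        gp_hfa_coarse.save(path)
        loaded = pz.load_model(path)
        obs = pz.Observation(pz.Sex.FEMALE, 50.0, 101.0, pz.MeasurementKind.HFA)
        assert pz.gp_predict(loaded, obs) == pz.gp_predict(gp_hfa_coarse, obs)

    def test_loaded_metrics_recompute_to_saved(self, tmp_path, gp_hfa_coarse):
        import json

        path = tmp_path / "model.json"
        gp_hfa_coarse.save(path)
        saved = json.loads(path.read_text())["metrics"]
        loaded = pz.load_model(path)
        assert loaded.metrics.rmse == pytest.approx(saved["rmse"], abs=1e-12)

    def test_tampered_model_rejected(self, tmp_path, gp_hfa_coarse):
        import json

        path = tmp_path / "model.json"
        gp_hfa_coarse.save(path)
        doc = json.loads(path.read_text())
        doc["kernel"]["length_scale"] = [-1.0]
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError):
            pz.load_model(path)
        doc["kernel"]["length_scale"] = [1.0]
        doc["schema_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError):
            pz.load_model(path)


class TestMetrics:
    def test_perfect_and_constant_predictions(self):
        t = np.array([0.0, 1.0, 2.0])
        m = compute_metrics(t, t)
        assert (m.r2_pct, m.rmse) == (100.0, 0.0)
        m = compute_metrics(t, np.full(3, t.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        m = compute_metrics([0.0, 1.0, 2.0], [0.0, 1.0, 1.0])
        assert m.mse == pytest.approx(1.0 / 3.0)
        assert m.rmse == pytest.approx(np.sqrt(1.0 / 3.0))
        assert m.mae == pytest.approx(1.0 / 3.0)
        assert m.rmse == pytest.approx(np.sqrt(m.mse))
        assert m.mae <= m.rmse

    def test_zero_variance_truth_flagged(self):
        m = compute_metrics([1.0, 1.0, 1.0], [1.0, 1.1, 0.9])
        assert m.degenerate and np.isnan(m.r2)


class TestKernelComparison:
    def test_four_family_report(self):
        table = pz.synth_lms_table(
            pz.MeasurementKind.HFA, np.arange(0.0, 241.0, 48.0), seed=3
        )
        grid = pz.grid_from_lms(table)
        report = pz.compare_kernels(grid, seed=0, n_restarts=1, maxiter=50)
        assert set(report["family"]) == set(pz.FAMILIES)
        assert np.isfinite(report[["r2_pct", "rmse", "mse", "mae"]].to_numpy()).all()
        assert report["rmse"].is_monotonic_increasing
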