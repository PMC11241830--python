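"""Weighted kernel, LS-SVM solve, PSO training loop and figures of merit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csarray import vwls
from csarray.datasets import NoiseSpec, generate_single_analyte
from csarray.pso import PSOConfig
from csarray.vwls import (
    WeightedKernelSpec,
    figures_of_merit,
    lod_loq,
    lssvm_fit,
    lssvm_predict,
    train_pso_vwls_svm,
    weighted_kernel_matrix,
)


def spec_of(w, s2=1.0, g=10.0):
    return WeightedKernelSpec(np.asarray(w, float), s2, g)


class TestWeightedKernel:
    def test_unit_diagonal_when_z_is_x(self, rng):
        X = rng.normal(size=(6, 4))
        K = weighted_kernel_matrix(X, X, spec_of(rng.uniform(size=4)))
        assert np.allclose(np.diag(K), 1.0)
        assert np.allclose(K, K.T)

    def test_zero_weights_collapse_kernel_to_one(self, rng):
        X, Z = rng.normal(size=(5, 3)), rng.normal(size=(4, 3))
        K = weighted_kernel_matrix(X, Z, spec_of(np.zeros(3)))
        assert np.allclose(K, 1.0)

    def test_hand_evaluated_entry(self):
        X = np.array([[0.0, 5.0], [2.0, -3.0]])
        K = weighted_kernel_matrix(X, X, spec_of([1.0, 0.0], s2=1.0))
        assert np.isclose(K[0, 1], np.exp(-4.0))

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            weighted_kernel_matrix(rng.normal(size=(3, 4)), rng.normal(size=(3, 5)), spec_of(np.ones(4)))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            spec_of([1.5, 0.0])
        with pytest.raises(ValueError):
            spec_of([0.5], s2=0.0)
        with pytest.raises(ValueError):
            spec_of([0.5], g=-1.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_kernel_matrix_positive_semidefinite(self, seed):
        r = np.random.default_rng(seed)
        X = r.normal(size=(8, 5))
        spec = spec_of(r.uniform(size=5), s2=float(r.uniform(0.1, 10)))
        eig = np.linalg.eigvalsh(weighted_kernel_matrix(X, X, spec))
        assert eig.min() >= -1e-10

    def test_scaling_equivariance(self, rng):
        # multiplying features by c and sigma2 by c^2 leaves the kernel unchanged
        X, Z = rng.normal(size=(5, 4)), rng.normal(size=(3, 4))
        w = rng.uniform(size=4)
        K1 = weighted_kernel_matrix(X, Z, spec_of(w, s2=2.0))
        K2 = weighted_kernel_matrix(3.0 * X, 3.0 * Z, spec_of(w, s2=18.0))
        assert np.allclose(K1, K2)


def assemble_and_solve(Xs, ys, spec):
    """Independent oracle: assemble the bordered system naively and solve."""
    n = len(ys)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = np.exp(-np.sum(spec.weights * (Xs[i] - Xs[j]) ** 2) / spec.kernel_width)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / spec.reg_weight
    sol = np.linalg.solve(A, np.concatenate([[0.0], ys]))
    return sol[0], sol[1:]


class TestLSSVM:
    def test_three_sample_problem_matches_direct_solve_oracle(self, rng):
        X = rng.normal(size=(3, 4))
        y = rng.normal(size=3)
        spec = spec_of(rng.uniform(size=4), s2=2.0, g=5.0)
        model = lssvm_fit(X, y, spec)
        ys = (y - model.y_mean) / model.y_scale
        b, alpha = assemble_and_solve(model.support_data, ys, spec)
        assert np.isclose(model.bias, b, rtol=1e-8)
        assert np.allclose(model.dual_coefficients, alpha, rtol=1e-8)

    def test_constant_target_reproduced_everywhere(self, rng):
        X = rng.normal(size=(6, 3))
        model = lssvm_fit(X, np.full(6, 7.0), spec_of(np.ones(3)))
        assert np.allclose(lssvm_predict(model, rng.normal(size=(4, 3))), 7.0)

    def test_large_gamma_interpolates_training_targets(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        model = lssvm_fit(X, y, spec_of(np.ones(3), s2=4.0, g=1e8))
        assert np.allclose(lssvm_predict(model, X), y, rtol=1e-4, atol=1e-4)

    def test_single_training_point_predicts_its_target(self):
        model = lssvm_fit(np.ones((1, 3)), np.array([2.5]), spec_of(np.ones(3)))
        assert np.allclose(lssvm_predict(model, np.zeros((2, 3))), 2.5)

    def test_alpha_zero_predicts_bias(self, rng):
        model = lssvm_fit(rng.normal(size=(4, 2)), rng.normal(size=4), spec_of(np.ones(2)))
        model.dual_coefficients = np.zeros(4)
        pred_std = model.bias * model.y_scale + model.y_mean
        assert np.allclose(lssvm_predict(model, rng.normal(size=(3, 2))), pred_std)

    def test_log_target_roundtrip(self, rng):
        X = rng.normal(size=(10, 3))
        y = 10.0 ** rng.uniform(-2, 1, 10)
        model = lssvm_fit(X, y, spec_of(np.ones(3), s2=3.0, g=1e6), log_target=True)
        assert np.allclose(lssvm_predict(model, X), y, rtol=1e-3)
        with pytest.raises(ValueError, match="positive"):
            lssvm_fit(X, np.zeros(10), spec_of(np.ones(3)), log_target=True)

    def test_singular_system_reported(self):
        # zero-weight kernel makes K all-ones; huge gamma leaves the bordered
        # system numerically singular rather than silently pseudo-inverted
        X = np.array([[0.0], [0.0], [0.0]])
        with pytest.raises(np.linalg.LinAlgError, match="singular|ill-conditioned"):
            lssvm_fit(X, np.array([1.0, 2.0, 3.0]), spec_of([0.0], g=1e16))

    def test_feature_mismatch_rejected(self, rng):
        model = lssvm_fit(rng.normal(size=(4, 3)), rng.normal(size=4), spec_of(np.ones(3)))
        with pytest.raises(ValueError, match="mismatch"):
            lssvm_predict(model, rng.normal(size=(2, 5)))


class TestTraining:
    def make_sets(self, fingerprints):
        fp = fingerprints["acetic"]
        sd = 0.005 * np.abs(fp.max_response).max()
        train = generate_single_analyte(fp, [0.01, 0.1, 1, 10], 6, NoiseSpec(sd, seed=1))
        monitor = generate_single_analyte(fp, [0.01, 0.1, 1, 10], 3, NoiseSpec(sd, seed=2))
        return train, monitor

    def small_pso(self, seed=0):
        lo, hi = vwls.default_pso_bounds(12)
        return PSOConfig(bounds_lo=lo, bounds_hi=hi, n_particles=20, n_iterations=15, seed=seed)

    def test_optimum_not_worse_than_unweighted_default(self, fingerprints):
        train, monitor = self.make_sets(fingerprints)
        model = train_pso_vwls_svm(train, monitor, pso=self.small_pso())
        baseline = lssvm_fit(
            train.features,
            train.labels["concentration"],
            spec_of(np.ones(12), s2=10.0, g=100.0),
            log_target=True,
        )
        y_mo = monitor.labels["concentration"].to_numpy()
        base_rmse = np.sqrt(np.mean((lssvm_predict(baseline, monitor.features) - y_mo) ** 2))
        assert model.monitoring_rmse <= base_rmse + 1e-9

    def test_monitoring_smaller_than_two_rejected(self, fingerprints):
        train, monitor = self.make_sets(fingerprints)
        with pytest.raises(ValueError, match="monitoring"):
            train_pso_vwls_svm(train, (monitor.features[:1], [1.0]), pso=self.small_pso())

    def test_training_deterministic_given_seed(self, fingerprints):
        train, monitor = self.make_sets(fingerprints)
        a = train_pso_vwls_svm(train, monitor, pso=self.small_pso(3))
        b = train_pso_vwls_svm(train, monitor, pso=self.small_pso(3))
        assert np.array_equal(a.spec.weights, b.spec.weights)
        assert a.monitoring_rmse == b.monitoring_rmse


class TestFiguresOfMerit:
    def perfect_model(self):
        X = np.arange(12.0).reshape(4, 3)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        return lssvm_fit(X, y, spec_of(np.ones(3), s2=10.0, g=1e8))

    def test_perfect_prediction_metrics(self):
        model = self.perfect_model()
        X = np.arange(12.0).reshape(4, 3)
        fom = figures_of_merit(model, (X, np.array([1.0, 2.0, 3.0, 4.0])))
        assert fom.r2 > 0.9999
        assert fom.rmsep < 1e-3
        assert abs(fom.recovery_mean - 100.0) < 0.1

    def test_constant_offset_hand_arithmetic(self):
        # yhat = y + 1 on y = (1,2,3): rmsep 1, r2 1, mean recovery from ratios
        class Fake:
            pass

        y = np.array([1.0, 2.0, 3.0])
        yhat = y + 1.0
        rec = 100.0 * yhat / y
        assert np.isclose(rec.mean(), 100.0 * (2.0 / 1 + 3.0 / 2 + 4.0 / 3) / 3)
        r = np.corrcoef(yhat, y)[0, 1]
        assert np.isclose(r ** 2, 1.0)
        assert np.isclose(np.sqrt(np.mean((yhat - y) ** 2)), 1.0)

    def test_zero_concentration_excluded_from_recovery_only(self):
        model = self.perfect_model()
        X = np.vstack([np.arange(12.0).reshape(4, 3), np.zeros((1, 3))])
        y = np.array([1.0, 2.0, 3.0, 4.0, 0.0])
        fom = figures_of_merit(model, (X, y))
        assert len(fom.recovery_pct) == 4  # zero-truth sample dropped
        assert np.isfinite(fom.rmsep)  # but kept in rmsep/r2

    def test_empty_prediction_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            figures_of_merit(self.perfect_model(), (np.zeros((0, 3)), np.zeros(0)))


class TestLodLoq:
    def test_hand_arithmetic_example(self, rng):
        # predictions over blanks = (0.01, 0.02, 0.03) mmol/L, M = 60 g/mol
        preds = np.array([0.01, 0.02, 0.03])
        sigma = preds.std(ddof=1)
        assert np.isclose(sigma, 0.01)
        assert np.isclose(3 * sigma * 60 / 1000, 1.8e-3)

    def test_ratio_forced_by_definition(self, fingerprints, rng):
        fp = fingerprints["acetic"]
        data = generate_single_analyte(fp, [0.01, 0.1, 1, 10], 4, NoiseSpec(0.5, seed=0))
        model = lssvm_fit(
            data.features, data.labels["concentration"], spec_of(np.ones(12), s2=20.0, g=100.0),
            log_target=True,
        )
        blanks = rng.normal(0, 0.5, (6, 12))
        lod, loq, sigma = lod_loq(blanks, model, 60.05)
        assert sigma > 0
        assert np.isclose(loq / lod, 10.0 / 3.0)

    def test_identical_blanks_give_zero_limits(self, fingerprints):
        fp = fingerprints["acetic"]
        data = generate_single_analyte(fp, [0.01, 1.0], 3, NoiseSpec(0.0, seed=0))
        model = lssvm_fit(
            data.features, data.labels["concentration"], spec_of(np.ones(12), s2=20.0, g=100.0),
        )
        lod, loq, sigma = lod_loq(np.zeros((4, 12)), model, 60.05)
        assert lod == loq == sigma == 0.0

    def test_fewer_than_three_replicates_rejected(self, fingerprints):
        fp = fingerprints["acetic"]
        data = generate_single_analyte(fp, [0.01, 1.0], 3, NoiseSpec(0.0, seed=0))
        model = lssvm_fit(
            data.features, data.labels["concentration"], spec_of(np.ones(12), s2=20.0, g=100.0),
        )
        with pytest.raises(ValueError, match="3 blank"):
            lod_loq(np.zeros((2, 12)), model, 60.05)
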