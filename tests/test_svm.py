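"""Kernels, the SMO solver, dual feasibility, and the decision function."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.svm import SVC

from gaitsym import KernelSpec, SvmModel, kernel_eval, train_svm
from gaitsym.errors import DimensionError, DomainError, LabelError
from gaitsym.svm import kernel_matrix, kkt_violation


def random_problem(rng, n_max=15, d_max=3):
    n = int(rng.integers(4, n_max + 1))
    d = int(rng.integers(1, d_max + 1))
    X = rng.normal(size=(n, d))
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    if len(set(y)) < 2:
        y[0] = -y[1]
    C = float(rng.choice([0.1, 1.0, 10.0]))
    return X, y, C


def slsqp_dual_optimum(spec, X, y, C):
    """Independent dense QP solve of the SVM dual (maximization value)."""
    K = kernel_matrix(spec, X, X)
    Q = np.outer(y, y) * K
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.zeros(y.size),
        jac=lambda a: Q @ a - 1.0,
        bounds=[(0.0, C)] * y.size,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    return -res.fun


KERNELS = [KernelSpec("linear"), KernelSpec("poly", degree=2), KernelSpec("rbf", sigma=1.5)]


class TestKernels:
    def test_linear_dot_product(self):
        assert kernel_eval(KernelSpec("linear"), [1.0, 2.0], [1.0, 2.0]) == 5.0

    def test_poly_hand_arithmetic(self):
        assert kernel_eval(KernelSpec("poly", degree=2), [1.0, 0.0], [1.0, 1.0]) == 4.0

    def test_rbf_self_similarity_is_one(self, rng):
        x = rng.normal(size=7)
        assert kernel_eval(KernelSpec("rbf", sigma=2.0), x, x) == 1.0

    def test_rbf_negative_exponent(self):
        # distance 2, sigma 1: exp(-4/2)
        val = kernel_eval(KernelSpec("rbf", sigma=1.0), [0.0], [2.0])
        assert val == pytest.approx(np.exp(-2.0))
        assert val < 1.0  # a diverging positive exponent would exceed 1

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionError):
            kernel_eval(KernelSpec("linear"), [1.0, 2.0], [1.0])

    def test_parameter_validation(self):
        with pytest.raises(DomainError):
            KernelSpec("rbf", sigma=0.0)
        with pytest.raises(DomainError):
            KernelSpec("poly", degree=0)
        with pytest.raises(DomainError):
            KernelSpec("sigmoid")


class TestTwoPointClosedForm:
    def setup_method(self):
        self.model = train_svm(
            np.array([[1.0, 0.0], [-1.0, 0.0]]),
            np.array([1.0, -1.0]),
            KernelSpec("linear"),
            penalty_c=10.0,
            tolerance=1e-8,
            standardize=False,
        )

    def test_dual_solution(self):
        np.testing.assert_allclose(self.model.beta, [0.5, 0.5], atol=1e-6)
        assert self.model.bias == pytest.approx(0.0, abs=1e-6)

    def test_margin_values(self):
        assert self.model.decision_function(np.array([1.0, 0.0])) == pytest.approx(1.0, abs=1e-6)
        assert self.model.decision_function(np.array([-1.0, 0.0])) == pytest.approx(-1.0, abs=1e-6)

    def test_predictions(self):
        assert self.model.predict(np.array([5.0, 3.0])) == 1
        assert self.model.predict(np.array([-0.1, 7.0])) == -1


class TestSmoCorrectness:
    @pytest.mark.parametrize("spec", KERNELS, ids=lambda s: s.kind)
    def test_matches_qp_oracle(self, spec, rng):
        for _ in range(30):
            X, y, C = random_problem(rng)
            model = train_svm(X, y, spec, penalty_c=C, tolerance=1e-6, standardize=False)
            W_oracle = slsqp_dual_optimum(spec, X, y, C)
            W_smo = model.beta.sum() - 0.5 * model.beta @ (np.outer(y, y) * kernel_matrix(spec, X, X)) @ model.beta
            assert W_smo == pytest.approx(W_oracle, abs=1e-4)

    @pytest.mark.parametrize("spec", KERNELS, ids=lambda s: s.kind)
    def test_dual_feasibility_and_kkt(self, spec, rng):
        for _ in range(20):
            X, y, C = random_problem(rng)
            model = train_svm(X, y, spec, penalty_c=C, tolerance=1e-4, standardize=False)
            assert np.all(model.beta >= -1e-8)
            assert np.all(model.beta <= C + 1e-8)
            assert abs(model.beta @ y) <= 1e-6
            K = kernel_matrix(spec, X, X)
            assert kkt_violation(K, y, model.beta, model.bias, C) <= 1e-3

    def test_objective_monotone(self, rng):
        for _ in range(10):
            X, y, C = random_problem(rng)
            model = train_svm(X, y, KernelSpec("rbf", sigma=1.0), penalty_c=C, standardize=False)
            assert np.all(np.diff(model.objective_path) >= -1e-9)

    def test_separable_data_no_slack(self, rng):
        X = np.vstack([rng.normal(size=(8, 2)) + [4.0, 0.0], rng.normal(size=(8, 2)) - [4.0, 0.0]])
        y = np.array([1.0] * 8 + [-1.0] * 8)
        model = train_svm(X, y, KernelSpec("linear"), penalty_c=1e4, tolerance=1e-6, standardize=False)
        assert np.all(model.slack <= 1e-6)
        assert np.all(model.predict(X) == y)

    def test_free_support_vectors_sit_on_margin(self, rng):
        X, y, _ = random_problem(rng, n_max=12)
        model = train_svm(X, y, KernelSpec("rbf", sigma=1.5), penalty_c=1.0, tolerance=1e-6, standardize=False)
        free = (model.beta > 1e-6) & (model.beta < 1.0 - 1e-6)
        for i in np.flatnonzero(free):
            assert y[i] * model.decision_function(X[i]) == pytest.approx(1.0, abs=1e-3)

    def test_label_symmetry(self, rng):
        X, y, C = random_problem(rng)
        a = train_svm(X, y, KernelSpec("rbf", sigma=1.0), penalty_c=C, standardize=False)
        b = train_svm(X, -y, KernelSpec("rbf", sigma=1.0), penalty_c=C, standardize=False)
        grid = rng.normal(size=(20, X.shape[1]))
        np.testing.assert_allclose(a.decision_function(grid), -b.decision_function(grid), atol=1e-8)

    def test_duplicating_non_support_point_is_inert(self, rng):
        X = np.vstack([rng.normal(size=(6, 2)) + [3.0, 0.0], rng.normal(size=(6, 2)) - [3.0, 0.0]])
        y = np.array([1.0] * 6 + [-1.0] * 6)
        model = train_svm(X, y, KernelSpec("linear"), penalty_c=10.0, tolerance=1e-6, standardize=False)
        non_sv = np.flatnonzero(model.beta <= 1e-8)
        assert non_sv.size, "construction should leave interior points"
        i = int(non_sv[0])
        X2 = np.vstack([X, X[i]])
        y2 = np.append(y, y[i])
        model2 = train_svm(X2, y2, KernelSpec("linear"), penalty_c=10.0, tolerance=1e-6, standardize=False)
        grid = rng.normal(size=(30, 2)) * 3
        np.testing.assert_array_equal(model.predict(grid), model2.predict(grid))

    def test_agrees_with_reference_implementation(self, rng):
        # sklearn's SVC as an independent cross-check, never the implementation
        X, y, _ = random_problem(rng, n_max=14)
        spec = KernelSpec("rbf", sigma=1.2)
        mine = train_svm(X, y, spec, penalty_c=2.0, tolerance=1e-7, standardize=False)
        ref = SVC(C=2.0, kernel="rbf", gamma=1.0 / (2 * 1.2**2), tol=1e-7).fit(X, y)
        grid = rng.normal(size=(40, X.shape[1]))
        np.testing.assert_allclose(
            mine.decision_function(grid), ref.decision_function(grid), atol=1e-3
        )


class TestModelBehaviour:
    def test_standardization_constants_stored_and_applied(self, rng):
        X = rng.normal(size=(12, 3)) * [10.0, 0.1, 1.0] + [5.0, -2.0, 0.0]
        y = np.where(X[:, 0] > 5.0, 1.0, -1.0)
        if len(set(y)) < 2:
            y[0] = -y[0]
        model = train_svm(X, y, KernelSpec("linear"), penalty_c=1.0)
        assert model.scaler_mean is not None
        np.testing.assert_allclose(model.scaler_mean, X.mean(axis=0))

    def test_serialization_round_trip(self, tmp_path, rng):
        X, y, C = random_problem(rng)
        model = train_svm(X, y, KernelSpec("poly", degree=2), penalty_c=C)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SvmModel.from_json(path)
        grid = rng.normal(size=(10, X.shape[1]))
        np.testing.assert_allclose(model.decision_function(grid), back.decision_function(grid), atol=1e-12)

    def test_tie_predicts_positive(self, rng):
        X, y, C = random_problem(rng)
        model = train_svm(X, y, KernelSpec("linear"), penalty_c=C)
        model.bias -= model.decision_function(X[0])  # force f(X[0]) = 0
        assert model.predict(X[0]) == 1

    def test_single_class_rejected(self):
        with pytest.raises(LabelError):
            train_svm(np.ones((3, 2)), np.ones(3), KernelSpec("linear"))

    def test_non_finite_features_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(DomainError):
            train_svm(X, np.array([1.0, -1.0]), KernelSpec("linear"))

    def test_dimension_mismatch_at_predict(self, rng):
        X, y, C = random_problem(rng, d_max=2)
        model = train_svm(X, y, KernelSpec("linear"), penalty_c=C)
        with pytest.raises(DimensionError):
            model.predict(np.zeros(X.shape[1] + 1))
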