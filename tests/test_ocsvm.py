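import numpy as np
import pytest
from scipy.optimize import minimize

from wcos.ocsvm import (
    KernelSpec,
    OCSVMConfig,
    anomaly_score,
    decision_value,
    fit,
    gram,
    predict,
)


def qp_oracle(K, nu):
    """Brute-force solution of the one-class dual:

        min 1/2 a' K a   s.t.  0 <= a_i <= 1/(nu N),  sum a = 1

    solved with SLSQP from several starts; returns (alpha, rho, objective).
    """
    n = K.shape[0]
    ub = 1.0 / (nu * n)

    def obj(a):
        return 0.5 * a @ K @ a

    def jac(a):
        return K @ a

    best = None
    for start in range(3):
        rng = np.random.default_rng(start)
        a0 = rng.random(n)
        a0 = np.clip(a0 / a0.sum(), 0, ub)
        a0 += (1 - a0.sum()) / n
        a0 = np.clip(a0, 0, ub)
        res = minimize(
            obj,
            a0,
            jac=jac,
            bounds=[(0.0, ub)] * n,
            constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0}],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha = best.x
    margin = (alpha > 1e-7) & (alpha < ub - 1e-7)
    g = K @ alpha
    rho = float(np.mean(g[margin])) if margin.any() else float(np.max(g[alpha > 1e-7]))
    return alpha, rho, float(best.fun)


def model_dual(model, H):
    """Recover the full dual vector and objective from a fitted model."""
    alpha = np.zeros(H.shape[0])
    # map support vectors back to training rows
    for w, sv in zip(model.weights, model.support_vectors):
        idx = np.flatnonzero(np.all(np.isclose(H, sv), axis=1))[0]
        alpha[idx] += w
    K = gram(H, H, model.kernel)
    return alpha, 0.5 * alpha @ K @ alpha


KERNELS = [
    KernelSpec(kind="linear"),
    KernelSpec(kind="poly", a1=1.0, b1=1.0, d=2),
    KernelSpec(kind="rbf", sigma=1.5),
    KernelSpec(kind="sigmoid", a2=0.2, b2=0.1),
]


class TestGram:
    def test_linear_on_orthonormal_basis_is_identity(self):
        H = np.eye(4)
        np.testing.assert_allclose(gram(H, H, KernelSpec(kind="linear")), np.eye(4))

    def test_rbf_unit_diagonal_and_psd(self, rng):
        H = rng.standard_normal((20, 3))
        K = gram(H, H, KernelSpec(kind="rbf", sigma=1.0))
        np.testing.assert_allclose(np.diag(K), 1.0)
        np.testing.assert_allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            gram(np.zeros((2, 3)), np.zeros((2, 4)), KernelSpec(kind="linear"))


class TestFitAgainstQPOracle:
    def test_three_point_linear_example(self):
        """1-D points {0, 1, 2}, linear kernel, C=0.5: dual weights and offset
        match the brute-force QP."""
        H = np.array([[0.0], [1.0], [2.0]])
        nu = 0.5
        model = fit(H, OCSVMConfig(C=nu, kernel=KernelSpec(kind="linear")))
        K = gram(H, H, model.kernel)
        alpha, rho, _ = qp_oracle(K, nu)
        got_alpha, _ = model_dual(model, H)
        np.testing.assert_allclose(got_alpha, alpha, atol=1e-4)
        assert model.offset == pytest.approx(rho, abs=1e-4)

    @pytest.mark.parametrize("kernel", KERNELS, ids=[k.kind for k in KERNELS])
    @pytest.mark.parametrize("n,nu", [(8, 0.3), (20, 0.15)])
    def test_dual_objective_and_predictions_match(self, rng, kernel, n, nu):
        H = rng.standard_normal((n, 2))
        model = fit(H, OCSVMConfig(C=nu, kernel=kernel))
        K = gram(H, H, model.kernel)
        alpha, rho, obj = qp_oracle(K, nu)
        _, got_obj = model_dual(model, H)
        assert got_obj == pytest.approx(obj, abs=1e-6)
        test = rng.standard_normal((30, 2))
        g_oracle = gram(test, H, model.kernel) @ alpha - rho
        pred_oracle = np.where(g_oracle >= 0, 1, -1)
        # only compare away from the boundary where solver tolerance can flip
        clear = np.abs(g_oracle) > 1e-5
        np.testing.assert_array_equal(predict(model, test)[clear], pred_oracle[clear])


class TestNuProperty:
    @pytest.mark.parametrize("nu", [0.01, 0.05, 0.1])
    def test_training_outlier_fraction_bounded(self, rng, nu):
        H = rng.standard_normal((200, 2))
        model = fit(H, OCSVMConfig(C=nu, kernel=KernelSpec(kind="rbf")))
        frac = np.mean(decision_value(model, H) < 0)
        assert frac <= nu + 2 / 200


@pytest.fixture(scope="module")
def gauss_model():
    rng = np.random.default_rng(3)
    H = rng.standard_normal((200, 2))
    return fit(H, OCSVMConfig(C=0.05, kernel=KernelSpec(kind="rbf"))), H


class TestDecision:

    def test_centroid_is_normal(self, gauss_model):
        model, H = gauss_model
        assert predict(model, H.mean(axis=0)) == 1

    def test_far_point_is_abnormal_with_positive_score(self, gauss_model):
        model, _ = gauss_model
        far = np.array([10.0, 10.0])
        assert predict(model, far) == -1
        assert anomaly_score(model, far) > 0

    def test_anomaly_score_is_negated_decision(self, gauss_model, rng):
        model, _ = gauss_model
        pts = rng.standard_normal((10, 2))
        np.testing.assert_allclose(
            anomaly_score(model, pts), -decision_value(model, pts)
        )

    def test_single_training_point_predicts_itself_normal(self):
        h = np.array([[0.5, -0.2]])
        model = fit(h, OCSVMConfig(C=0.5, kernel=KernelSpec(kind="rbf", sigma=1.0)))
        assert predict(model, h[0]) == 1  # g = 0 ties break to normal

    def test_rbf_scale_invariance(self, rng):
        """Rescaling data and sigma together leaves rbf predictions unchanged."""
        H = rng.standard_normal((100, 2))
        test = rng.standard_normal((50, 2))
        a = 7.0
        m1 = fit(H, OCSVMConfig(C=0.1, kernel=KernelSpec(kind="rbf", sigma=1.0)))
        m2 = fit(a * H, OCSVMConfig(C=0.1, kernel=KernelSpec(kind="rbf", sigma=a)))
        np.testing.assert_array_equal(predict(m1, test), predict(m2, a * test))


class TestValidation:
    def test_invalid_C_rejected(self):
        with pytest.raises(ValueError):
            OCSVMConfig(C=0.0)
        with pytest.raises(ValueError):
            OCSVMConfig(C=1.5)

    def test_abnormal_labeled_input_rejected(self):
        data = [(np.zeros(2), "normal"), (np.ones(2), "abnormal")]
        with pytest.raises(ValueError, match="abnormal"):
            fit(data, OCSVMConfig(C=0.5))

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec(kind="laplacian")
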