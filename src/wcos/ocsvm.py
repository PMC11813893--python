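"""One-class SVM scoring of latent representations.

The model is the nu-style one-class formulation: given normal training
vectors h_1..h_N mapped through a kernel, it solves

    min_{w, xi, v}  1/2 ||w||^2 + 1/(C N) sum_i xi_i - v
    s.t.            w . phi(h_i) >= v - xi_i,   xi_i >= 0

whose dual yields nonnegative weights w_i on (support) training points and an
offset v; the decision value of a test point h is g = sum_i w_i k(h, h_i) - v,
the prediction is +1 (normal) iff g >= 0, and the anomaly score is -g. The
control factor C in (0, 1] plays the role of nu: it upper-bounds the fraction
of training points treated as outliers and lower-bounds the support-vector
fraction.

Fitting delegates to libsvm (scikit-learn's ``OneClassSVM``) on a precomputed
Gram matrix so that the four kernel parameterizations below are honored
exactly; dual weights are rescaled to the convention above (sum w_i = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.svm import OneClassSVM

KERNEL_KINDS = ("linear", "poly", "rbf", "sigmoid")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and its parameters.

    linear:  k(h, h') = h . h'
    poly:    k(h, h') = (a1 h . h' + b1)^d
    rbf:     k(h, h') = exp(-||h - h'||^2 / (2 sigma^2))
    sigmoid: k(h, h') = tanh(a2 h . h' + b2)

    ``sigma=None`` requests the median pairwise-distance heuristic at fit time;
    ``a2=None`` requests 1/feature_dim.
    """

    kind: str = "rbf"
    a1: float = 1.0
    b1: float = 1.0
    d: int = 3
    sigma: float | None = None
    a2: float | None = None
    b2: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"kernel kind must be one of {KERNEL_KINDS}, got {self.kind!r}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("rbf sigma must be positive")
        if self.kind == "poly" and (self.d < 1 or int(self.d) != self.d):
            raise ValueError("poly degree d must be a positive integer")


@dataclass(frozen=True)
class OCSVMConfig:
    """Control factor C in (0, 1] (the nu role) and kernel."""

    C: float = 1e-3
    kernel: KernelSpec = field(default_factory=KernelSpec)
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 < self.C <= 1):
            raise ValueError("C must lie in (0, 1]")


def median_pairwise_sigma(H: np.ndarray) -> float:
    """Median of the nonzero pairwise Euclidean distances (rbf width heuristic)."""
    H = np.atleast_2d(H)
    if H.shape[0] < 2:
        return 1.0
    sq = np.sum(H**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * H @ H.T, 0.0)
    iu = np.triu_indices(H.shape[0], k=1)
    d = np.sqrt(d2[iu])
    d = d[d > 0]
    return float(np.median(d)) if d.size else 1.0


def gram(H: np.ndarray, Hp: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix ``K[i, j] = k(H[i], Hp[j])`` for the requested kernel.

    Parameter defaults that depend on the data (rbf sigma, sigmoid a2) must
    already be resolved; :func:`fit` does this automatically.
    """
    H, Hp = np.atleast_2d(H), np.atleast_2d(Hp)
    if H.shape[1] != Hp.shape[1]:
        raise ValueError(f"feature dimensions differ: {H.shape[1]} vs {Hp.shape[1]}")
    inner = H @ Hp.T
    if spec.kind == "linear":
        return inner
    if spec.kind == "poly":
        return (spec.a1 * inner + spec.b1) ** spec.d
    if spec.kind == "rbf":
        if spec.sigma is None:
            raise ValueError("rbf sigma unresolved; pass a value or fit first")
        sq1 = np.sum(H**2, axis=1)[:, None]
        sq2 = np.sum(Hp**2, axis=1)[None, :]
        d2 = np.maximum(sq1 + sq2 - 2 * inner, 0.0)
        return np.exp(-d2 / (2.0 * spec.sigma**2))
    a2 = spec.a2 if spec.a2 is not None else 1.0 / H.shape[1]
    return np.tanh(a2 * inner + spec.b2)


@dataclass
class OCSVMModel:
    """Fitted model: support vectors, weights, offset and the resolved kernel."""

    support_vectors: np.ndarray
    weights: np.ndarray
    offset: float
    kernel: KernelSpec
    config: OCSVMConfig

    def __post_init__(self) -> None:
        if np.any(self.weights < -1e-12) or self.weights.sum() <= 0:
            raise ValueError("dual weights must be nonnegative with positive sum")


def fit(H_normal, config: OCSVMConfig = OCSVMConfig()) -> OCSVMModel:
    """Fit the one-class SVM on normal latent vectors.

    Accepts a 2-D array or a list of (vector, label) — any abnormal label
    raises. Data-dependent kernel defaults (rbf sigma via the median pairwise
    distance, sigmoid a2 = 1/dim) are resolved here and frozen into the model.
    """
    if not isinstance(H_normal, np.ndarray):
        vals = []
        for item in H_normal:
            if isinstance(item, tuple):
                vec, label = item
                if label == "abnormal":
                    raise ValueError("abnormal sample passed to ocsvm.fit")
                vals.append(vec)
            else:
                vals.append(item)
        H_normal = np.stack([np.asarray(v, float) for v in vals])
    H = np.atleast_2d(np.asarray(H_normal, dtype=np.float64))
    if H.shape[0] < 1:
        raise ValueError("empty training set")

    kernel = config.kernel
    if kernel.kind == "rbf" and kernel.sigma is None:
        kernel = replace(kernel, sigma=median_pairwise_sigma(H))
    if kernel.kind == "sigmoid" and kernel.a2 is None:
        kernel = replace(kernel, a2=1.0 / H.shape[1])

    if H.shape[0] == 1:
        # exact dual solution for a single point: alpha = 1, rho = k(h, h),
        # so the training point itself sits on the boundary (g = 0, normal)
        K11 = float(gram(H, H, kernel)[0, 0])
        return OCSVMModel(
            support_vectors=H,
            weights=np.array([1.0]),
            offset=K11,
            kernel=kernel,
            config=config,
        )

    K = gram(H, H, kernel)
    svm = OneClassSVM(kernel="precomputed", nu=config.C, tol=config.tol, max_iter=-1)
    svm.fit(K)
    # libsvm scales dual coefficients to sum to nu*N; renormalize to sum 1 so
    # the decision function matches the 1/(CN) objective convention exactly.
    scale = config.C * H.shape[0]
    weights = svm.dual_coef_.ravel() / scale
    offset = float(-svm.intercept_[0]) / scale
    return OCSVMModel(
        support_vectors=H[svm.support_],
        weights=weights,
        offset=offset,
        kernel=kernel,
        config=config,
    )


def decision_value(model: OCSVMModel, h: np.ndarray) -> np.ndarray | float:
    """``g(h) = sum_i w_i k(h, h_i) - v``; scalar for a single vector."""
    h = np.asarray(h, dtype=np.float64)
    single = h.ndim == 1
    K = gram(np.atleast_2d(h), model.support_vectors, model.kernel)
    g = K @ model.weights - model.offset
    return float(g[0]) if single else g


def predict(model: OCSVMModel, h: np.ndarray) -> np.ndarray | int:
    """+1 (normal) iff g >= 0, else -1 (abnormal); g == 0 counts as normal."""
    g = decision_value(model, h)
    if np.isscalar(g):
        return 1 if g >= 0 else -1
    return np.where(g >= 0, 1, -1)


def anomaly_score(model: OCSVMModel, h: np.ndarray) -> np.ndarray | float:
    """Negated decision value: larger means more abnormal."""
    g = decision_value(model, h)
    return -g
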