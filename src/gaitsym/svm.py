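"""Soft-margin kernel SVM trained by sequential minimal optimization (SMO).

The binary classifier at the heart of the package.  Training solves the
standard box-constrained dual

    maximize  W(beta) = sum_i beta_i - 1/2 sum_ij beta_i beta_j y_i y_j K(x_i, x_j)
    subject to  sum_i beta_i y_i = 0,   0 <= beta_i <= C,

by pairwise analytic coordinate steps (SMO): each iteration picks the
most-violating pair of dual variables (second-order choice of the second
index), optimizes the two jointly under the equality constraint, and clips
to the box; the bias is recovered from the KKT conditions of the free
support vectors.  The decision function is
f(x) = sign( sum_{i in SV} beta_i y_i K(x_i, x) + b ), with labels
+1 (right side) and -1 (left side).

Kernels: linear x.z, polynomial ((x.z) + 1)^d, and Gaussian RBF
exp(-||x - z||^2 / (2 sigma^2)).  Because the polynomial and RBF kernels are
scale sensitive, features are standardized (zero mean, unit variance,
constants fitted on the training set) by default; pass ``standardize=False``
for raw geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# randomness: the solver is deterministic; sub-streams are used elsewhere in the package
from .errors import DimensionError, DomainError, LabelError

SUPPORT_EPS = 1e-8  # beta above this counts as a support vector


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice: ``linear``, ``poly`` (degree d) or ``rbf`` (width sigma)."""

    kind: str
    degree: int = 3
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "poly", "rbf"):
            raise DomainError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "poly" and (int(self.degree) != self.degree or self.degree < 1):
            raise DomainError(f"polynomial degree must be a positive integer, got {self.degree}")
        if self.kind == "rbf" and not self.sigma > 0:
            raise DomainError(f"RBF width sigma must be positive, got {self.sigma}")

    def label(self) -> str:
        if self.kind == "poly":
            return f"poly(d={self.degree})"
        if self.kind == "rbf":
            return f"rbf(sigma={self.sigma:g})"
        return "linear"


def kernel_matrix(spec: KernelSpec, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Gram matrix K[i, j] = K(X[i], Z[j])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise DimensionError(f"feature dimensions differ: {X.shape[1]} vs {Z.shape[1]}")
    G = X @ Z.T
    if spec.kind == "linear":
        return G
    if spec.kind == "poly":
        return (G + 1.0) ** spec.degree
    sq = (X * X).sum(axis=1)[:, None] + (Z * Z).sum(axis=1)[None, :] - 2.0 * G
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / (2.0 * spec.sigma**2))


def kernel_eval(spec: KernelSpec, x, z) -> float:
    """Evaluate K(x, z) for two feature vectors."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape or x.ndim != 1:
        raise DimensionError(f"kernel arguments must be equal-length vectors, got {x.shape} vs {z.shape}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(z))):
        raise DomainError("kernel arguments must be finite")
    return float(kernel_matrix(spec, x[None, :], z[None, :])[0, 0])


@dataclass
class SvmModel:
    """A trained soft-margin kernel SVM.

    ``dual_coef`` holds beta_i * y_i for the support vectors (in the
    standardized feature space when ``scaler_mean`` is set).  ``beta`` and
    ``labels`` keep the full training-time dual solution so the constraints
    0 <= beta_i <= C and sum beta_i y_i = 0 remain checkable.
    """

    kernel: KernelSpec
    penalty_c: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    bias: float
    beta: np.ndarray
    labels: np.ndarray
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    n_iter: int = 0
    kkt_violation: float = np.nan
    objective_path: np.ndarray = field(default_factory=lambda: np.zeros(0))
    slack: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]

    def dual_objective(self) -> float:
        """W(beta) at the returned solution (computed from the support set)."""
        coef = self.dual_coef
        K = kernel_matrix(self.kernel, self.support_vectors, self.support_vectors)
        return float(self.beta.sum() - 0.5 * coef @ K @ coef)

    def _standardized(self, X: np.ndarray) -> np.ndarray:
        if self.scaler_mean is None:
            return X
        return (X - self.scaler_mean) / self.scaler_scale

    def decision_function(self, X) -> np.ndarray | float:
        """Raw decision values f(x) = sum beta_i y_i K(x_i, x) + b."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X2 = np.atleast_2d(X)
        if X2.shape[1] != self.support_vectors.shape[1]:
            raise DimensionError(
                f"feature dimension {X2.shape[1]} does not match model dimension "
                f"{self.support_vectors.shape[1]}"
            )
        K = kernel_matrix(self.kernel, self._standardized(X2), self.support_vectors)
        f = K @ self.dual_coef + self.bias
        return float(f[0]) if single else f

    def predict(self, X) -> np.ndarray | int:
        """Predicted labels ±1; the tie f(x) = 0 maps to +1."""
        f = self.decision_function(X)
        if np.isscalar(f):
            return 1 if f >= 0 else -1
        return np.where(np.asarray(f) >= 0, 1, -1)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format": "gaitsym-svm",
            "version": 1,
            "kernel": {"kind": self.kernel.kind, "degree": self.kernel.degree, "sigma": self.kernel.sigma},
            "penalty_c": self.penalty_c,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "beta": self.beta.tolist(),
            "labels": self.labels.tolist(),
            "scaler_mean": None if self.scaler_mean is None else self.scaler_mean.tolist(),
            "scaler_scale": None if self.scaler_scale is None else self.scaler_scale.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SvmModel":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = str(source)
            if not text.lstrip().startswith("{"):
                text = Path(text).read_text()
        payload = json.loads(text)
        if payload.get("format") != "gaitsym-svm":
            raise DomainError("not a gaitsym SVM model file")
        k = payload["kernel"]
        return cls(
            kernel=KernelSpec(k["kind"], degree=k["degree"], sigma=k["sigma"]),
            penalty_c=payload["penalty_c"],
            support_vectors=np.asarray(payload["support_vectors"], dtype=float),
            dual_coef=np.asarray(payload["dual_coef"], dtype=float),
            bias=float(payload["bias"]),
            beta=np.asarray(payload["beta"], dtype=float),
            labels=np.asarray(payload["labels"], dtype=float),
            scaler_mean=None if payload["scaler_mean"] is None else np.asarray(payload["scaler_mean"]),
            scaler_scale=None if payload["scaler_scale"] is None else np.asarray(payload["scaler_scale"]),
        )


def kkt_violation(K: np.ndarray, y: np.ndarray, beta: np.ndarray, b: float, C: float) -> float:
    """Largest KKT violation of the dual solution (0 at exact optimality).

    With r_i = y_i f(x_i) - 1: beta_i = 0 requires r_i >= 0, beta_i = C
    requires r_i <= 0, and interior beta_i require r_i = 0.
    """
    f = K @ (beta * y) + b
    r = y * f - 1.0
    viol = np.abs(r).copy()
    at_zero = beta <= SUPPORT_EPS
    at_c = beta >= C - SUPPORT_EPS
    viol[at_zero] = np.maximum(0.0, -r[at_zero])
    viol[at_c] = np.maximum(0.0, r[at_c])
    # points at both bounds (C ~ 0) keep the loosest requirement
    both = at_zero & at_c
    viol[both] = 0.0
    return float(viol.max()) if viol.size else 0.0


def train_svm(
    X,
    y,
    kernel: KernelSpec,
    penalty_c: float = 1.0,
    tolerance: float = 1e-3,
    max_passes: int = 5000,
    seed: int = 0,
    standardize: bool = True,
) -> SvmModel:
    """Train a soft-margin SVM with SMO.

    Parameters
    ----------
    X, y
        Training features (n, d) and labels ±1; both classes must be present.
    kernel, penalty_c
        Kernel specification and box constraint C > 0.
    tolerance
        KKT tolerance driving both pair selection and termination.
    max_passes
        Cap on pair updates, in units of training-set sweeps
        (``max_passes * n`` updates).
    seed
        Accepted for interface stability; the working-set selection is
        deterministic (most-violating pair with second-order second index),
        so identical inputs always give identical models.
    standardize
        Fit per-feature zero-mean/unit-variance scaling on the training set
        and apply it before the kernel (recommended for poly/RBF).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DimensionError(f"X shape {X.shape} inconsistent with {y.size} labels")
    if not np.all(np.isfinite(X)):
        raise DomainError("training features must be finite")
    if not set(np.unique(y)) == {-1.0, 1.0}:
        if not set(np.unique(y)) <= {-1.0, 1.0}:
            raise LabelError(f"labels must be ±1, got {sorted(set(y))}")
        raise LabelError("training data must contain both classes")
    if not penalty_c > 0:
        raise DomainError(f"penalty C must be positive, got {penalty_c}")

    scaler_mean = scaler_scale = None
    Xs = X
    if standardize:
        scaler_mean = X.mean(axis=0)
        scaler_scale = X.std(axis=0)
        scaler_scale = np.where(scaler_scale > 0, scaler_scale, 1.0)
        Xs = (X - scaler_mean) / scaler_scale

    n = Xs.shape[0]
    C = float(penalty_c)
    K = kernel_matrix(kernel, Xs, Xs)
    Q = (y[:, None] * y[None, :]) * K
    tau = 1e-12  # floor for the pair curvature

    # Most-violating-pair SMO on the dual.  In minimization form the dual is
    #   min 1/2 beta' Q beta - 1' beta,  grad G = Q beta - 1,
    # and a pair (i, j) with i in I_up, j in I_low maximally violating
    #   max_{I_up} (-y G)  <=  min_{I_low} (-y G)
    # is optimized analytically under the equality constraint and the box.
    beta = np.zeros(n)
    G = -np.ones(n)
    objective = [0.0]
    max_iter = max_passes * max(n, 10)
    n_iter = 0
    gap = np.inf
    diagK = np.diag(K).copy()
    while n_iter < max_iter:
        minus_yG = -y * G
        up = np.where(y > 0, beta < C - SUPPORT_EPS, beta > SUPPORT_EPS)
        low = np.where(y > 0, beta > SUPPORT_EPS, beta < C - SUPPORT_EPS)
        if not up.any() or not low.any():
            gap = 0.0
            break
        up_scores = np.where(up, minus_yG, -np.inf)
        low_scores = np.where(low, minus_yG, np.inf)
        i = int(np.argmax(up_scores))
        gap = float(up_scores[i] - low_scores.min())
        if gap <= tolerance:
            break
        # second-order choice of j: maximal decrease of the dual along (i, t)
        bvals = up_scores[i] - minus_yG
        curv = np.maximum(diagK[i] + diagK - 2.0 * K[i, :], tau)
        cand = low & (bvals > tau)
        if cand.any():
            decrease = np.where(cand, -(bvals**2) / curv, np.inf)
            j = int(np.argmin(decrease))
        else:
            j = int(np.argmin(low_scores))
        n_iter += 1
        bi, bj = beta[i], beta[j]
        quad = max(K[i, i] + K[j, j] - 2.0 * K[i, j], tau)
        if y[i] != y[j]:
            delta = (-G[i] - G[j]) / quad
            diff = bi - bj
            bi_new, bj_new = bi + delta, bj + delta
            if diff > 0:
                if bj_new < 0:
                    bi_new, bj_new = diff, 0.0
                if bi_new > C:
                    bi_new, bj_new = C, C - diff
            else:
                if bi_new < 0:
                    bi_new, bj_new = 0.0, -diff
                if bj_new > C:
                    bi_new, bj_new = C + diff, C
        else:
            delta = (G[i] - G[j]) / quad
            total = bi + bj
            bi_new, bj_new = bi - delta, bj + delta
            if bi_new < 0:
                bi_new, bj_new = 0.0, total
            elif bj_new < 0:
                bi_new, bj_new = total, 0.0
            if bi_new > C:
                bi_new, bj_new = C, total - C
            elif bj_new > C:
                bi_new, bj_new = total - C, C
        G += Q[:, i] * (bi_new - bi) + Q[:, j] * (bj_new - bj)
        beta[i], beta[j] = bi_new, bj_new
        objective.append(float(beta.sum() - 0.5 * beta @ Q @ beta))

    # bias from the KKT conditions: free support vectors satisfy y_i f_i = 1
    minus_yG = -y * G
    free = (beta > SUPPORT_EPS) & (beta < C - SUPPORT_EPS)
    if free.any():
        b = float(minus_yG[free].mean())
    else:
        up = np.where(y > 0, beta < C - SUPPORT_EPS, beta > SUPPORT_EPS)
        low = np.where(y > 0, beta > SUPPORT_EPS, beta < C - SUPPORT_EPS)
        hi = minus_yG[up].max() if up.any() else minus_yG.min()
        lo = minus_yG[low].min() if low.any() else minus_yG.max()
        b = float(0.5 * (hi + lo))

    final_violation = kkt_violation(K, y, beta, b, C)
    sv = beta > SUPPORT_EPS
    f = K @ (beta * y) + b
    slack = np.maximum(0.0, 1.0 - y * f)
    return SvmModel(
        kernel=kernel,
        penalty_c=C,
        support_vectors=Xs[sv],
        dual_coef=(beta * y)[sv],
        bias=float(b),
        beta=beta,
        labels=y,
        scaler_mean=scaler_mean,
        scaler_scale=scaler_scale,
        n_iter=n_iter,
        kkt_violation=final_violation,
        objective_path=np.asarray(objective),
        slack=slack,
    )


def predict(model: SvmModel, x) -> np.ndarray | int:
    """Functional alias for :meth:`SvmModel.predict`."""
    return model.predict(x)


def decision_value(model: SvmModel, x) -> np.ndarray | float:
    """Functional alias for :meth:`SvmModel.decision_function`."""
    return model.decision_function(x)
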