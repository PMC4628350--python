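"""Covariate-adjusted combination with a personalized cut-point.

Instead of one population-wide threshold, the cut-point becomes a function
c(z) of subject covariates, living in its own RKHS (kernel K2 over Z),
while the combination g(x) lives in the RKHS of K1 over the markers.  The
class weights become covariate-dependent, w(1, z) = 1/pi_z and
w(-1, z) = 1/(1 - pi_z) with pi_z = Pr(Y=1 | Z=z), and the fit minimizes

    (1/n) sum_i w(y_i, z_i) L_delta(y_i (g(x_i) - c(z_i)))
    + (lam/2) (||g||_K1^2 + ||c||_K2^2)

by the same DCA as the unadjusted estimator.  Because the decision
function g(x) - c(z) lives in the direct-sum RKHS with kernel K1 + K2, at
every subproblem optimum the two representer coefficient vectors are
opposite (b = -a), so the convex subproblem is a pure box QP over the
summed kernel.  K2 is augmented with a +1 constant so that c(z) carries an
intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from ._qp import box_qp_solve
from .data import BiomarkerSample
from .kernels import KernelSpec, kernel_matrix
from .losses import LossSpec, loss_value


def covariate_weights(y, Z, estimator: str = "logistic",
                      clip: tuple[float, float] = (0.01, 0.99)) -> np.ndarray:
    """Per-subject weights 1/pi_z (positives) and 1/(1-pi_z) (negatives).

    pi_z comes from a main-effects logistic fit of y on Z by default;
    ``estimator="constant"`` uses the overall prevalence (reducing to the
    unadjusted class weights up to normalization).
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if not (np.any(y > 0) and np.any(y < 0)):
        raise ValueError("both classes must be present")
    if estimator == "constant" or np.allclose(Z.std(axis=0), 0):
        pi = np.full(len(y), np.mean(y > 0))
    elif estimator == "logistic":
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                clf = LogisticRegression(C=np.inf, solver="lbfgs",
                                         max_iter=1000).fit(Z, y)
            except ConvergenceWarning:
                clf = LogisticRegression(C=1000.0, solver="lbfgs",
                                         max_iter=1000).fit(Z, y)
        pi = clf.predict_proba(Z)[:, list(clf.classes_).index(1.0)]
    else:
        raise ValueError(f"unknown pi_z estimator {estimator!r}")
    pi = np.clip(pi, clip[0], clip[1])
    return np.where(y > 0, 1.0 / pi, 1.0 / (1.0 - pi))


@dataclass
class CovariateKMEModel:
    """Fitted covariate-adjusted combination: rule sign(g(x) - c(z))."""

    a: np.ndarray
    b: np.ndarray
    X_train: np.ndarray
    Z_train: np.ndarray
    kernel_g: KernelSpec
    kernel_c: KernelSpec
    lam: float
    delta: float
    pi_model: str = "logistic"
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def scores(self, X_new: np.ndarray, Z_new: np.ndarray) -> np.ndarray:
        """g(x) - c(z) for each row; positives are scores >= 0."""
        Kx = kernel_matrix(X_new, self.X_train, self.kernel_g)
        Kz = kernel_matrix(Z_new, self.Z_train, self.kernel_c) + 1.0
        return Kx @ self.a - Kz @ self.b

    @property
    def cutoff(self) -> float:
        return 0.0


def fit_covariate_kme(data: BiomarkerSample, kernel_g: KernelSpec,
                      kernel_c: KernelSpec, lam: float, delta: float = 0.1,
                      pi_estimator: str = "logistic", max_iter: int = 20,
                      rel_tol: float = 1e-5) -> CovariateKMEModel:
    """Fit the covariate-adjusted estimator by DCA over the summed kernel.

    The target ramp sharpness is reached by continuation: the fit starts at
    delta = 0.5 and halves delta down to the requested value, warm-starting
    each stage at the previous solution.  This guards the non-convex DCA
    against the poor local minima a cold start finds at small delta; the
    reported objective trace covers the final (target-delta) stage only.
    """
    data.require_both_classes()
    if data.Z is None:
        raise ValueError("sample has no covariates Z")
    if not lam > 0:
        raise ValueError("lam must be positive")
    X, y, Z = data.X, data.y, data.Z
    n = data.n
    w = covariate_weights(y, Z, estimator=pi_estimator)
    K1 = kernel_matrix(X, X, kernel_g)
    K2 = kernel_matrix(Z, Z, kernel_c) + 1.0  # +1 absorbs the intercept of c(z)
    Keff = K1 + K2
    Q = (y[:, None] * y[None, :]) * Keff

    def objective_at(gamma: np.ndarray, d: float) -> float:
        u = y * (Keff @ gamma)
        losses = loss_value(u, LossSpec("psi_delta", d))
        return float(np.mean(w * losses) + 0.5 * lam * gamma @ Keff @ gamma)

    delta_path = [0.5]
    while delta_path[-1] > delta * 1.0001:
        delta_path.append(max(delta_path[-1] / 2.0, delta))
    if delta >= 0.5:
        delta_path = [delta]

    gamma = np.zeros(n)
    alpha_prev = None
    trace: list[float] = []
    for d in delta_path:
        C = w / (n * d)
        u = y * (Keff @ gamma)
        obj = objective_at(gamma, d)
        trace = [obj]  # keep the final stage's trace only
        for _ in range(max_iter):
            q = np.where(u < 0, C, 0.0)
            alpha = box_qp_solve(Q, C, q, d, lam, x0=alpha_prev)
            gamma_new = y * (alpha - q) / lam
            obj_new = objective_at(gamma_new, d)
            if obj_new > obj + 1e-10:
                break
            gamma = gamma_new
            alpha_prev = alpha
            u = y * (Keff @ gamma)
            trace.append(obj_new)
            if obj - obj_new < rel_tol * max(abs(obj), 1e-12):
                obj = obj_new
                break
            obj = obj_new
    return CovariateKMEModel(a=gamma, b=-gamma, X_train=X.copy(), Z_train=Z.copy(),
                             kernel_g=kernel_g, kernel_c=kernel_c, lam=float(lam),
                             delta=float(delta), pi_model=pi_estimator,
                             objective_trace=np.asarray(trace))
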