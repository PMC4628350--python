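"""Kernel-machine estimation of a biomarker combination maximizing the
Youden index.

The combination score g lives in the RKHS of a chosen kernel and, with the
inverse-prevalence class weights w(1) = n/|S1|, w(-1) = n/|S-1|, the fitted
(g, c) minimizes the weighted truncated-ramp surrogate objective

    s(a, c) = (1/n) sum_i w(y_i) L_delta(y_i (sum_j a_j K(x_i, x_j) - c))
              + (lam/2) a'Ka,

a finite-dimensional problem by the representer theorem.  The non-convex
ramp loss is handled by the difference-of-convex algorithm (DCA): the
concave part of the loss is linearized at the current iterate and the
resulting convex subproblem is solved exactly (see ``_qp``), which yields a
monotonically non-increasing objective trace.

Numerical choices: the iterate starts at a = 0, c = 0 (so the first DCA
step is a weighted hinge-type fit at margin delta); the concave-part
subgradient at a zero margin is taken on the inactive side (0); iteration
stops when the relative objective decrease falls below 1e-5 or after 20
iterations; a new iterate is accepted only if the exactly evaluated
objective does not increase.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from ._qp import best_offset, smo_solve
from .data import BiomarkerSample
from .kernels import KernelSpec, kernel_matrix
from .losses import LossSpec, loss_value


def class_weights(y: np.ndarray) -> tuple[float, float]:
    """Inverse-prevalence weights (n/|S1|, n/|S-1|).

    They normalize each class's total weight to n, so the weighted sample
    size is 2n.
    """
    y = np.asarray(y, dtype=float).ravel()
    n_pos = int(np.sum(y > 0))
    n_neg = int(np.sum(y < 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    n = len(y)
    return n / n_pos, n / n_neg


def _weight_vector(y: np.ndarray) -> np.ndarray:
    w_pos, w_neg = class_weights(y)
    return np.where(y > 0, w_pos, w_neg)


def objective_value(a, c, Gram, y, delta, lam, weights=None) -> float:
    """The surrogate objective at (a, c): weighted ramp losses plus penalty."""
    a = np.asarray(a, dtype=float).ravel()
    Gram = np.asarray(Gram, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if Gram.shape != (len(y), len(a)):
        raise ValueError("Gram shape inconsistent with a and y")
    w = _weight_vector(y) if weights is None else np.asarray(weights, float)
    u = y * (Gram @ a - c)
    losses = loss_value(u, LossSpec("psi_delta", delta))
    return float(np.mean(w * losses) + 0.5 * lam * a @ Gram @ a)


@dataclass
class KMEModel:
    """Fitted kernel-machine combination: score g(x) = sum_i a_i K(x_i, x),
    diagnostic rule sign(g(x) - c)."""

    a: np.ndarray
    c: float
    X_train: np.ndarray
    kernel: KernelSpec
    lam: float
    delta: float
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    def scores(self, X_new: np.ndarray) -> np.ndarray:
        return predict_score(self, X_new)

    @property
    def cutoff(self) -> float:
        return self.c

    def to_json(self) -> str:
        payload = {
            "a": self.a.tolist(),
            "c": self.c,
            "X_train": self.X_train.tolist(),
            "kernel": {"family": self.kernel.family, "degree": self.kernel.degree,
                       "tau2": self.kernel.tau2},
            "lam": self.lam,
            "delta": self.delta,
            "objective_trace": np.asarray(self.objective_trace).tolist(),
            "converged": self.converged,
            "X_train_sha256": hashlib.sha256(
                np.ascontiguousarray(self.X_train).tobytes()).hexdigest(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "KMEModel":
        d = json.loads(text)
        X = np.asarray(d["X_train"], dtype=float)
        digest = hashlib.sha256(np.ascontiguousarray(X).tobytes()).hexdigest()
        if digest != d["X_train_sha256"]:
            raise ValueError("training-matrix checksum mismatch")
        return cls(a=np.asarray(d["a"], dtype=float), c=float(d["c"]), X_train=X,
                   kernel=KernelSpec(**d["kernel"]), lam=float(d["lam"]),
                   delta=float(d["delta"]),
                   objective_trace=np.asarray(d["objective_trace"], dtype=float),
                   converged=bool(d["converged"]))


def predict_score(model: KMEModel, X_new: np.ndarray) -> np.ndarray:
    """Evaluate g(x) = sum_i a_i K(x_i, x) on each row of X_new."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError("column count mismatch with training data")
    return kernel_matrix(X_new, model.X_train, model.kernel) @ model.a


def fit_kme(data: BiomarkerSample, kernel: KernelSpec, lam: float,
            delta: float = 0.1, max_iter: int = 20, rel_tol: float = 1e-5,
            smo_tol: float = 1e-6, _gram: np.ndarray | None = None) -> KMEModel:
    """Fit the kernel-machine combination by DCA.

    ``_gram`` lets callers (cross-validation) reuse a precomputed training
    Gram matrix; it must equal ``kernel_matrix(X, X, kernel)``.
    """
    data.require_both_classes()
    if not lam > 0:
        raise ValueError("lam must be positive")
    if not (0 < delta <= 1):
        raise ValueError("delta must lie in (0, 1]")
    X, y = data.X, data.y
    n = data.n
    K = kernel_matrix(X, X, kernel) if _gram is None else np.asarray(_gram, float)
    w = _weight_vector(y)
    C = w / (n * delta)
    Q = (y[:, None] * y[None, :]) * K

    a = np.zeros(n)
    c = 0.0
    u = np.zeros(n)
    obj = objective_value(a, c, K, y, delta, lam, w)
    trace = [obj]
    converged = False
    max_smo = max(200 * n, 20000)
    for _ in range(max_iter):
        q = np.where(u < 0, C, 0.0)  # subgradient at u == 0: inactive side
        alpha = smo_solve(Q, y, C, q, delta, lam, smo_tol, max_smo)
        a_new = y * (alpha - q) / lam
        f_new = K @ a_new
        c_new = best_offset(f_new, y, C, q, delta)
        obj_new = objective_value(a_new, c_new, K, y, delta, lam, w)
        if obj_new > obj + 1e-10:
            # subproblem tolerance exhausted; keep the better iterate
            converged = True
            break
        a, c, u = a_new, c_new, y * (f_new - c_new)
        trace.append(obj_new)
        if obj - obj_new < rel_tol * max(abs(obj), 1e-12):
            converged = True
            obj = obj_new
            break
        obj = obj_new
    return KMEModel(a=a, c=float(c), X_train=X.copy(), kernel=kernel, lam=float(lam),
                    delta=float(delta), objective_trace=np.asarray(trace),
                    converged=converged)
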