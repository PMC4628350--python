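"""Low-level solvers for the DCA convex subproblems.

Each DCA iteration of the truncated-ramp objective solves

    min_{a, c}  sum_i C_i (delta - u_i)_+  +  sum_i q_i u_i  +  (lam/2) a'Ka,
    u_i = y_i (K[i] a - c),

where C_i = w_i / (n delta) and q_i in {0, C_i} carries the linearized
concave part.  Its dual is an SVM-like box-constrained QP with a single
equality constraint,

    max_alpha  delta 1'alpha - (1/(2 lam)) (alpha-q)' Q (alpha-q),
    0 <= alpha <= C,   y'(alpha - q) = 0,      Q = diag(y) K diag(y),

solved here by SMO-style maximal-violating-pair updates (numba-compiled;
no general-purpose QP library is required).  The primal coefficients are
recovered as a = y*(alpha-q)/lam and the unpenalized offset c by exact
minimization of the piecewise-linear primal in c.

The covariate-adjusted variant penalizes the offset function too, which
removes the equality constraint; that box QP is solved by L-BFGS-B (the
penalized-offset direction makes the dual too ill-conditioned for
coordinate-wise updates at small lam).
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.optimize import minimize

__all__ = ["smo_solve", "box_qp_solve", "best_offset"]


@njit(cache=True)
def smo_solve(Q, y, C, q, delta, lam, tol, max_iter):  # pragma: no cover - compiled
    n = Q.shape[0]
    alpha = q.copy()  # feasible: box-interior-or-corner and y'(alpha-q)=0
    G = np.zeros(n)  # G = Q (alpha - q)
    for _ in range(max_iter):
        # F_i = y_i * dD/dalpha_i = y_i * (delta - G_i/lam)
        i_up = -1
        j_dn = -1
        f_up = -1e300
        f_dn = 1e300
        for k in range(n):
            fk = y[k] * (delta - G[k] / lam)
            if (y[k] > 0 and alpha[k] < C[k]) or (y[k] < 0 and alpha[k] > 0):
                if fk > f_up:
                    f_up = fk
                    i_up = k
            if (y[k] > 0 and alpha[k] > 0) or (y[k] < 0 and alpha[k] < C[k]):
                if fk < f_dn:
                    f_dn = fk
                    j_dn = k
        if i_up < 0 or j_dn < 0 or f_up - f_dn < tol:
            break
        i = i_up
        j = j_dn
        eta = (Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j]) / lam
        if eta < 1e-12:
            eta = 1e-12
        step = (f_up - f_dn) / eta
        # box room along direction (alpha_i += y_i t, alpha_j -= y_j t)
        hi_i = C[i] - alpha[i] if y[i] > 0 else alpha[i]
        hi_j = alpha[j] if y[j] > 0 else C[j] - alpha[j]
        if step > hi_i:
            step = hi_i
        if step > hi_j:
            step = hi_j
        if step <= 0.0:
            break
        alpha[i] += y[i] * step
        alpha[j] -= y[j] * step
        for k in range(n):
            G[k] += step * (y[i] * Q[k, i] - y[j] * Q[k, j])
    return alpha


def box_qp_solve(Q, C, q, delta, lam, x0=None, maxiter=5000):
    """Maximize delta 1'a - (1/(2 lam)) (a-q)'Q(a-q) over 0 <= a <= C
    (no equality constraint: the offset function is penalized)."""

    def neg_dual(a):
        b = a - q
        Qb = Q @ b
        return (-(delta * a.sum() - (b @ Qb) / (2.0 * lam)),
                -(delta - Qb / lam))

    start = q if x0 is None else np.clip(x0, 0.0, C)
    res = minimize(neg_dual, start, jac=True, method="L-BFGS-B",
                   bounds=list(zip(np.zeros_like(C), C)),
                   options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-9})
    return res.x


def best_offset(f: np.ndarray, y: np.ndarray, C: np.ndarray, q: np.ndarray,
                delta: float) -> float:
    """Exact minimizer over c of the piecewise-linear primal, a held fixed.

    h(c) = sum C_i (delta - y_i(f_i - c))_+ + sum q_i y_i (f_i - c) is convex
    piecewise-linear with breakpoints f_i - y_i delta; the minimum is attained
    at a breakpoint (smallest one on ties).
    """
    b = f - y * delta
    cands = np.unique(b)
    u = y[None, :] * (f[None, :] - cands[:, None])  # candidates x points
    h = (np.maximum(delta - u, 0.0) * C[None, :]).sum(axis=1) + (u * q[None, :]).sum(axis=1)
    return float(cands[int(np.argmin(h))])
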