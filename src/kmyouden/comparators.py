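"""Baseline linear-combination methods benchmarked against the kernel
machine: the parametric binormal method (MVN), the min-max combination
(MMM), the stepwise combination (SWM), and logistic regression (LR).

All four produce a linear score with a scalar cut-point and share the
``scores`` / ``cutoff`` contract of the kernel-machine model, so the study
runner treats every method identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .data import BiomarkerSample
from .model_selection import default_lambda_grid
from .youden import empirical_youden, optimal_cutoff


@dataclass
class LinearComboModel:
    """A fitted linear biomarker combination.

    For ``method="mmm"`` the two coefficients apply to the per-subject
    (max, min) features instead of the raw markers.
    """

    beta: np.ndarray
    cutoff: float
    method: str
    intercept: float = 0.0
    degenerate: bool = False
    extras: dict = field(default_factory=dict)

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.method == "mmm":
            feats = np.column_stack([X.max(axis=1), X.min(axis=1)])
            return feats @ self.beta + self.intercept
        return X @ self.beta + self.intercept


def _coefficient_grid() -> np.ndarray:
    """Shared search grid for MMM/SWM coefficients: 0 and +-10^((s-41)/10)."""
    g = default_lambda_grid()
    return np.concatenate(([0.0], g, -g))


def binormal_optimal_cutpoint(m0: float, s0: float, m1: float, s1: float) -> float:
    """Youden-optimal cut-point for scores N(m0, s0^2) in the negative and
    N(m1, s1^2) in the positive class (closed form; density-crossing root)."""
    if abs(s1 - s0) < 1e-12 * max(s0, s1):
        return 0.5 * (m0 + m1)
    # (c-m1)^2/s1^2 - (c-m0)^2/s0^2 = 2 log(s0/s1)
    A = 1.0 / s1**2 - 1.0 / s0**2
    B = -2.0 * (m1 / s1**2 - m0 / s0**2)
    D = m1**2 / s1**2 - m0**2 / s0**2 - 2.0 * np.log(s0 / s1)
    disc = B**2 - 4 * A * D
    if disc < 0:
        return 0.5 * (m0 + m1)
    roots = np.array([(-B + np.sqrt(disc)) / (2 * A), (-B - np.sqrt(disc)) / (2 * A)])
    J = norm.cdf((roots - m0) / s0) - norm.cdf((roots - m1) / s1)
    return float(roots[int(np.argmax(J))])


def _binormal_J(beta: np.ndarray, mu0, cov0, mu1, cov1) -> tuple[float, float]:
    """Best binormal Youden index of the projection beta'X, with its cutoff."""
    nrm = np.linalg.norm(beta)
    if nrm < 1e-12:
        return 0.0, 0.0
    b = beta / nrm
    m0, m1 = float(b @ mu0), float(b @ mu1)
    s0 = float(np.sqrt(b @ cov0 @ b))
    s1 = float(np.sqrt(b @ cov1 @ b))
    c = binormal_optimal_cutpoint(m0, s0, m1, s1)
    J = norm.cdf((c - m0) / s0) - norm.cdf((c - m1) / s1)
    return float(J), c


def fit_mvn(data: BiomarkerSample, n_starts: int = 10, seed: int = 0) -> LinearComboModel:
    """Parametric method under per-class multivariate normality.

    Class means and covariances are estimated by their sample analogues and
    the linear direction maximizing the binormal Youden index is found
    numerically (unit-norm parameterization, multi-start: the Fisher
    direction plus random unit vectors), with the closed-form binormal
    cut-point.
    """
    data.require_both_classes()
    X, y = data.X, data.y
    m = data.m
    Xp, Xn = X[y > 0], X[y < 0]
    if len(Xp) < 2 or len(Xn) < 2:
        raise ValueError("need at least two observations per class")
    mu1, mu0 = Xp.mean(axis=0), Xn.mean(axis=0)
    cov1 = np.atleast_2d(np.cov(Xp, rowvar=False))
    cov0 = np.atleast_2d(np.cov(Xn, rowvar=False))
    for cov in (cov0, cov1):
        ridge = 1e-6 * np.trace(cov) / m
        while np.linalg.cond(cov) > 1e12:
            cov += ridge * np.eye(m)
            ridge *= 10

    rng = np.random.default_rng(seed)
    pooled = 0.5 * (cov0 + cov1)
    fisher = np.linalg.solve(pooled, mu1 - mu0)
    starts = [fisher / max(np.linalg.norm(fisher), 1e-12)]
    for _ in range(n_starts):
        v = rng.standard_normal(m)
        starts.append(v / np.linalg.norm(v))

    def neg_J(b):
        return -_binormal_J(b, mu0, cov0, mu1, cov1)[0]

    best_b, best_val = starts[0], neg_J(starts[0])
    for s in starts:
        res = minimize(neg_J, s, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400})
        if res.fun < best_val:
            best_val, best_b = res.fun, res.x
    beta = best_b / max(np.linalg.norm(best_b), 1e-12)
    _, cutoff = _binormal_J(beta, mu0, cov0, mu1, cov1)
    return LinearComboModel(beta=beta, cutoff=cutoff, method="mvn",
                            extras={"binormal_J": -best_val})


def fit_minmax(data: BiomarkerSample) -> LinearComboModel:
    """Min-max combination: score = sign * max_j x_j + gamma * min_j x_j.

    The max coefficient is fixed at +-1 and the min coefficient gamma is
    grid-searched (shared coefficient grid), each candidate scored by its
    Youden-optimal training cut-point.
    """
    data.require_both_classes()
    if data.m < 2:
        raise ValueError("min-max combination needs at least two markers")
    X, y = data.X, data.y
    feats = np.column_stack([X.max(axis=1), X.min(axis=1)])
    grid = _coefficient_grid()
    best = None
    for sign in (1.0, -1.0):
        for gam in grid:
            s = sign * feats[:, 0] + gam * feats[:, 1]
            est = optimal_cutoff(s, y)
            if best is None or est.J > best[0].J:
                best = (est, sign, gam)
    est, sign, gam = best
    return LinearComboModel(beta=np.array([sign, gam]), cutoff=est.cutoff,
                            method="mmm", extras={"train_J": est.J})


def fit_stepwise(data: BiomarkerSample) -> LinearComboModel:
    """Stepwise combination: markers enter in order of decreasing
    single-marker Youden index; at each step the running score s gains the
    next marker as s + gamma x_j with gamma grid-searched (zero allowed)."""
    data.require_both_classes()
    X, y = data.X, data.y
    m = data.m
    single = np.array([optimal_cutoff(X[:, j], y).J for j in range(m)])
    order = np.argsort(-single, kind="stable")
    beta = np.zeros(m)
    beta[order[0]] = 1.0
    s = X[:, order[0]].astype(float)
    grid = _coefficient_grid()
    for j in order[1:]:
        best_gam, best_J = 0.0, optimal_cutoff(s, y).J
        for gam in grid[1:]:  # gamma = 0 is the incumbent
            est = optimal_cutoff(s + gam * X[:, j], y)
            if est.J > best_J:
                best_J, best_gam = est.J, gam
        beta[j] = best_gam
        s = s + best_gam * X[:, j]
    est = optimal_cutoff(s, y)
    return LinearComboModel(beta=beta, cutoff=est.cutoff, method="swm",
                            extras={"train_J": est.J, "order": order.tolist()})


def fit_logistic(data: BiomarkerSample, cutoff: str = "prob_half") -> LinearComboModel:
    """Main-effects logistic regression; the score is the linear predictor.

    The default cut-point is the classification default, predicted
    probability 1/2 (linear predictor 0) — this is what standard logistic
    classifiers report and what the benchmark reference values reflect;
    ``cutoff="youden"`` instead optimizes the training Youden index.
    Perfect separation / non-convergence falls back to a ridge-stabilized
    fit (flagged on the model).
    """
    if cutoff not in ("prob_half", "youden"):
        raise ValueError("cutoff must be 'prob_half' or 'youden'")
    data.require_both_classes()
    X, y = data.X, data.y
    degenerate = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000,
                                     tol=1e-8).fit(X, y)
        except ConvergenceWarning:
            degenerate = True
    if not degenerate:
        s = X @ clf.coef_.ravel() + clf.intercept_[0]
        if s[y > 0].min() > s[y < 0].max():  # perfect separation: MLE diverges
            degenerate = True
    if degenerate:
        clf = LogisticRegression(C=1000.0, solver="lbfgs", max_iter=1000).fit(X, y)
    beta = clf.coef_.ravel().astype(float)
    intercept = float(clf.intercept_[0])
    s = X @ beta + intercept
    if cutoff == "youden":
        est = optimal_cutoff(s, y)
        c, train_J = est.cutoff, est.J
    else:
        c = 0.0
        train_J = empirical_youden(s, y, c).J
    return LinearComboModel(beta=beta, cutoff=c, method="lr",
                            intercept=intercept, degenerate=degenerate,
                            extras={"train_J": train_J})
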