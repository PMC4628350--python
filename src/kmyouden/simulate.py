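"""Synthetic biomarker studies used to benchmark the combination methods.

Four four-marker examples span the regimes a practitioner cares about:

* ``ex1`` — homoscedastic Gaussian classes (a linear combination is Bayes
  optimal): Y ~ Bernoulli(1/2); X|Y=1 ~ MVN((0.4, 1.0, 1.5, 1.2),
  0.3 I4 + 0.7 J4), X|Y=-1 ~ MVN(0, same covariance).
* ``ex2`` — skewed positive markers: per-class multivariate gamma built
  from a shared common-shock, X_j = G0 + G_j with G0 ~ Gamma(1, 0.5) and
  G_j ~ Gamma(k_j, 0.5) (k = (0.1, 0.4, 0.7, 1.0) for positives, 0.1 for
  all negatives), which gives positives mean (0.55, 0.7, 0.85, 1.0) and
  covariance 0.25 J4 + diag(0.025, 0.1, 0.175, 0.25) exactly, negatives
  mean 0.55·1 and covariance 0.025 I4 + 0.25 J4.  A Gaussian-copula
  multivariate gamma with these moments (``gamma_copula_sample``) is also
  provided, but its weaker tail dependence makes the classes measurably
  less separable than the common-shock model.
* ``ex3`` — polynomial logistic model: X ~ MVN(0, 0.3 I4 + 0.7 J4),
  logit p(x) = x1 + x2^2 + x3^3 + x4^4 - 1.5.
* ``ex4`` — heavy tails and strong nonlinearity: X ~ t4(0, I4) (I4 read
  as the t scale matrix), logit p(x) = 8 (sin(pi x1 / 2) + cos(pi x1 x2)
  + x3^2 + 3 x3 x4 + x4^2).

Two bivariate toys illustrate when the ideal combination is linear
(``toy_homo``: N2((1,1), I2) vs N2((0,0), I2), ideal score x1 + x2 at
cut-point 1) or quadratic (``toy_hetero``: negative covariance 2 I2,
ideal score (x1^2 + x2^2)/4 - (x1 + x2) at cut-point log(2) - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from .comparators import fit_logistic, fit_minmax, fit_mvn, fit_stepwise
from .data import BiomarkerSample
from .kernels import KernelSpec, median_heuristic_tau2
from .kme import fit_kme
from .model_selection import CVConfig, default_lambda_grid, select_lambda
from .youden import empirical_youden

EXAMPLE_IDS = ("ex1", "ex2", "ex3", "ex4", "toy_homo", "toy_hetero")


@dataclass
class SimulationConfig:
    """One cell of the benchmark study."""

    example_id: str = "ex1"
    n_tr: int = 100
    n_te: int = 2000
    replications: int = 100
    seed: int = 0
    methods: list[str] = field(default_factory=lambda: ["lr"])
    delta: float = 0.1
    cv_folds: int = 5
    grid_thin: int = 1

    def __post_init__(self) -> None:
        if self.example_id not in EXAMPLE_IDS:
            raise ValueError(f"unknown example {self.example_id!r}")
        if self.n_te < 1 or self.replications < 1:
            raise ValueError("n_te and replications must be >= 1")


def _compound_symmetric(diag: float, offdiag: float, dim: int) -> np.ndarray:
    return diag * np.eye(dim) + offdiag * np.ones((dim, dim))


def gamma_copula_sample(mean, cov, n: int, seed=None) -> np.ndarray:
    """Multivariate gamma draws via a Gaussian copula.

    Marginals are gamma with shape mu_j^2/sigma_j^2 and scale
    sigma_j^2/mu_j (moment matching); dependence comes from a Gaussian
    copula whose correlation matrix is the correlation matrix of ``cov``
    (no Nataf correction — the induced covariance is only approximately
    ``cov`` off the diagonal).
    """
    mean = np.asarray(mean, dtype=float).ravel()
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if np.any(mean <= 0) or np.any(np.diag(cov) <= 0):
        raise ValueError("gamma marginals need positive means and variances")
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    # reject non-PD correlation targets
    if np.min(np.linalg.eigvalsh(corr)) <= 1e-10:
        raise ValueError("copula correlation matrix is not positive definite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    var = np.diag(cov)
    shape = mean**2 / var
    scale = var / mean
    Z = rng.multivariate_normal(np.zeros(len(mean)), corr, size=n,
                                method="cholesky")
    U = norm.cdf(Z)
    U = np.clip(U, 1e-12, 1 - 1e-12)
    return gamma_dist.ppf(U, shape[None, :], scale=scale[None, :])


def _labels_from_prob(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.where(rng.random(len(p)) < p, 1.0, -1.0)


def generate_example(example_id: str, n: int, seed=None) -> BiomarkerSample:
    """Draw a sample of size n from one of the study distributions."""
    if example_id not in EXAMPLE_IDS:
        raise ValueError(f"unknown example {example_id!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if example_id == "ex1":
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        cov = _compound_symmetric(0.3, 0.7, 4)
        mu1 = np.array([0.4, 1.0, 1.5, 1.2])
        X = rng.multivariate_normal(np.zeros(4), cov, size=n, method="cholesky")
        X[y > 0] += mu1
        return BiomarkerSample(X, y)
    if example_id == "ex2":
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        X = np.empty((n, 4))
        for mask, shapes in ((y > 0, (0.1, 0.4, 0.7, 1.0)),
                             (y < 0, (0.1, 0.1, 0.1, 0.1))):
            k = int(mask.sum())
            shock = rng.gamma(1.0, 0.5, size=k)  # shared across markers
            own = np.column_stack([rng.gamma(s, 0.5, size=k) for s in shapes])
            X[mask] = shock[:, None] + own
        return BiomarkerSample(X, y)
    if example_id == "ex3":
        cov = _compound_symmetric(0.3, 0.7, 4)
        X = rng.multivariate_normal(np.zeros(4), cov, size=n, method="cholesky")
        logit = X[:, 0] + X[:, 1] ** 2 + X[:, 2] ** 3 + X[:, 3] ** 4 - 1.5
        p = 1.0 / (1.0 + np.exp(-logit))
        return BiomarkerSample(X, _labels_from_prob(p, rng))
    if example_id == "ex4":
        Z = rng.standard_normal((n, 4))
        chi = rng.chisquare(4, size=n)
        X = Z / np.sqrt(chi / 4.0)[:, None]
        logit = 8.0 * (np.sin(0.5 * np.pi * X[:, 0]) + np.cos(np.pi * X[:, 0] * X[:, 1])
                       + X[:, 2] ** 2 + 3.0 * X[:, 2] * X[:, 3] + X[:, 3] ** 2)
        p = 1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500)))
        return BiomarkerSample(X, _labels_from_prob(p, rng))
    # bivariate toys
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    X = rng.standard_normal((n, 2))
    if example_id == "toy_hetero":
        X[y < 0] *= np.sqrt(2.0)
    X[y > 0] += 1.0
    return BiomarkerSample(X, y)


def _fit_kme_method(train: BiomarkerSample, family: str, delta: float,
                    cv_folds: int, grid_thin: int, seed: int):
    if family == "gaussian":
        kernel = KernelSpec("gaussian", tau2=median_heuristic_tau2(train.X, train.y))
    else:
        kernel = KernelSpec("linear")
    grid = default_lambda_grid()[::grid_thin]
    cv = CVConfig(folds=cv_folds, lambda_grid=grid, seed=seed)
    lam, _ = select_lambda(train, kernel, cv, delta=delta)
    return fit_kme(train, kernel, lam, delta=delta)


def fit_method(name: str, train: BiomarkerSample, seed: int = 0, delta: float = 0.1,
               cv_folds: int = 5, grid_thin: int = 1):
    """Fit any benchmarked method by name; all return the scores/cutoff contract."""
    name = name.lower()
    if name == "lkme":
        return _fit_kme_method(train, "linear", delta, cv_folds, grid_thin, seed)
    if name == "gkme":
        return _fit_kme_method(train, "gaussian", delta, cv_folds, grid_thin, seed)
    if name == "mvn":
        return fit_mvn(train, seed=seed)
    if name == "mmm":
        return fit_minmax(train)
    if name == "swm":
        return fit_stepwise(train)
    if name == "lr":
        return fit_logistic(train)
    raise ValueError(f"unknown method {name!r}")


def run_study(config: SimulationConfig) -> pd.DataFrame:
    """Replicate the benchmark protocol for one study cell.

    Each replication draws fresh training (n_tr) and testing (n_te) sets,
    fits every requested method on the training set, and records the test
    empirical Youden index at the method's own fitted cut-point.  The tidy
    result has one row per method with the mean, the replication standard
    deviation, and the standard error of the mean; failed replications are
    warned about and excluded, never silently dropped.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.replications)
    results: dict[str, list[float]] = {m: [] for m in config.methods}
    failures: dict[str, int] = {m: 0 for m in config.methods}
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        train = generate_example(config.example_id, config.n_tr, rng)
        test = generate_example(config.example_id, config.n_te, rng)
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        for name in config.methods:
            try:
                model = fit_method(name, train, seed=rep_seed, delta=config.delta,
                                   cv_folds=config.cv_folds,
                                   grid_thin=config.grid_thin)
                est = empirical_youden(model.scores(test.X), test.y, model.cutoff)
                results[name].append(est.J)
            except Exception as exc:  # noqa: BLE001 - recorded, not silenced
                failures[name] += 1
                warnings.warn(f"replication {rep} failed for {name}: {exc}",
                              stacklevel=2)
    rows = []
    for name in config.methods:
        vals = np.asarray(results[name])
        k = len(vals)
        sd = float(np.std(vals, ddof=1)) if k > 1 else 0.0
        rows.append({"example": config.example_id, "n_tr": config.n_tr,
                     "method": name, "mean_J": float(np.mean(vals)) if k else np.nan,
                     "sd_J": sd, "se_J": sd / np.sqrt(k) if k > 1 else np.nan,
                     "replications": k, "failures": failures[name]})
    return pd.DataFrame(rows)
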