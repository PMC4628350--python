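"""Kernel functions, Gram matrices, and the median-heuristic scale.

Three kernel families are supported:

* linear          ``K(u, v) = u'v``
* polynomial      ``K(u, v) = (1 + u'v)^d``
* gaussian        ``K(u, v) = exp(-||u - v||^2 / (2 tau^2))``

The Gaussian scale ``tau^2`` defaults to the square of the median of
pairwise Euclidean distances between positive and negative training
instances (the median heuristic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus its parameters.

    ``degree`` applies to the polynomial family only; ``tau2`` (the squared
    scale) to the Gaussian family only.
    """

    family: str = "linear"
    degree: int = 2
    tau2: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("linear", "polynomial", "gaussian"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.family == "gaussian" and not self.tau2 > 0:
            raise ValueError("gaussian tau2 must be positive")


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix ``K[i, j] = K(X1[i], X2[j])`` for the given kernel."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("X1 and X2 must have the same number of columns")
    if not (np.all(np.isfinite(X1)) and np.all(np.isfinite(X2))):
        raise ValueError("non-finite input values")
    if spec.family == "linear":
        return X1 @ X2.T
    if spec.family == "polynomial":
        return (1.0 + X1 @ X2.T) ** spec.degree
    d2 = cdist(X1, X2, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * spec.tau2))


def median_heuristic_tau2(X: np.ndarray, y: np.ndarray) -> float:
    """Squared median of cross-class pairwise Euclidean distances.

    Only positive-vs-negative pairs enter the median; an even pair count
    uses the mean of the two central order statistics.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    pos = X[y > 0]
    neg = X[y < 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    d = cdist(pos, neg, metric="euclidean").ravel()
    med = float(np.median(d))
    if med <= 0:
        raise ValueError("median cross-class distance is zero (coincident classes)")
    return med**2
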