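"""Core data container for labelled biomarker panels.

A sample holds an ``n x m`` matrix of continuous marker measurements, a
label vector in ``{+1, -1}`` (diseased / non-diseased), and optionally an
``n x q`` covariate matrix used by the covariate-adjusted estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BiomarkerSample:
    """Labelled biomarker measurements.

    Parameters
    ----------
    X : ndarray of shape (n, m)
        Continuous marker measurements, one row per subject.
    y : ndarray of shape (n,)
        Disease labels in {+1, -1}.
    Z : ndarray of shape (n, q), optional
        Covariates for the covariate-adjusted variant.
    """

    X: np.ndarray
    y: np.ndarray
    Z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite values in X")
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise ValueError("labels must be +1 or -1")
        if self.Z is not None:
            self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
            if self.Z.shape[0] != self.y.shape[0]:
                raise ValueError("Z row count does not match y")
            if not np.all(np.isfinite(self.Z)):
                raise ValueError("non-finite values in Z")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def require_both_classes(self) -> None:
        if not (np.any(self.y > 0) and np.any(self.y < 0)):
            raise ValueError("both classes (+1 and -1) must be present")
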