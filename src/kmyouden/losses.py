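"""Surrogate loss functions for margin-based Youden-index estimation.

All losses are functions of the functional margin ``u = y (g(x) - c)``.
The workhorse is the truncated ramp ("psi-delta") loss

    L_delta(u) = min{ (delta - u)_+ / delta, 1 },

a non-convex surrogate of the 0-1 loss that equals 1 for u <= 0, ramps
linearly down on (0, delta) and vanishes for u >= delta.  It admits the
difference-of-convex split used by the DCA solver:

    L_delta(u) = (delta - u)_+ / delta  -  (-u)_+ / delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VALID_KINDS = ("zero_one", "hinge", "logistic", "psi", "psi_delta")


@dataclass(frozen=True)
class LossSpec:
    kind: str = "psi_delta"
    delta: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.kind == "psi_delta" and not (0 < self.delta <= 1):
            raise ValueError("delta must lie in (0, 1]")


def loss_value(u, spec: LossSpec):
    """Evaluate the loss at margin ``u`` (scalar or array).

    The 0-1 loss uses the convention sign(0) = +1, so u = 0 incurs no
    0-1 loss while every surrogate is 1 there.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite margin")
    if spec.kind == "zero_one":
        out = np.where(u < 0, 1.0, 0.0)
    elif spec.kind == "hinge":
        out = np.maximum(1.0 - u, 0.0)
    elif spec.kind == "logistic":
        out = np.logaddexp(0.0, -u)
    elif spec.kind == "psi":
        out = np.minimum(np.maximum(1.0 - u, 0.0), 1.0)
    else:
        d = spec.delta
        out = np.minimum(np.maximum(d - u, 0.0) / d, 1.0)
    return out if out.ndim else float(out)


def psi_delta_dc_parts(u, delta: float):
    """Convex and concave parts of the DC split of the psi-delta loss.

    Returns ``((delta - u)_+ / delta, (-u)_+ / delta)``; their difference
    equals ``loss_value(u, psi_delta)`` for every u.
    """
    if not delta > 0:
        raise ValueError("delta must be positive")
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite margin")
    convex = np.maximum(delta - u, 0.0) / delta
    concave = np.maximum(-u, 0.0) / delta
    if convex.ndim:
        return convex, concave
    return float(convex), float(concave)
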