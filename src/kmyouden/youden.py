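"""Empirical Youden index and optimal cut-point search.

Boundary convention: a score exactly equal to the cut-point is classified
negative (the "<= c" indicator), so

    specificity(c) = #{negatives with score <= c} / #negatives
    sensitivity(c) = #{positives with score >  c} / #positives
    J(c)           = sensitivity + specificity - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class YoudenEstimate:
    """Empirical Youden index with its operating point."""

    J: float
    sensitivity: float
    specificity: float
    cutoff: float


def _check(scores: np.ndarray, y: np.ndarray):
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if scores.shape != y.shape:
        raise ValueError("scores and y must have the same length")
    if not (np.any(y > 0) and np.any(y < 0)):
        raise ValueError("both classes must be present")
    return scores, y


def empirical_youden(scores, y, cutoff: float) -> YoudenEstimate:
    """Sensitivity, specificity and J of a score vector at a fixed cut-point."""
    scores, y = _check(scores, y)
    pos = y > 0
    sen = float(np.mean(scores[pos] > cutoff))
    spe = float(np.mean(scores[~pos] <= cutoff))
    return YoudenEstimate(J=sen + spe - 1.0, sensitivity=sen, specificity=spe,
                          cutoff=float(cutoff))


def optimal_cutoff(scores, y) -> YoudenEstimate:
    """Cut-point maximizing the empirical Youden index.

    Candidates are midpoints between consecutive distinct sorted scores plus
    sentinels below the minimum and above the maximum; ties are broken by the
    smallest maximizing candidate.
    """
    scores, y = _check(scores, y)
    uniq = np.unique(scores)
    if len(uniq) == 1:
        cands = np.array([uniq[0] - 1.0, uniq[0] + 1.0])
    else:
        mids = 0.5 * (uniq[:-1] + uniq[1:])
        cands = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    pos = y > 0
    s_pos = np.sort(scores[pos])
    s_neg = np.sort(scores[~pos])
    # J(c) = F_neg(c) - F_pos(c) with F the empirical CDFs (<= convention)
    F_neg = np.searchsorted(s_neg, cands, side="right") / len(s_neg)
    F_pos = np.searchsorted(s_pos, cands, side="right") / len(s_pos)
    J = F_neg - F_pos
    k = int(np.argmax(J))
    return empirical_youden(scores, y, float(cands[k]))
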