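"""Turning per-2-s-segment predictions into 10-s seizure flags.

The base rule: a sliding block of 10 consecutive 2-s segments (1-segment
hop) is flagged as a seizure when more than 7 of the 10 predictions are 1
(i.e. at least 8).  Within a maximal run of consecutive flagged blocks only
the first is retained.  Because of the 50 % overlap the 10-segment block
physically spans 11 s; flags store the geometric interval ``[start,
start+11]`` and are reported nominally as 10-s flags.

Low-trust filtering (LTF) generalises the rule: per patient, the fraction
``q`` of segments with the lowest trust (or confidence) scores is marked
untrustworthy.  In each block, if fewer than 5 of the 10 predictions are
marked, the block is flagged when the mean of the remaining predictions
exceeds 0.7; otherwise it is flagged when the mean of the 5 highest-trusted
predictions (selected from all 10 by score) exceeds 0.7.  With an empty mask
this reduces exactly to the 8-of-10 rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SeizureFlag", "seizure_flags", "mark_untrustworthy", "ltf_flags"]

WINDOW = 10  # segments per flag block
MIN_POSITIVE = 8  # "more than 7 out of 10"
MEAN_THRESHOLD = 0.7
FLAG_SPAN_S = 11.0  # 10 segments of 2 s at 1-s hop
HOP_S = 1.0


@dataclass
class SeizureFlag:
    """A flagged 10-segment block; the interval covers [start, start+11] s."""

    start_s: float
    end_s: float

    @classmethod
    def at(cls, start_s: float) -> "SeizureFlag":
        return cls(float(start_s), float(start_s) + FLAG_SPAN_S)


def _first_of_runs(flagged: np.ndarray) -> np.ndarray:
    """Indices of the first window of each maximal run of flagged windows."""
    if flagged.size == 0:
        return np.empty(0, dtype=int)
    prev = np.concatenate([[False], flagged[:-1]])
    return np.flatnonzero(flagged & ~prev)


def seizure_flags(predictions, hop_s: float = HOP_S) -> list[SeizureFlag]:
    """Apply the 8-of-10 sliding rule with first-of-run retention."""
    p = np.asarray(predictions)
    if p.size < WINDOW:
        return []
    counts = sliding_window_view(p, WINDOW).sum(axis=1)
    starts = _first_of_runs(counts >= MIN_POSITIVE)
    return [SeizureFlag.at(i * hop_s) for i in starts]


def mark_untrustworthy(scores, q: float) -> np.ndarray:
    """Boolean mask of the floor(q*n) lowest-scored segments (ties: earlier time)."""
    if not 0.0 <= q < 1.0:
        raise ValueError("filter fraction q must lie in [0, 1)")
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    k = int(np.floor(q * n + 1e-9))  # guard against 0.29*100 = 28.999...
    mask = np.zeros(n, dtype=bool)
    if k:
        order = np.argsort(scores, kind="stable")
        mask[order[:k]] = True
    return mask


def ltf_flags(predictions, mask, scores, hop_s: float = HOP_S) -> list[SeizureFlag]:
    """Low-trust-filtered flag rule.

    Parameters
    ----------
    predictions : binary per-segment predictions.
    mask : boolean per-segment untrustworthy mask (see
        :func:`mark_untrustworthy`).
    scores : per-segment trust/confidence scores used to rank the "5
        highest-trusted" fallback (ties broken by earlier time).
    """
    p = np.asarray(predictions, dtype=float)
    m = np.asarray(mask, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if not (p.size == m.size == s.size):
        raise ValueError("predictions, mask and scores must have equal lengths")
    if p.size < WINDOW:
        return []

    P = sliding_window_view(p, WINDOW)
    M = sliding_window_view(m, WINDOW)
    S = sliding_window_view(s, WINDOW)

    r = M.sum(axis=1)
    kept = (~M).sum(axis=1)
    mean_unmasked = (P * ~M).sum(axis=1) / np.maximum(kept, 1)

    # 5 highest-trusted of all 10 (masked or not); stable sort on -score
    # keeps the earliest segment first among ties
    top5 = np.take_along_axis(
        P, np.argsort(-S, axis=1, kind="stable")[:, :5], axis=1
    )
    mean_top5 = top5.mean(axis=1)

    flagged = np.where(r < 5, mean_unmasked > MEAN_THRESHOLD, mean_top5 > MEAN_THRESHOLD)
    return [SeizureFlag.at(i * hop_s) for i in _first_of_runs(flagged)]
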