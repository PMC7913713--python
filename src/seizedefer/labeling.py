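"""Label regimes for 2-s segments: full-seizure (FS) and clear-ictal (CI).

FS labels mark every segment overlapping an annotated seizure event by at
least 1 s.  CI labels mark only segments fully contained in each event's
designated 10-s clear-ictal window, so CI-positive training segments are
guaranteed to be pure ictal.  On the integer 1-s-hop grid a 10-s window
contains exactly 9 fully-contained 2-s segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SeizureEvent",
    "BackgroundStats",
    "select_clear_ictal_window",
    "derive_labels",
]

SEGMENT_S = 2.0
HOP_S = 1.0
CLEAR_ICTAL_S = 10.0


@dataclass
class SeizureEvent:
    """Annotated seizure interval [onset_s, end_s) with optional 10-s clear-ictal window."""

    onset_s: float
    end_s: float
    clear_ictal_start_s: float | None = None

    def __post_init__(self):
        if self.end_s - self.onset_s < CLEAR_ICTAL_S:
            raise ValueError("seizure events must last at least 10 s")
        if self.clear_ictal_start_s is not None:
            if not (
                self.onset_s
                <= self.clear_ictal_start_s
                <= self.end_s - CLEAR_ICTAL_S
            ):
                raise ValueError("clear-ictal window must lie inside the event")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.onset_s


@dataclass
class BackgroundStats:
    """Pre-event background statistics of the amplitude / frequency-change proxies."""

    amp_mean: float
    amp_sd: float
    freq_mean: float = 0.0
    freq_sd: float = 1.0


def select_clear_ictal_window(
    amplitude_series: np.ndarray,
    freq_change_series: np.ndarray,
    event: SeizureEvent,
    background: BackgroundStats,
    amp_factor: float = 2.0,
    freq_factor: float = 2.0,
) -> float:
    """Pick the start of the event's 10-s clear-ictal window.

    Priority: the first 10-s window whose mean amplitude exceeds the
    background mean by ``amp_factor`` background standard deviations; failing
    that, the first window whose mean frequency-change score exceeds its
    threshold; failing that, the event onset.

    The series are indexed by segment start (1-s hop); a 10-s window starting
    at ``t`` averages the 9 segments fully inside ``[t, t+10]``.
    """
    if event.duration_s < CLEAR_ICTAL_S:
        raise ValueError("event shorter than 10 s")
    amp = np.asarray(amplitude_series, dtype=float)
    freq = np.asarray(freq_change_series, dtype=float)
    t0 = int(event.onset_s)
    t_last = int(event.end_s - CLEAR_ICTAL_S)
    if t_last + 9 > amp.size or t_last + 9 > freq.size:
        raise ValueError("series do not cover the event")

    amp_thresh = background.amp_mean + amp_factor * background.amp_sd
    for t in range(t0, t_last + 1):
        if amp[t : t + 9].mean() > amp_thresh:
            return float(t)
    freq_thresh = background.freq_mean + freq_factor * background.freq_sd
    for t in range(t0, t_last + 1):
        if freq[t : t + 9].mean() > freq_thresh:
            return float(t)
    return float(event.onset_s)


def derive_labels(events, regime: str, n_segments: int) -> np.ndarray:
    """Binary per-segment labels on the 1-s-hop grid.

    FS: segment labelled 1 iff its overlap with any event is >= 1 s.
    CI: segment labelled 1 iff it lies entirely inside a clear-ictal window.
    """
    regime = regime.lower()
    if regime not in ("fs", "ci"):
        raise ValueError("regime must be 'fs' or 'ci'")
    events = sorted(events, key=lambda e: e.onset_s)
    for a, b in zip(events, events[1:]):
        if b.onset_s < a.end_s:
            raise ValueError("overlapping seizure events")

    labels = np.zeros(n_segments, dtype=np.int8)
    starts = np.arange(n_segments, dtype=float) * HOP_S
    for ev in events:
        if regime == "fs":
            ov = np.minimum(starts + SEGMENT_S, ev.end_s) - np.maximum(
                starts, ev.onset_s
            )
            labels[ov >= 1.0] = 1
        else:
            if ev.clear_ictal_start_s is None:
                raise ValueError(
                    f"event at {ev.onset_s}s lacks a clear-ictal window for CI labels"
                )
            w0 = ev.clear_ictal_start_s
            w1 = w0 + CLEAR_ICTAL_S
            inside = (starts >= w0) & (starts + SEGMENT_S <= w1)
            labels[inside] = 1
    return labels
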