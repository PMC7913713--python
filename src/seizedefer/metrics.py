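"""Event-based scoring of seizure flags, cohort aggregation and testing.

Scoring is per event: a flag overlapping the annotated interval of a
seizure makes it a true positive (multiple flags on one event still count
once); events without any overlapping flag are false negatives; flags
overlapping no event are false positives, with FPs whose starts lie within
10 s of each other collapsed into one.  Metrics are computed per patient and
then averaged across patients; detection sensitivity (DS), PPV and F1 are
only defined for patients with at least one seizure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PatientMetrics",
    "match_events",
    "patient_metrics",
    "aggregate_cohort",
    "paired_test",
    "ranking_agreement",
]


@dataclass
class PatientMetrics:
    """Per-patient event-based performance.

    ``ds``, ``ppv`` and ``f1`` are percentages and ``None`` for patients
    without seizures; ``mean_delay_s`` is ``None`` when no event was detected
    by an algorithm flag (e.g. all detections were made by the human
    annotator under deferral).
    """

    tp: int
    fp: int
    fn: int
    recording_days: float
    delays_s: list = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return self.tp + self.fn

    @property
    def ds(self) -> float | None:
        return 100.0 * self.tp / self.n_events if self.n_events else None

    @property
    def fdr_per_24h(self) -> float:
        return self.fp / self.recording_days

    @property
    def ppv(self) -> float | None:
        if not self.n_events:
            return None
        if self.tp + self.fp == 0:
            # seizure patient with no flags at all: no detection was offered
            return 0.0 if self.fn else 100.0
        return 100.0 * self.tp / (self.tp + self.fp)

    @property
    def f1(self) -> float | None:
        if not self.n_events:
            return None
        return 100.0 * 2 * self.tp / (2 * self.tp + self.fp + self.fn)

    @property
    def mean_delay_s(self) -> float | None:
        return float(np.mean(self.delays_s)) if self.delays_s else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "recording_days": self.recording_days,
            "ds": self.ds,
            "fdr_per_24h": self.fdr_per_24h,
            "ppv": self.ppv,
            "f1": self.f1,
            "mean_delay_s": self.mean_delay_s,
        }


def merge_fp_starts(starts, within_s: float = 10.0) -> int:
    """Count false positives after chaining starts within ``within_s`` of each other."""
    starts = sorted(starts)
    if not starts:
        return 0
    count = 1
    for a, b in zip(starts, starts[1:]):
        if b - a > within_s:
            count += 1
    return count


def match_events(flags, events, duration_s: float):
    """Match flags to events.

    Returns ``(tp, fp, fn, delays)`` where ``delays`` holds, for each
    detected event, the start of its first overlapping flag minus the event
    onset (seconds).
    """
    for f in flags:
        if f.start_s < 0 or f.end_s > duration_s:
            raise ValueError("flag outside the recording")
    flags = sorted(flags, key=lambda f: f.start_s)
    events = sorted(events, key=lambda e: e.onset_s)

    tp = 0
    delays = []
    matched = [False] * len(flags)
    for ev in events:
        hit = [
            i
            for i, f in enumerate(flags)
            if f.start_s < ev.end_s and f.end_s > ev.onset_s
        ]
        if hit:
            tp += 1
            delays.append(flags[hit[0]].start_s - ev.onset_s)
            for i in hit:
                matched[i] = True
    fn = len(events) - tp
    fp = merge_fp_starts([f.start_s for f, m in zip(flags, matched) if not m])
    return tp, fp, fn, delays


def patient_metrics(flags, events, duration_s: float) -> PatientMetrics:
    """Event-based metrics for one patient's flags against its annotations."""
    tp, fp, fn, delays = match_events(flags, events, duration_s)
    return PatientMetrics(tp, fp, fn, duration_s / 86_400.0, delays)


def _agg(values) -> dict:
    vals = [v for v in values if v is not None]
    if not vals:
        return {"mean": None, "sd": None, "median": None, "min": None, "max": None, "n": 0}
    arr = np.asarray(vals, dtype=float)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "n": int(arr.size),
    }


def aggregate_cohort(per_patient: list[PatientMetrics]) -> dict:
    """Mean (sd) and median [range] tables across patients.

    DS, PPV, F1 and delay are averaged over patients with seizures (delay:
    with at least one algorithm-detected seizure); FDR over all patients.
    """
    return {
        "ds": _agg(m.ds for m in per_patient),
        "fdr_per_24h": _agg(m.fdr_per_24h for m in per_patient),
        "ppv": _agg(m.ppv for m in per_patient),
        "f1": _agg(m.f1 for m in per_patient),
        "mean_delay_s": _agg(m.mean_delay_s for m in per_patient),
    }


def paired_test(metric_a, metric_b, direction: str = "greater") -> float:
    """One-sided Wilcoxon signed-rank p-value for paired per-patient metrics.

    ``direction="greater"`` tests whether ``metric_a`` tends to exceed
    ``metric_b``.  The exact null distribution is used for n <= 25 without
    ties or zeros, otherwise the normal approximation with tie correction.
    Identical vectors return 0.5 by convention.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metric vectors must have equal lengths")
    if np.allclose(a, b):
        return 0.5
    res = stats.wilcoxon(a, b, alternative=direction, method="auto")
    return float(res.pvalue)


def ranking_agreement(conf_by_patient, trust_by_patient) -> float:
    """Kendall rank correlation between confidences and trust scores,
    computed per patient and then averaged."""
    taus = []
    for conf, tr in zip(conf_by_patient, trust_by_patient):
        tau = stats.kendalltau(conf, tr).statistic
        taus.append(tau)
    return float(np.mean(taus))
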