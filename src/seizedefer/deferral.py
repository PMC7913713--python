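"""Deferral of low-confidence recording segments to a perfect human annotator.

The recording is partitioned into reviewable segments: every seizure flag is
centred in a 5-min segment (segments closer than 5 min are merged; segments
at the recording boundary are shifted inward to keep their length), and the
remaining signal is tiled left-to-right with 5-min segments.  Each non-flag
segment receives a confidence score: the mean of the lowest ``p_low`` percent
of its 2-s segment scores.  Segments are then deferred — flag segments
unconditionally in the default mode, the rest in increasing score order —
until the requested fraction of recording time is reached.

The human annotator is modelled as perfect: false-positive flags inside
deferred time disappear, and a seizure counts as detected when at least 10 s
of it lies in deferred time or an algorithm flag overlaps its non-deferred
part.  An undetected seizure split so that both parts hold less than 10 s
stays undetected.  In the alternative ("any_overlap") mode, flag segments are not
prioritised and a flag overlapping deferred time by at least 1 s counts as
fully human-checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .metrics import PatientMetrics, merge_fp_starts

__all__ = [
    "DeferralSegment",
    "build_deferral_segments",
    "aggregate_confidence",
    "score_segments",
    "select_deferrals",
    "evaluate_with_deferral",
    "deferral_curve",
]

SEGMENT_LEN_S = 300.0
_EPS = 1e-9


@dataclass
class DeferralSegment:
    """A reviewable interval [start_s, end_s); >= 300 s except at boundaries."""

    start_s: float
    end_s: float
    contains_flag: bool = False
    score: float | None = None

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


def _merge_intervals(intervals, gap: float = 0.0):
    """Union of intervals, merging pairs whose gap is < ``gap`` (or overlap)."""
    out: list[list[float]] = []
    for s, e in sorted(intervals):
        if out and s - out[-1][1] < gap + _EPS:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def build_deferral_segments(duration_s: float, flags) -> list[DeferralSegment]:
    """Partition the recording into flag-centred and tiled 5-min segments."""
    L = SEGMENT_LEN_S
    flag_ivs = []
    for f in flags:
        c = 0.5 * (f.start_s + f.end_s)
        if duration_s <= L:
            flag_ivs.append((0.0, float(duration_s)))
            continue
        s = min(max(c - L / 2, 0.0), duration_s - L)
        flag_ivs.append((s, s + L))
    # segments with < 5 min between them are merged
    flag_ivs = _merge_intervals(flag_ivs, gap=L)

    segments = [DeferralSegment(s, e, contains_flag=True) for s, e in flag_ivs]

    # tile the remaining gaps left-to-right with 5-min pieces; a final
    # remainder < 300 s is absorbed into the previous tile of the same gap
    # so only boundary gaps may produce short segments
    edges = [0.0] + [x for iv in flag_ivs for x in iv] + [float(duration_s)]
    for g0, g1 in zip(edges[::2], edges[1::2]):
        gap = g1 - g0
        if gap <= _EPS:
            continue
        n_tiles = int(gap // L)
        rem = gap - n_tiles * L
        if n_tiles == 0:
            segments.append(DeferralSegment(g0, g1))
            continue
        for i in range(n_tiles):
            segments.append(DeferralSegment(g0 + i * L, g0 + (i + 1) * L))
        if rem > _EPS:
            segments[-1].end_s = g1
    segments.sort(key=lambda s: s.start_s)

    # boundary slivers shorter than one 2-s segment cannot be scored;
    # absorb them into their neighbour
    cleaned: list[DeferralSegment] = []
    for seg in segments:
        if cleaned and cleaned[-1].length_s < 2.0:  # leading sliver
            seg.start_s = cleaned.pop().start_s
        if seg.length_s >= 2.0 or not cleaned:
            cleaned.append(seg)
        else:  # trailing sliver
            cleaned[-1].end_s = seg.end_s
    return cleaned


def _contained_slice(segment: DeferralSegment, n_scores: int):
    """Index range of 2-s segments (1-s hop) fully inside the deferral segment."""
    lo = int(math.ceil(segment.start_s - _EPS))
    hi = int(math.floor(segment.end_s - 2 + _EPS))
    hi = min(hi, n_scores - 1)
    return lo, hi


def aggregate_confidence(segment: DeferralSegment, per2s_scores, p_low: float) -> float:
    """Mean of the lowest ``p_low`` percent of the segment's 2-s scores.

    ``k = max(1, ceil(p_low/100 * n))`` lowest scores are averaged, with
    ``n`` the number of 2-s segments fully inside the deferral segment.
    """
    if not 0.0 < p_low <= 100.0:
        raise ValueError("p_low must lie in (0, 100]")
    scores = np.asarray(per2s_scores, dtype=float)
    lo, hi = _contained_slice(segment, scores.size)
    if hi < lo:
        raise ValueError("deferral segment contains no 2-s segments")
    vals = scores[lo : hi + 1]
    k = max(1, int(math.ceil(p_low / 100.0 * vals.size - _EPS)))
    return float(np.sort(vals)[:k].mean())


def score_segments(segments, per2s_scores, p_low: float, flag_segments_too: bool = False):
    """Attach aggregated confidence scores to (non-flag) deferral segments in place."""
    for seg in segments:
        if seg.contains_flag and not flag_segments_too:
            continue
        seg.score = aggregate_confidence(seg, per2s_scores, p_low)
    return segments


def select_deferrals(
    segments,
    defer_fraction: float,
    mode: str = "flags_first",
    rng: np.random.Generator | None = None,
) -> list[DeferralSegment]:
    """Choose which segments to defer.

    Modes
    -----
    ``flags_first`` : all flag segments are deferred unconditionally, then
        non-flag segments in increasing score order until the deferred time
        reaches ``defer_fraction`` of the recording (overshoot allowed).
    ``flags_not_first`` : pure increasing-score order over all segments
        (flag segments need scores too).
    ``random`` : uniformly random order over all segments (baseline);
        requires ``rng``.
    """
    if not 0.0 <= defer_fraction <= 1.0:
        raise ValueError("defer_fraction must lie in [0, 1]")
    duration = max(s.end_s for s in segments)
    target = defer_fraction * duration

    if mode == "flags_first":
        deferred = [s for s in segments if s.contains_flag]
        rest = sorted(
            (s for s in segments if not s.contains_flag),
            key=lambda s: (s.score, s.start_s),
        )
    elif mode == "flags_not_first":
        deferred = []
        rest = sorted(segments, key=lambda s: (s.score, s.start_s))
    elif mode == "random":
        if rng is None:
            raise ValueError("random mode requires an rng")
        deferred = []
        rest = [segments[i] for i in rng.permutation(len(segments))]
    else:
        raise ValueError(f"unknown deferral mode {mode!r}")

    total = sum(s.length_s for s in deferred)
    for s in rest:
        if total >= target - 1e-6:
            break
        deferred.append(s)
        total += s.length_s
    return sorted(deferred, key=lambda s: s.start_s)


def _overlap(a0: float, a1: float, intervals) -> float:
    return sum(max(0.0, min(a1, e) - max(a0, s)) for s, e in intervals)


def evaluate_with_deferral(
    events,
    flags,
    deferred,
    duration_s: float,
    mode: str = "flags_first",
) -> PatientMetrics:
    """Event-based metrics under the perfect-annotator deferral model.

    ``deferred`` is a list of :class:`DeferralSegment` or (start, end)
    tuples.  In the default mode a flag counts as human-checked only when
    fully inside deferred time; in ``any_overlap`` mode an overlap of >= 1 s with
    deferred time suffices, and a checked flag overlapping a genuine seizure
    is a human-confirmed detection.
    """
    ivs = [
        (s.start_s, s.end_s) if isinstance(s, DeferralSegment) else (s[0], s[1])
        for s in deferred
    ]
    union = _merge_intervals(ivs)

    checked, surviving = [], []
    for f in flags:
        ov = _overlap(f.start_s, f.end_s, union)
        is_checked = (
            ov >= 1.0 if mode == "any_overlap" else ov >= (f.end_s - f.start_s) - 1e-6
        )
        (checked if is_checked else surviving).append(f)

    tp = 0
    delays = []
    for ev in events:
        alg_hits = [
            f for f in surviving if f.start_s < ev.end_s and f.end_s > ev.onset_s
        ]
        human = _overlap(ev.onset_s, ev.end_s, union) >= 10.0 - _EPS
        if mode == "any_overlap" and not human:
            human = any(
                f.start_s < ev.end_s and f.end_s > ev.onset_s for f in checked
            )
        if alg_hits or human:
            tp += 1
            if alg_hits:  # delay defined only for algorithm detections
                delays.append(alg_hits[0].start_s - ev.onset_s)
    fn = len(events) - tp

    event_list = list(events)
    fp_starts = [
        f.start_s
        for f in surviving
        if not any(f.start_s < e.end_s and f.end_s > e.onset_s for e in event_list)
    ]
    fp = merge_fp_starts(fp_starts)
    return PatientMetrics(tp, fp, fn, duration_s / 86_400.0, delays)


def deferral_curve(
    patients_io: list[dict],
    fractions,
    p_low: float = 5.0,
    mode: str = "flags_first",
    seed: int | None = None,
):
    """Sweep the deferred fraction and aggregate metrics across patients.

    Parameters
    ----------
    patients_io : one dict per patient with keys ``duration_s``, ``events``,
        ``flags`` and ``scores`` (per-2-s-segment confidence or trust
        scores).
    fractions : iterable of deferred-time fractions in [0, 1].
    mode : ``flags_first``, ``flags_not_first`` (any-overlap evaluation) or
        ``random`` (baseline; requires ``seed``).

    Returns
    -------
    list of per-fraction dicts with aggregated metrics plus the number and
    mean length of merged deferred intervals per patient per 24 h.
    """
    from .metrics import aggregate_cohort

    eval_mode = "any_overlap" if mode == "flags_not_first" else "flags_first"
    prepared = []
    for p in patients_io:
        segs = build_deferral_segments(p["duration_s"], p["flags"])
        score_segments(
            segs, p["scores"], p_low, flag_segments_too=(mode != "flags_first")
        )
        prepared.append((p, segs))

    results = []
    for frac in fractions:
        per_patient, n_segs, lengths = [], [], []
        rng = np.random.default_rng(seed) if mode == "random" else None
        for p, segs in prepared:
            deferred = select_deferrals(segs, frac, mode=mode, rng=rng)
            merged = _merge_intervals([(s.start_s, s.end_s) for s in deferred])
            days = p["duration_s"] / 86_400.0
            n_segs.append(len(merged) / days)
            if merged:
                lengths.append(
                    float(np.mean([e - s for s, e in merged])) / 60.0
                )
            per_patient.append(
                evaluate_with_deferral(
                    p["events"], p["flags"], deferred, p["duration_s"], eval_mode
                )
            )
        entry = {
            "fraction": float(frac),
            "metrics": aggregate_cohort(per_patient),
            "deferred_segments_per_24h": float(np.mean(n_segs)),
            "mean_deferred_length_min": float(np.mean(lengths)) if lengths else None,
            "per_patient": per_patient,
        }
        results.append(entry)
    return results
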