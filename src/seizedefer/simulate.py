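"""Synthetic multi-patient cohorts of 2-s EEG-feature segments with seizure annotations.

Long ambulatory EEG recordings are summarised here as a grid of 2-s feature
segments with 50 % overlap (1-s hop).  Each patient carries a feature matrix
(one row per segment), a list of annotated seizure events (each with a
designated 10-s "clear ictal" sub-window), and optionally artifact bursts.

The feature model is deliberately simple: class-conditional Gaussians with
shared unit diagonal covariance.  Non-seizure segments are centred at ``m0``
(the origin), seizure segments at ``m1`` with ``|m1 - m0|`` equal to
``class_separation``, spread over the first few features.  Feature 0 acts as
an amplitude proxy and feature 1 as a frequency-change proxy, so the
clear-ictal window selection rule has something to operate on.  Artifact
bursts overwrite non-seizure segments with a distribution displaced from both
class means: partly along the class axis (so a margin classifier tends to
call them seizure, producing false positives) and partly orthogonal to it
(so they are atypical for both classes and receive low trust scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimConfig",
    "SegmentSeries",
    "PatientData",
    "generate_cohort",
    "desk_preset",
    "full_preset",
    "AMPLITUDE_FEATURE",
    "FREQ_CHANGE_FEATURE",
]

#: index of the amplitude-proxy feature
AMPLITUDE_FEATURE = 0
#: index of the frequency-change-proxy feature
FREQ_CHANGE_FEATURE = 1

# fraction of the class-axis displacement given to artifact bursts; >0.5 puts
# artifacts on the seizure side of the midpoint so they trigger false positives
_ARTIFACT_CLASS_AXIS_BIAS = 0.75
# number of features carrying the class-mean displacement
_N_DISCRIMINATIVE = 10
# number of features carrying the orthogonal artifact displacement
_N_ARTIFACT = 20


@dataclass
class SimConfig:
    """Configuration of a synthetic cohort.

    Parameters mirror the shape of a multi-day ambulatory EEG study:
    ``seizure_rate`` is the expected number of events per seizure-prone
    patient (Poisson), durations are uniform in ``seizure_duration_range``
    (seconds), and ``artifact_rate`` is the expected number of artifact
    bursts per 24 h of recording.
    """

    n_patients: int = 12
    duration_s: int = 21_600  # 6 h desk-scale default
    seizure_rate: float = 114 / 42
    seizure_duration_range: tuple[float, float] = (15.0, 75.0)
    fraction_patients_with_seizures: float = 42 / 54
    feature_dim: int = 67
    class_separation: float = 5.0
    artifact_rate: float = 10.0
    artifact_duration_s: float = 30.0
    artifact_shift: float = 6.0
    ci_amplitude_boost: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.duration_s < 600:
            raise ValueError("duration_s must be >= 600 s")
        lo, hi = self.seizure_duration_range
        if not (10.0 < lo <= hi < self.duration_s):
            raise ValueError(
                "seizure_duration_range must lie within (10, duration_s) with lo <= hi"
            )
        for name in ("seizure_rate", "artifact_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.fraction_patients_with_seizures <= 1.0:
            raise ValueError("fraction_patients_with_seizures must be in [0, 1]")
        if self.feature_dim < 2:
            raise ValueError("feature_dim must be >= 2")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        # expected seizure load; >= 50% of the recording is an unusable regime
        mean_dur = 0.5 * (lo + hi)
        if self.seizure_rate * mean_dur >= 0.5 * self.duration_s:
            raise ValueError(
                "expected seizure time >= 50% of the recording; "
                "reduce seizure_rate or durations"
            )
        if self.artifact_rate > 0:
            if self.feature_dim < _N_DISCRIMINATIVE + 2:
                raise ValueError(
                    "feature_dim too small to place artifacts orthogonally; "
                    "use artifact_rate=0 or feature_dim >= 12"
                )
            min_shift = (1.0 - _ARTIFACT_CLASS_AXIS_BIAS) * self.class_separation
            if self.artifact_shift <= min_shift:
                raise ValueError(
                    "artifact_shift must exceed "
                    f"{min_shift:.3g} (= (1-{_ARTIFACT_CLASS_AXIS_BIAS})*class_separation)"
                )


@dataclass
class SegmentSeries:
    """A time-indexed grid of 2-s feature segments at 1-s hop.

    Segment ``i`` covers ``[i, i+2)`` seconds; a recording of ``duration_s``
    seconds yields ``duration_s - 1`` segments (starts ``0 .. duration_s-2``).
    """

    features: np.ndarray  # (n_segments, feature_dim)
    hop_s: float = 1.0
    window_s: float = 2.0

    @property
    def n_segments(self) -> int:
        return self.features.shape[0]

    @property
    def starts_s(self) -> np.ndarray:
        return np.arange(self.n_segments) * self.hop_s


@dataclass
class PatientData:
    """One patient's recording: segment grid, seizure events, artifact bursts."""

    patient_id: str
    duration_s: int
    segments: SegmentSeries
    events: list  # list[SeizureEvent]
    artifacts: list[tuple[float, float]] = field(default_factory=list)


def desk_preset(**overrides) -> SimConfig:
    """Small cohort (12 patients x 6 h) that runs in seconds on one CPU."""
    return replace(SimConfig(), **overrides)


def full_preset(**overrides) -> SimConfig:
    """Cohort mirroring the study shape: 54 patients, ~4 days each, 42 with seizures."""
    cfg = SimConfig(n_patients=54, duration_s=4 * 86_400)
    return replace(cfg, **overrides)


def _class_mean(config: SimConfig) -> np.ndarray:
    k = min(_N_DISCRIMINATIVE, config.feature_dim)
    m1 = np.zeros(config.feature_dim)
    m1[:k] = config.class_separation / np.sqrt(k)
    return m1


def _artifact_direction(config: SimConfig, cohort_rng: np.random.Generator) -> np.ndarray:
    """Cohort-wide unit direction of the artifact displacement, orthogonal
    to the class axis.  Shared across patients: artifact morphology (muscle
    activity, electrode movement) looks alike on different recordings, so
    the non-seizure reference sets of a trust model fitted on other
    patients contain exemplars near a test patient's artifacts."""
    m1 = _class_mean(config)
    u = m1 / np.linalg.norm(m1) if np.linalg.norm(m1) > 0 else None
    g = cohort_rng.normal(size=config.feature_dim)
    if u is not None:
        g -= (g @ u) * u
    return g / np.linalg.norm(g)


def _artifact_mean(config: SimConfig, v: np.ndarray) -> np.ndarray:
    """Mean of the artifact feature distribution.

    Placed at 0.75 of the way from the non-seizure to the seizure mean (so
    a margin classifier trained on artifact-free data calls artifact
    segments seizure), plus an offset along the cohort's artifact direction
    sized so the distance to the nearer class mean equals
    ``artifact_shift`` — atypical for both classes.
    """
    m1 = _class_mean(config)
    beta = _ARTIFACT_CLASS_AXIS_BIAS
    h2 = config.artifact_shift**2 - ((1 - beta) * config.class_separation) ** 2
    return beta * m1 + np.sqrt(h2) * v


def _draw_events(config: SimConfig, rng: np.random.Generator):
    """Non-overlapping integer-resolution events with clear-ictal windows."""
    from .labeling import SeizureEvent

    n_events = rng.poisson(config.seizure_rate)
    lo, hi = config.seizure_duration_range
    events: list[SeizureEvent] = []
    margin = 60  # pre-event background for clear-ictal threshold estimation
    for _ in range(n_events):
        dur = int(round(rng.uniform(lo, hi)))
        dur = max(dur, 10)
        placed = False
        for _attempt in range(200):
            onset = int(rng.integers(margin, config.duration_s - dur - margin))
            if all(
                onset + dur + margin <= e.onset_s or onset >= e.end_s + margin
                for e in events
            ):
                ci = int(rng.integers(onset, onset + dur - 10 + 1))
                events.append(SeizureEvent(onset, onset + dur, ci))
                placed = True
                break
        if not placed:
            raise ValueError(
                "could not place non-overlapping seizure events; "
                "recording too short for the requested seizure load"
            )
    events.sort(key=lambda e: e.onset_s)
    return events


def _draw_artifacts(
    config: SimConfig, events, rng: np.random.Generator
) -> list[tuple[float, float]]:
    n_bursts = rng.poisson(config.artifact_rate * config.duration_s / 86_400)
    bursts: list[tuple[float, float]] = []
    dur = config.artifact_duration_s
    for _ in range(n_bursts):
        for _attempt in range(100):
            start = float(rng.integers(0, int(config.duration_s - dur)))
            end = start + dur
            if any(start < e.end_s and end > e.onset_s for e in events):
                continue
            if any(start < b1 and end > b0 for b0, b1 in bursts):
                continue
            bursts.append((start, end))
            break
    bursts.sort()
    return bursts


def _patient(
    config: SimConfig, pid: str, has_seizures: bool, rng, artifact_direction
) -> PatientData:
    from .labeling import derive_labels

    events = _draw_events(config, rng) if has_seizures else []
    artifacts = _draw_artifacts(config, events, rng) if config.artifact_rate > 0 else []

    n_seg = config.duration_s - 1
    X = rng.normal(size=(n_seg, config.feature_dim))
    fs = derive_labels(events, "fs", n_seg)
    X[fs == 1] += _class_mean(config)

    for ev in events:
        # 9 fully-contained 2-s segments in the 10-s clear-ictal window
        ci0 = int(ev.clear_ictal_start_s)
        X[ci0 : ci0 + 9, AMPLITUDE_FEATURE] += config.ci_amplitude_boost

    if artifacts:
        art_mean = _artifact_mean(config, artifact_direction)
        starts = np.arange(n_seg)
        art_mask = np.zeros(n_seg, dtype=bool)
        for b0, b1 in artifacts:
            # segments overlapping the burst by >= 1 s
            ov = np.minimum(starts + 2, b1) - np.maximum(starts, b0)
            art_mask |= ov >= 1.0
        art_mask &= fs == 0
        X[art_mask] = rng.normal(size=(int(art_mask.sum()), config.feature_dim))
        X[art_mask] += art_mean

    return PatientData(
        patient_id=pid,
        duration_s=config.duration_s,
        segments=SegmentSeries(X),
        events=events,
        artifacts=artifacts,
    )


def generate_cohort(config: SimConfig) -> list[PatientData]:
    """Draw a full cohort; deterministic given ``config.seed``.

    The first ``round(fraction_patients_with_seizures * n_patients)`` patients
    (after a seeded shuffle of ids) are seizure-prone with event counts
    ~ Poisson(``seizure_rate``); the rest have no seizures.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(ss)
    children = ss.spawn(config.n_patients)

    n_seiz = int(round(config.fraction_patients_with_seizures * config.n_patients))
    order = cohort_rng.permutation(config.n_patients)
    seizure_prone = set(order[:n_seiz].tolist())
    artifact_direction = _artifact_direction(config, cohort_rng)

    cohort = []
    for i in range(config.n_patients):
        rng = np.random.default_rng(children[i])
        cohort.append(
            _patient(config, f"p{i:02d}", i in seizure_prone, rng, artifact_direction)
        )
    return cohort
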