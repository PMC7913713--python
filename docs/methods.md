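# Methods

This note records the model choices behind `seizedefer`, the defaults and
their rationale, what the synthetic data generator does and does not
emulate, and the numerical conventions that matter for reproducing
results.

## Pipeline overview

Recordings are represented as a grid of 2-s feature segments with 50 %
overlap (1-s hop): a recording of `T` seconds yields `T − 1` segments with
integer starts. Two label regimes are derived from the seizure
annotations:

* **FS (full seizure)** — a segment is positive iff it overlaps an
  annotated event by ≥ 1 s. The overlap threshold is a design choice (the
  natural majority rule for a 2-s window); annotations do not specify how
  partial overlaps are labelled.
* **CI (clear ictal)** — positive iff fully contained in the event's
  designated 10-s clear-ictal window; on the integer grid each event
  contributes exactly 9 CI-positive segments. Containment guarantees pure
  ictal training segments.

The clear-ictal window of an event is the first 10-s stretch whose mean
amplitude-proxy exceeds the pre-event background mean by a configurable
factor (default 2 background SDs); failing that, the first stretch whose
frequency-change proxy exceeds its threshold (default 2 SDs); failing
that, the event onset. Only the priority order is prescribed by the
underlying procedure; both thresholds are package defaults.

## Classifier and confidences

The per-segment detector is a standard-scaled SVM with balanced class
weights, trained across patients and never on the patient it scores. The
default kernel is **linear**. Rationale: with the Gaussian feature model a
radial-basis kernel is local — segments far from the training manifold
(artifacts) fall back to the majority class and never produce false flags,
which removes the very failure mode the post-processing exists to fix. A
linear margin extrapolates the way high-dimensional EEG classifiers do in
practice, so artifact segments on the seizure side of the margin are
predicted seizure. The kernel remains a constructor argument.

Temperature scaling `p_a = 1/(1+exp(−a·d))` maps margin distances to
probabilities. Because `p_a(0) = 0.5` for every `a > 0`, the predicted
class and the confidence ranking `|p_a − 0.5|` are invariant to `a`; the
cross-validation code exploits this (the LTF mask is identical across the
temperature grid, so per-`q` metrics are computed once and the grid argmax
returns the first — smallest — grid temperature). The default temperature
grid is logarithmic over [1e−2, 1e2].

## Trust model

Features are projected to `min(20, d)` principal components (20 is the
conventional choice for this score and is not optimised); reference sets
are the *full* projected classes of the training subsample — no
density-based pruning step, which would add two hyper-parameters. The
score is the ratio of the distance to the nearest reference of the other
class over the distance to the nearest reference of the predicted class.
Conventions: exact duplicates of a predicted-class reference score +inf if
the other class is at positive distance, 1 if both distances vanish;
nearest-neighbour ties are immaterial for the score (equal distances) and
resolved toward the lowest reference index. Nearest neighbours are found
by exact brute force (BLAS-backed); tree indices lose to brute force at 20
dimensions.

The subsample per patient contains every seizure-labelled segment plus 100
one-minute non-seizure windows (30 non-overlapping 2-s segments each)
drawn without replacement from a 15-min-spaced candidate grid; when the
grid offers fewer than 100 candidates the spacing drops to 5 min, and if
even that grid is short all its windows are taken. Whether the projection
is fitted on the subsample or on all training features is an open choice;
the implementation fits on the subsample (the object the model actually
sees).

Classifier training uses the same windowed subsampling with fewer windows
(default 30/patient, for tractable SVM fits) and **excludes windows
overlapping known artifact bursts** — routine training-set artifact
rejection, mirroring the fact that upstream seizure classifiers are
trained on curated data. Trust reference sets deliberately keep artifact
windows: randomly drawn reference windows containing artifacts are what
allow the score to recognise artifactual predictions as atypical.

## Flags, low-trust filtering

A sliding block of 10 consecutive segments is flagged iff ≥ 8 predictions
are seizure (strict reading of "more than 7 of 10"); within a run of
consecutive flagged blocks only the first is retained. The block spans
11 s geometrically (10 overlapping 2-s segments); flags store
`[start, start+11]` and are reported nominally as 10-s flags.

LTF marks the `⌊q·n⌋` lowest-scored segments per patient (ties resolved
toward earlier time; the product `q·n` is computed with a 1e−9 guard
against binary-float artifacts such as `0.29·100 = 28.999…`). Per block:
with fewer than 5 marked predictions, flag iff the mean of the unmarked
ones exceeds 0.7; otherwise flag iff the mean of the 5 highest-scored
predictions of the block (marked or not, ties toward earlier time)
exceeds 0.7. With `q = 0` this reduces exactly to the 8-of-10 rule
(verified exhaustively over all 2^10 blocks).

## Deferral

Every flag is centred in a 300-s segment (shifted inward at recording
boundaries, preserving length); flag segments closer than 300 s are
merged; remaining gaps are tiled left-to-right with 300-s segments. A
final gap remainder shorter than 300 s is absorbed into the previous tile
of the same gap, so segments shorter than 300 s occur only at recording
boundaries; slivers shorter than one 2-s segment are absorbed into their
neighbour (they cannot carry a score). Each non-flag segment's score is
the mean of its lowest `p_low` percent of 2-s scores
(`k = max(1, ⌈p_low/100·n⌉)`; default `p_low = 5`).

Selection modes: `flags_first` defers all flag segments unconditionally,
then non-flag segments in increasing score order until the deferred time
reaches the requested fraction of the recording (greedy, overshoot
allowed; the quota is a fraction of recording *time* and flag segments
count toward it). `flags_not_first` uses pure score order;
`random` is the Monte-Carlo baseline.

Evaluation assumes a perfect annotator. A flag fully inside deferred time
is human-checked (false flags vanish); a seizure counts as detected iff
≥ 10 s of it lies in deferred time or a surviving algorithm flag overlaps
it — a seizure split so that both parts hold < 10 s stays undetected. In
the alternative mode a flag overlapping deferred time by ≥ 1 s counts as
fully checked, and a checked flag on a genuine seizure is a
human-confirmed detection. Detection delay is defined only for
algorithm-flag detections; human-detected seizures are excluded from
delay averages. Merging of adjacent deferred segments (for the
count/length statistics) happens after selection and never changes the
deferred time.

Two structural identities follow and are asserted in the test suite:
`flags_first` yields FDR = 0 at every fraction, and DS is non-decreasing
in the fraction for a fixed flag set (added deferred time can only turn
misses into detections).

## Metrics and testing

Event-based: a flag overlapping `[onset, end)` detects the event (many
flags, one TP); unmatched flags are FPs with starts within 10 s chained
into one (start-to-start anchoring, chosen for determinism); FDR is FPs
per 24 h. DS, PPV, F1 and delay are averaged over patients with seizures
— the published convention states this for PPV/F1 and it is extended to
DS by necessity (undefined denominator); FDR averages over all patients.
Paired comparisons use the one-sided Wilcoxon signed-rank test (exact
null for n ≤ 25 without ties/zeros, else normal approximation with tie
correction; identical vectors return p = 0.5 by convention), significance
at 0.05. Confidence/trust ranking agreement is the Kendall rank
correlation per patient, then averaged.

## Cross-validation

Folds are rejection-sampled random partitions under per-fold bounds on
the number of 10-s seizure segments and recording days. The reference
bounds describe the per-fold share of a 54-patient, 6-fold clinical
cohort and are rescaled to the cohort's totals and fold count; small
synthetic cohorts (12 patients with lumpy Poisson seizure loads) cannot
meet clinical tightness, so callers widen the band with a `relax` factor
(the pipeline default is 4).

Nested CV for trust-LTF: for each test fold the remaining folds form two
roughly equal inner cohorts (consecutive fold groups; the last fold split
in half, balancing seizure-segment totals greedily — the split rule is
otherwise unspecified); 2-fold inner CV selects the patient-averaged-F1-
optimal `q` on each half (ties toward the smallest `q`; zero-seizure
validation patients are excluded from the objective), and the test fold
uses the mean of the two optima, applied as-is even if off-grid. Each
test patient is finally scored with a trust model fitted on all other
patients. SVM-confidence LTF uses leave-one-patient-out selection of
`(a, q)`, with a raw-distance mode. The default `q` grid is 0–20 % in 1 %
steps.

## Synthetic cohorts

The generator emulates the study conditions, not EEG waveforms. Defaults
(desk preset): 12 patients × 6 h; the full preset mirrors the clinical
cohort shape (54 patients × 4 days, 42 of 54 with seizures). Per
seizure-prone patient the event count is Poisson with mean 114/42 ≈ 2.7;
event durations are uniform on [15, 75] s (mean 45 s ≈ 4.3 10-s segments
per event, matching the clinical ratio of ~490 segments to 114 events);
events carry a random integer clear-ictal start with an amplified
amplitude proxy (+3 SD on feature 0).

Features are class-conditional Gaussians with unit diagonal covariance in
67 dimensions; the seizure mean is displaced by `class_separation`
(default 5, per-segment Bayes error ≈ 0.6 % along the class axis) spread
over the first 10 features (feature 0 = amplitude proxy, feature 1 =
frequency-change proxy). Artifact bursts (default 10 per 24 h, 30 s long,
placed off seizures) overwrite segment features with a Gaussian centred
at 0.75 of the way to the seizure mean plus an offset along a single
cohort-wide direction orthogonal to the class axis, sized so the distance
to the nearer class mean equals `artifact_shift` (default 6). The
placement realises both halves of the premise: a linear margin trained on
artifact-free data predicts seizure on artifact segments (false flags),
while trust models fitted on other patients — whose reference windows
contain artifacts of the same morphology — score those predictions below
1. The cohort-wide direction encodes that artifact morphology (muscle,
electrode movement) recurs across patients; it is what makes
cross-patient trust references informative.

What the generator does **not** emulate: raw waveforms and spectra,
temporal correlation between overlapping segments (noise is independent
per segment), patient-specific seizure morphology, non-stationary
background, heterogeneous artifact families, and variable recording
lengths within a cohort. Passing tests therefore demonstrate the
correctness and internal logic of the post-processing — the exact
identities, the direction of the filtering effect under the stated
artifact mechanism, the deferral trade-off — not clinical performance
levels; headline clinical numbers are not reproducible without the
private recordings.

## Problem sizes and determinism

The test suite and the acceptance script run on purpose-sized cohorts
(2–8 patients, 1–3 h recordings; 20-cohort sweeps for the monotonicity
property; 50 draws for the random-deferral baseline) — small enough for a
single CPU in minutes, large enough that every assertion is exercised on
real flags and real artifacts (asserted where it matters). All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` substreams (one per patient), so cohorts,
subsamples, fold plans and result bundles are bit-reproducible; result
bundles embed the config hash and seed.
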