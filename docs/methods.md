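# Methods

`gazekit` implements a gaze-based usability analysis for expert
interaction with an AI decision-support interface for radiograph reading
(the motivating setting is dentists inspecting bitewing x-rays with an
optional caries-detection overlay). The pipeline turns raw remote-tracker
samples into fixation events, bins attention into interface regions,
counts scanpath transitions, segments sessions by the AI overlay's on/off
state, and compares the two viewing conditions nonparametrically.

## Event detection (I-VT)

Gaze is sampled nominally at 60 Hz as monocular, binocular-interpolated
screen coordinates with a per-sample validity score in [0, 1]. Fixations
are detected with a velocity-threshold classifier:

- Angular velocity between consecutive valid samples is the visual angle
  of the displacement divided by the inter-sample interval. The visual
  angle of a chord of `d` mm at viewing distance `D` mm is
  `2·arctan(d / 2D)`; pixel offsets convert to mm with per-axis factors
  from the physical screen size.
- Intervals slower than the threshold (default **30 deg/s**) are
  fixation intervals; maximal runs of fixation intervals become
  candidate fixations; candidates spanning less than the minimum
  duration (default **60 ms**) are discarded.
- Centroid = unweighted mean of member sample positions; duration =
  last member time − first member time.

Assumptions and numerical choices:

- **Two-point differencing, no smoothing.** At 60 Hz a multi-sample
  smoothing window would blur saccades that occupy one or two frames.
- **Gap handling.** Samples with quality 0 are dropped before
  classification. An interval whose extra gap (beyond the nominal frame
  interval) is at most `max_gap_bridge = 25 ms` — i.e. a single dropped
  frame — is still classified; longer dropouts are unclassifiable and
  terminate the run.
- **Boundary.** Velocity exactly at the threshold is saccade-labelled
  (strict `<`); the tie-break is arbitrary but must be fixed for
  determinism.
- **No post-hoc merging** of adjacent fixations: merging would change
  fixation counts, which are a primary outcome metric.
- Saccade-level metrics (amplitude, peak velocity) are deliberately not
  computed: 60 Hz cannot resolve saccade dynamics.

The physical screen size is not always known; the default geometry is a
24-inch 16:9 panel (531 × 299 mm) at 1920 × 1080 px viewed from 700 mm.
**If your monitor differs, set `ViewingGeometry` accordingly** — every
angular quantity scales with it. At the default geometry 1 deg ≈ 44 px.

## Quality control

Recordings are excluded in a fixed order, each tallied once under the
first rule that caught it:

1. **Duplicate first views** — if a participant saw the same image twice
   (identified by participant × image with two recordings), the earlier
   one (lower recording index) is dropped: an accidental first view is
   too short for a proper inspection.
2. **Signal quality** — mean per-sample validity strictly below 0.60
   ("valid signal over total signal"; sample-weighted, since the tracker
   emits on a regular clock). A recording at exactly 0.60 is kept.
3. **Stimulus-presentation errors** — flagged externally per
   participant × image.

The ledger lists every input recording exactly once, so statuses always
sum to the input count, and the outcome is invariant to input order.

## AOI metrics

To absorb small calibration offsets, every AOI rectangle is expanded by
the pixel equivalent of **3 degrees of visual angle** per side (rounded
per axis; 133 px at the default geometry), then clipped to the screen.
Rectangles are half-open so adjacent regions tile without double hits; a
fixation whose centroid falls in several (overlapping, padded) AOIs
counts fully in each — the both-hit rule. Membership is decided by the
centroid, not a per-sample majority.

Per-recording metrics: task time (full recording span, no trimming),
total fixation duration on the radiograph and on the UI aggregate (every
non-radiograph AOI, browser chrome included; configurable via
`ui_roles`), fixation counts per group, mean fixation duration, fixation
frequency (count / task time), and group dwell as a percentage of task
time. A recording with zero fixations reports its mean duration as NaN —
missing, never imputed — and the statistics layer drops it.

## Transition analysis

A transition is a pair of consecutive fixations whose AOI memberships
differ; within-AOI pairs are excluded, so the matrix diagonal is zero by
construction and asymmetry is preserved. Two genuinely open choices are
exposed as configuration, with these defaults:

- **Outside fixations break chains** (A → outside → B adds nothing):
  counting across an outside event would manufacture transitions that
  never happened at consecutive-fixation resolution.
- **Overlap handling** is the cross-product of memberships (consistent
  with the both-hit rule), switchable to a priority mode where the
  smallest-area AOI wins.

Per-recording matrices are pooled per condition by element-wise sum.

## Toggle intervals

The AI overlay starts off; an alternating ON/OFF event log segments
`[0, task_end]` into contiguous state intervals (half-open, so a
fixation onset on a boundary belongs to the interval starting there). A
fixation spanning a toggle belongs wholly to its onset interval —
splitting would create sub-minimum fragments. Summaries per recording:
activation count, total and percentage ON time, first-activation latency
(absolute and as % of task), per-interval fixation counts and median
durations, and per-state aggregates (fixation count, UI fixation count,
mean/median duration, frequency). Because sessions repeat within
participants, activation averages can be taken per recording or per
participant; both groupings are available.

## Condition statistics

Metrics are summarized as median and IQR (linear interpolation between
order statistics — the convention must be fixed, this is the most common
default) and compared with the two-sided Wilcoxon rank-sum test at
α = 0.05. The exact null distribution is used for pooled samples of at
most 16 tie-free observations; otherwise the normal approximation with
tie and continuity corrections (via `scipy.stats.mannwhitneyu`; the test
suite checks it against an independent enumeration over rank
assignments). If the pooled data carry no ranking information (all
values identical) the p-value is 1 by convention.

The default unit of analysis is the **recording**, matching group sizes
like 170/179 that arise from dataset-level inclusion; this ignores the
repeated-measures structure within participants, which is statistically
generous — a per-participant-mean grouping is provided as the
conservative alternative. No multiple-testing correction is applied by
default (eight related outcome metrics at α = 0.05); a Holm step-down
option exists. A mixed-effects re-analysis is out of scope.

## Synthetic data generator

The generator produces the study conditions every test runs under:

- **Scanpath**: a first-order Markov chain over the seven interface
  AOIs chooses each fixation's region (radiograph-dominant; the
  AI-condition preset adds excursions to the findings list and tooth
  map). Fixation centres are uniform within a 10 %-inset of the AOI;
  durations are lognormal with configured median **313.27 ms** (AI
  preset) / **317.29 ms** (no-AI preset) and log-sd 0.30, chosen so the
  generated IQR brackets the ~[240, 370] ms regime of per-recording
  averages the analysis targets. Durations are resampled below 75 ms so
  every generated fixation is detectable.
- **Saccades** are 0–3 linearly interpolated bridging samples, the
  count chosen from the inter-centre distance so each inter-sample jump
  is ≈1 deg or more (≥ ~60 deg/s), and consecutive centres are kept at
  least 1 deg apart. 60 Hz cannot represent realistic saccade dynamics;
  what the analysis needs is clean I-VT separability, which this
  guarantees.
- **Tracker noise** is an AR(1) Gaussian process per axis (marginal
  sigma, default 0.1 deg; lag-1 correlation 0.95). Remote-tracker output
  is temporally filtered, so its noise is strongly correlated; white
  noise of equal sigma would produce inter-sample velocity spikes above
  30 deg/s at rates no real tracker shows and would make exact
  event-count recovery impossible at any useful noise level.
- **Dropouts**: each sample is invalid with probability
  `dropout_rate` (default 0.02). Degraded recordings for QC testing use
  dropout 0.42–0.55, putting mean quality safely below the 0.60 cut.
- **Toggles**: the first activation lands at a Beta-distributed
  fraction of task time (mean 0.4357, sd 0.3235 — a U-shaped Beta);
  activations count 1 + Poisson(7.4); the ON budget is a Beta fraction
  of the *remaining* time with mean `0.2431 / (1 − 0.4357)`, so the
  expected overall ON share is exactly 24.31 % by independence of the
  two draws. ON stretches and OFF gaps are Dirichlet splits.
- **Study**: 22 participants × 20 images by default (pool of 140
  images, ~1:1 condition split within participant), task times lognormal
  with medians 109.19 s (AI) / 87.1 s (no AI), plus built-in defects —
  5 duplicate first views, an 80/440 low-quality fraction, 11 stimulus
  errors — reproducing a 445 → 349 inclusion funnel at full scale;
  defect counts scale proportionally for smaller studies.

Everything is driven by a single `numpy.random.Generator` (PCG64), so a
fixed seed reproduces every artifact bit-exactly across runs and
platforms, and ground truth records each generated fixation for
closed-loop tests.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: image-content-driven gaze (lesion
salience, tooth-by-tooth scanning), inter-participant strategy
differences beyond what the shared Markov chain captures, slow drift or
calibration decay over a session, blinks with their characteristic
pre/post artifacts, smooth pursuit, and any dependence of toggling on
what the AI actually shows. Calibration targets (dwell medians,
ON-fraction) are generator settings, not claims about any particular
dataset.

## Problem sizes used in the checks

The acceptance checks run the classifier-recovery test on 100 × 60 s
recordings at 0.2 deg noise, the transition oracle on 1 000 random
sequences of up to 300 fixations, rank-sum calibration on 1 000 null and
200 shifted replicates at n = 170/179, interval conservation on 500
random toggle logs, and the closed-loop study at the full 22 × 20
(445-recording) scale. `scripts/acceptance.py` recomputes the same
quantities from scratch for any seed.

## Known limitations

- The exact event counts of proprietary tracker software cannot be
  reproduced: vendor I-VT variants apply unreported smoothing, gap and
  merge rules. Parameters here are documented and fixed instead.
- Physical screen size defaults to a 24-inch panel and must be set by
  the user for faithful angular units.
- Recording-level inference ignores within-participant clustering (see
  above).
- Pupillometry, usability questionnaires, diagnostic-performance and
  lesion-level attention analyses are out of scope.
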