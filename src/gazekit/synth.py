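"""Seeded synthetic gaze recordings, toggle logs and full studies.

The generator emulates the statistical structure the analysis assumes:
60 Hz monocular (binocular-interpolated) gaze with quality dropouts,
fixation/saccade alternation with lognormal fixation durations (median
~313-317 ms depending on condition), AOI-structured dwell driven by a
first-order Markov chain over the interface regions (radiograph-dominant
with excursions to UI elements), and AI-toggle behaviour with the first
activation near mid-task and the overlay on for ~25% of task time.

Scanpaths are built fixation-by-fixation: each fixation holds an
AOI-conditioned centre, saccades are 0-3 bridging samples placed so every
inter-sample jump stays well above the 30 deg/s classification threshold
(guaranteeing I-VT separability at 60 Hz, where realistic saccade
dynamics cannot be represented anyway). Tracker noise is an AR(1)
Gaussian process — marginal sigma as configured, lag-1 correlation
``noise_ar`` — because remote-tracker output is temporally filtered;
white noise of the same sigma would produce spurious supra-threshold
velocity spikes that no real tracker shows.

Everything is driven by ``numpy.random.Generator`` (PCG64), so any fixed
seed reproduces every artifact bit-exactly, and ground truth records each
generated event for closed-loop testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.signal import lfilter

from .errors import ValidationError
from .geometry import ViewingGeometry, px_per_deg
from .io import (
    AOI,
    AOILayout,
    AOIRole,
    Condition,
    GazeRecording,
    ToggleEvent,
    ToggleState,
    validate_toggle_sequence,
)

__all__ = [
    "ScanpathModel",
    "ToggleModel",
    "TrueFixation",
    "GroundTruth",
    "StudyData",
    "default_layout",
    "ai_scanpath_model",
    "no_ai_scanpath_model",
    "default_toggle_model",
    "generate_recording",
    "generate_toggles",
    "generate_study",
]


def default_layout() -> AOILayout:
    """Seven-AOI layout of the reading interface on a 1920x1080 screen.

    The radiograph sits in the centre; AI-related panels (findings list,
    tooth map, overlay toggle) on the right, image tools and case info on
    the left, browser chrome on top. In the no-AI condition the right-side
    panels are empty but the regions still exist on screen.
    """
    return AOILayout(
        (
            AOI("browser", AOIRole.BROWSER, (0, 0, 1920, 90)),
            AOI("tools", AOIRole.TOOLS, (40, 140, 300, 640)),
            AOI("info", AOIRole.INFO, (40, 680, 300, 1040)),
            AOI("bitewing", AOIRole.BITEWING, (380, 230, 1480, 830)),
            AOI("ai_findings", AOIRole.AI_FINDINGS, (1520, 140, 1900, 560)),
            AOI("tooth_map", AOIRole.TOOTH_MAP, (1520, 600, 1900, 930)),
            AOI("toggle", AOIRole.TOGGLE, (1530, 960, 1730, 1040)),
        )
    )


_AI_MARKOV: dict[str, dict[str, float]] = {
    "bitewing": {"bitewing": 0.88, "ai_findings": 0.045, "tooth_map": 0.03, "tools": 0.015, "info": 0.01, "browser": 0.005, "toggle": 0.015},
    "ai_findings": {"bitewing": 0.70, "ai_findings": 0.22, "tooth_map": 0.05, "tools": 0.01, "info": 0.01, "browser": 0.005, "toggle": 0.005},
    "tooth_map": {"bitewing": 0.70, "ai_findings": 0.08, "tooth_map": 0.18, "tools": 0.01, "info": 0.01, "browser": 0.01, "toggle": 0.01},
    "tools": {"bitewing": 0.80, "ai_findings": 0.05, "tooth_map": 0.02, "tools": 0.08, "info": 0.03, "browser": 0.01, "toggle": 0.01},
    "info": {"bitewing": 0.80, "ai_findings": 0.04, "tooth_map": 0.02, "tools": 0.05, "info": 0.06, "browser": 0.02, "toggle": 0.01},
    "browser": {"bitewing": 0.75, "ai_findings": 0.05, "tooth_map": 0.03, "tools": 0.05, "info": 0.05, "browser": 0.05, "toggle": 0.02},
    "toggle": {"bitewing": 0.85, "ai_findings": 0.07, "tooth_map": 0.03, "tools": 0.01, "info": 0.01, "browser": 0.01, "toggle": 0.02},
}

_NO_AI_MARKOV: dict[str, dict[str, float]] = {
    "bitewing": {"bitewing": 0.935, "ai_findings": 0.01, "tooth_map": 0.005, "tools": 0.02, "info": 0.015, "browser": 0.01, "toggle": 0.005},
    "ai_findings": {"bitewing": 0.85, "ai_findings": 0.05, "tooth_map": 0.02, "tools": 0.03, "info": 0.03, "browser": 0.015, "toggle": 0.005},
    "tooth_map": {"bitewing": 0.85, "ai_findings": 0.03, "tooth_map": 0.05, "tools": 0.03, "info": 0.02, "browser": 0.015, "toggle": 0.005},
    "tools": {"bitewing": 0.82, "ai_findings": 0.01, "tooth_map": 0.01, "tools": 0.09, "info": 0.04, "browser": 0.02, "toggle": 0.01},
    "info": {"bitewing": 0.82, "ai_findings": 0.01, "tooth_map": 0.01, "tools": 0.05, "info": 0.07, "browser": 0.03, "toggle": 0.01},
    "browser": {"bitewing": 0.78, "ai_findings": 0.02, "tooth_map": 0.01, "tools": 0.05, "info": 0.05, "browser": 0.07, "toggle": 0.02},
    "toggle": {"bitewing": 0.87, "ai_findings": 0.02, "tooth_map": 0.02, "tools": 0.03, "info": 0.02, "browser": 0.02, "toggle": 0.02},
}


@dataclass(frozen=True)
class ScanpathModel:
    """Generative model of one recording's scanpath.

    fix_duration_median / fix_duration_log_sd
        Lognormal fixation durations (ms). The log-sd 0.30 makes the
        generated interquartile range span roughly [250, 380] ms around a
        ~315 ms median, matching the regime the analysis targets.
    within_aoi_inset
        Fraction of each AOI's width/height kept as a margin when placing
        fixation centres, so noisy centroids stay inside the region.
    min_separation_deg
        Minimum distance between consecutive fixation centres; keeps every
        saccade supra-threshold for the I-VT classifier.
    sample_noise_deg / noise_ar
        Marginal sigma (deg) and lag-1 correlation of the AR(1) tracker
        noise added to each sample.
    dropout_rate
        Probability that a sample is invalid (quality 0).
    """

    layout: AOILayout = field(default_factory=default_layout)
    dwell_markov: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _AI_MARKOV
    )
    fix_duration_median: float = 313.27
    fix_duration_log_sd: float = 0.30
    within_aoi_inset: float = 0.10
    min_separation_deg: float = 1.0
    sample_noise_deg: float = 0.10
    noise_ar: float = 0.95
    dropout_rate: float = 0.02
    rate: float = 60.0
    start_aoi: str = "bitewing"
    geometry: ViewingGeometry = field(default_factory=ViewingGeometry)

    def __post_init__(self) -> None:
        if len(self.layout) == 0:
            raise ValidationError("scanpath model needs a non-empty AOI layout")
        names = set(self.layout.names)
        for src, row in self.dwell_markov.items():
            if src not in names:
                raise ValidationError(f"Markov row for unknown AOI {src!r}")
            if set(row) - names:
                raise ValidationError(f"Markov row {src!r} references unknown AOIs")
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"Markov row {src!r} sums to {total}, not 1")
            if any(p < 0 for p in row.values()):
                raise ValidationError(f"Markov row {src!r} has negative probabilities")
        if missing := names - set(self.dwell_markov):
            raise ValidationError(f"Markov chain missing rows for {sorted(missing)}")
        if not self.fix_duration_median > 0 or not self.fix_duration_log_sd > 0:
            raise ValidationError("fixation duration distribution needs positive scale")
        if not (0 <= self.dropout_rate < 1):
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if not (0 <= self.noise_ar < 1):
            raise ValidationError("noise_ar must lie in [0, 1)")
        if self.sample_noise_deg < 0:
            raise ValidationError("sample_noise_deg must be non-negative")
        if not self.rate > 0:
            raise ValidationError("sampling rate must be positive")
        if self.start_aoi not in names:
            raise ValidationError(f"start_aoi {self.start_aoi!r} not in layout")


@dataclass(frozen=True)
class ToggleModel:
    """Generative model of AI-overlay toggling within one recording.

    The first activation lands at a Beta-distributed fraction of task time
    (mean 0.4357, sd 0.3235). The total ON budget is a Beta fraction of
    the *remaining* time with mean ``on_frac_target / (1 - first_on_mean)``
    so that the expected overall ON share equals ``on_frac_target``
    exactly. Activations beyond the first follow a Poisson count
    (``1 + Poisson(n_activations_rate)``); ON stretches and the OFF gaps
    between them are Dirichlet splits of their respective budgets.
    """

    p_use: float = 1.0
    first_on_mean: float = 0.4357
    first_on_sd: float = 0.3235
    n_activations_rate: float = 7.4
    on_frac_target: float = 0.2431
    on_frac_concentration: float = 15.0

    def __post_init__(self) -> None:
        for name in ("p_use", "first_on_mean", "on_frac_target"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValidationError(f"ToggleModel.{name} must lie in [0, 1]")
        if not self.first_on_sd > 0:
            raise ValidationError("first_on_sd must be positive")
        if self.n_activations_rate < 0:
            raise ValidationError("n_activations_rate must be non-negative")
        if not self.on_frac_target < 1 - 1e-9 or not self.first_on_mean < 1 - 1e-9:
            raise ValidationError("fractions must be strictly below 1")
        if self.on_frac_target / (1 - self.first_on_mean) >= 1:
            raise ValidationError(
                "on_frac_target infeasible given first_on_mean (needs >100% of remaining time)"
            )

    def _first_on_beta(self) -> tuple[float, float]:
        m, v = self.first_on_mean, self.first_on_sd**2
        nu = m * (1 - m) / v - 1
        if nu <= 0:
            raise ValidationError("first_on_sd too large for a Beta distribution")
        return m * nu, (1 - m) * nu

    def _on_frac_beta(self) -> tuple[float, float]:
        m = self.on_frac_target / (1 - self.first_on_mean)
        nu = self.on_frac_concentration
        return m * nu, (1 - m) * nu


@dataclass(frozen=True)
class TrueFixation:
    """Ground-truth fixation as generated (times on the sample grid)."""

    onset: float
    offset: float
    aoi: str
    cx: float
    cy: float
    n_samples: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator decided, for closed-loop verification."""

    fixations: tuple[TrueFixation, ...]
    seed: int | None
    task_time_ms: float


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _inset_rect(rect, inset_frac):
    x0, y0, x1, y1 = rect
    mx = (x1 - x0) * inset_frac
    my = (y1 - y0) * inset_frac
    return x0 + mx, y0 + my, x1 - mx, y1 - my


def _draw_center(rng, rect, inset_frac, prev, min_sep_px):
    x0, y0, x1, y1 = _inset_rect(rect, inset_frac)
    for _ in range(50):
        cx = rng.uniform(x0, x1)
        cy = rng.uniform(y0, y1)
        if prev is None or math.hypot(cx - prev[0], cy - prev[1]) >= min_sep_px:
            return cx, cy
    # tiny AOI: push the candidate away from the previous centre, then clip
    dx, dy = cx - prev[0], cy - prev[1]
    norm = math.hypot(dx, dy) or 1.0
    cx = min(max(prev[0] + dx / norm * min_sep_px, x0), x1)
    cy = min(max(prev[1] + dy / norm * min_sep_px, y0), y1)
    return cx, cy


def generate_recording(
    model: ScanpathModel,
    task_time_ms: float,
    seed,
    participant_id: str = "P00",
    image_id: str = "I000",
    condition: Condition | str = Condition.AI,
    recording_index: int = 0,
) -> tuple[GazeRecording, GroundTruth]:
    """Generate one recording and its ground truth.

    ``seed`` may be an int (bit-exact reproducibility) or an existing
    ``numpy.random.Generator`` (sequential use inside a study).
    """
    if not task_time_ms > 0:
        raise ValidationError("task_time_ms must be positive")
    rng = _as_rng(seed)
    geom = model.geometry
    dt = 1000.0 / model.rate
    n_total = int(round(task_time_ms / dt)) + 1

    sx, sy = px_per_deg(geom)
    scale = 0.5 * (sx + sy)  # px per degree, isotropic approximation
    min_sep_px = model.min_separation_deg * scale
    mu = math.log(model.fix_duration_median)

    labels = list(model.layout.names)
    rows = {
        src: np.array([model.dwell_markov[src].get(dst, 0.0) for dst in labels])
        for src in labels
    }
    rects = {a.name: a.rect for a in model.layout}

    base_x = np.empty(n_total)
    base_y = np.empty(n_total)
    truths: list[TrueFixation] = []
    i = 0
    prev_center: tuple[float, float] | None = None
    current = model.start_aoi
    while i < n_total:
        if prev_center is not None:
            current = labels[rng.choice(len(labels), p=rows[current])]
        cx, cy = _draw_center(rng, rects[current], model.within_aoi_inset, prev_center, min_sep_px)

        if prev_center is None:
            n_bridge = 0
        else:
            dist_deg = math.hypot(cx - prev_center[0], cy - prev_center[1]) / scale
            n_bridge = int(min(3, max(0, round(dist_deg / 2.0) - 1)))

        dur = float(rng.lognormal(mean=mu, sigma=model.fix_duration_log_sd))
        while dur < 75.0:  # keep every generated fixation detectable (>60 ms)
            dur = float(rng.lognormal(mean=mu, sigma=model.fix_duration_log_sd))
        n_samp = max(5, int(round(dur / dt)) + 1)

        if i + n_bridge + n_samp > n_total:
            n_samp = n_total - i - n_bridge
            if n_samp < 6:
                break

        if n_bridge and prev_center is not None:
            frac = np.arange(1, n_bridge + 1) / (n_bridge + 1)
            base_x[i : i + n_bridge] = prev_center[0] + frac * (cx - prev_center[0])
            base_y[i : i + n_bridge] = prev_center[1] + frac * (cy - prev_center[1])
        start = i + n_bridge
        base_x[start : start + n_samp] = cx
        base_y[start : start + n_samp] = cy
        truths.append(
            TrueFixation(
                onset=start * dt,
                offset=(start + n_samp - 1) * dt,
                aoi=current,
                cx=cx,
                cy=cy,
                n_samples=n_samp,
            )
        )
        i = start + n_samp
        prev_center = (cx, cy)

    n_used = i
    if n_used < 6 or not truths:
        raise ValidationError("task_time_ms too short to fit a single fixation")
    t = np.arange(n_used) * dt

    if model.sample_noise_deg > 0:
        rho = model.noise_ar
        eps = rng.standard_normal((2, n_used)) * model.sample_noise_deg * math.sqrt(1 - rho**2)
        noise = lfilter([1.0], [1.0, -rho], eps, axis=1)
        x = base_x[:n_used] + noise[0] * sx
        y = base_y[:n_used] + noise[1] * sy
    else:
        x = base_x[:n_used].copy()
        y = base_y[:n_used].copy()

    quality = np.ones(n_used)
    if model.dropout_rate > 0:
        quality[rng.random(n_used) < model.dropout_rate] = 0.0

    rec = GazeRecording(
        participant_id=participant_id,
        image_id=image_id,
        condition=Condition(condition),
        t=t,
        x=x,
        y=y,
        quality=quality,
        nominal_rate=model.rate,
        recording_index=recording_index,
    )
    truth = GroundTruth(
        fixations=tuple(truths),
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        task_time_ms=float(t[-1]),
    )
    return rec, truth


def generate_toggles(
    model: ToggleModel, task_time_ms: float, seed
) -> list[ToggleEvent]:
    """Generate one recording's alternating toggle log (possibly empty)."""
    if not task_time_ms > 0:
        raise ValidationError("task_time_ms must be positive")
    rng = _as_rng(seed)
    if model.p_use <= 0 or rng.random() >= model.p_use:
        return []
    a_f, b_f = model._first_on_beta()
    f = float(np.clip(rng.beta(a_f, b_f), 0.02, 0.96))
    t0 = f * task_time_ms
    remaining = task_time_ms - t0
    a_p, b_p = model._on_frac_beta()
    on_total = float(rng.beta(a_p, b_p)) * remaining

    n_act = 1 + int(rng.poisson(model.n_activations_rate))
    # each activation should be a perceptible stretch (>= ~0.5 s)
    n_act = max(1, min(n_act, int(on_total // 500) or 1))
    on_durs = on_total * rng.dirichlet(np.full(n_act, 1.5))
    off_parts = (remaining - on_total) * rng.dirichlet(np.full(n_act, 1.5))

    events: list[ToggleEvent] = []
    t = t0
    for k in range(n_act):
        events.append(ToggleEvent(t=t, state=ToggleState.ON))
        t += on_durs[k]
        if k < n_act - 1:
            events.append(ToggleEvent(t=t, state=ToggleState.OFF))
            t += off_parts[k]
        elif task_time_ms - t > 1.0:
            events.append(ToggleEvent(t=t, state=ToggleState.OFF))
    validate_toggle_sequence(events)
    return events


def ai_scanpath_model(**overrides) -> ScanpathModel:
    """Preset for the AI-support condition (median fixation 313.27 ms)."""
    params = dict(dwell_markov=_AI_MARKOV, fix_duration_median=313.27)
    params.update(overrides)
    return ScanpathModel(**params)


def no_ai_scanpath_model(**overrides) -> ScanpathModel:
    """Preset for the unassisted condition (median fixation 317.29 ms)."""
    params = dict(dwell_markov=_NO_AI_MARKOV, fix_duration_median=317.29)
    params.update(overrides)
    return ScanpathModel(**params)


def default_toggle_model(**overrides) -> ToggleModel:
    return ToggleModel(**overrides)


# task-time lognormals per condition: (median ms, log-sd), spread chosen so
# the generated IQR brackets the regime the analysis operates in
_TASK_TIME = {
    Condition.AI: (109190.0, 0.429),
    Condition.NO_AI: (87100.0, 0.228),
}


@dataclass
class StudyData:
    """A complete synthetic study: inputs for every pipeline stage."""

    layout: AOILayout
    recordings: list[GazeRecording]
    toggles: dict[tuple[str, str, int], list[ToggleEvent]]
    error_flags: frozenset[tuple[str, str]]
    truths: dict[tuple[str, str, int], GroundTruth]
    seed: int | None

    @property
    def n_recordings(self) -> int:
        return len(self.recordings)


def generate_study(
    n_participants: int = 22,
    images_per_participant: int = 20,
    seed: int | None = 0,
    ai_model: ScanpathModel | None = None,
    no_ai_model: ScanpathModel | None = None,
    toggle_model: ToggleModel | None = None,
    low_quality_fraction: float = 80 / 440,
    n_duplicate_first_views: int | None = None,
    n_stimulus_errors: int | None = None,
    image_pool: int = 140,
) -> StudyData:
    """Generate a full study dataset with QC-relevant defects built in.

    Each participant views ``images_per_participant`` images drawn from a
    pool of ``image_pool``, split ~1:1 between conditions. A configurable
    fraction of recordings get degraded signal quality (to exercise the
    0.60 exclusion), ``n_duplicate_first_views`` participants re-view an
    image (the accidental short first view is added as an extra
    recording), and ``n_stimulus_errors`` healthy recordings are flagged
    as presentation errors. Defect counts default to the 5-duplicate /
    11-error rates of a 440-view acquisition, scaled to the study size,
    so the full-size default reproduces a 445 -> 349 inclusion funnel.
    """
    if n_participants <= 0 or images_per_participant <= 0:
        raise ValidationError("study sizes must be positive")
    n_views = n_participants * images_per_participant
    if n_duplicate_first_views is None:
        n_duplicate_first_views = int(round(n_views * 5 / 440))
    if n_stimulus_errors is None:
        n_stimulus_errors = int(round(n_views * 11 / 440))
    rng = _as_rng(seed)
    layout = default_layout()
    ai_model = ai_model or ai_scanpath_model(layout=layout)
    no_ai_model = no_ai_model or no_ai_scanpath_model(layout=layout)
    toggle_model = toggle_model or ToggleModel()

    n_main = n_participants * images_per_participant
    sessions: list[tuple[str, str, Condition]] = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        imgs = rng.choice(image_pool, size=images_per_participant, replace=False)
        n_ai = images_per_participant // 2
        conds = np.array(
            [Condition.AI] * n_ai + [Condition.NO_AI] * (images_per_participant - n_ai),
            dtype=object,
        )
        rng.shuffle(conds)
        for img, cond in zip(imgs, conds):
            sessions.append((pid, f"I{int(img) + 1:03d}", cond))

    n_low = int(round(low_quality_fraction * n_main))
    if not (0 <= n_low <= n_main):
        raise ValidationError("low_quality_fraction out of range")
    if n_duplicate_first_views > n_main or n_stimulus_errors > n_main - n_low:
        raise ValidationError("more defects requested than recordings available")
    order = rng.permutation(n_main)
    low_idx = set(order[:n_low].tolist())
    # stimulus errors must hit recordings that survive the quality rule
    healthy = [k for k in order.tolist() if k not in low_idx]
    err_idx = set(healthy[:n_stimulus_errors])
    dup_idx = set(rng.choice(n_main, size=n_duplicate_first_views, replace=False).tolist())

    recordings: list[GazeRecording] = []
    toggles: dict[tuple[str, str, int], list[ToggleEvent]] = {}
    truths: dict[tuple[str, str, int], GroundTruth] = {}
    error_flags: set[tuple[str, str]] = set()

    for k, (pid, iid, cond) in enumerate(sessions):
        model = ai_model if cond is Condition.AI else no_ai_model
        median, log_sd = _TASK_TIME[cond]
        task = float(
            np.clip(rng.lognormal(math.log(median), log_sd), 30_000.0, 400_000.0)
        )
        if k in low_idx:
            model_k = replace(model, dropout_rate=float(rng.uniform(0.42, 0.55)))
        else:
            model_k = model
        rec, truth = generate_recording(
            model_k, task, rng, participant_id=pid, image_id=iid,
            condition=cond, recording_index=1,
        )
        recordings.append(rec)
        truths[rec.key] = truth
        if cond is Condition.AI:
            toggles[rec.key] = generate_toggles(toggle_model, rec.duration_ms, rng)
        if k in err_idx:
            error_flags.add((pid, iid))
        if k in dup_idx:
            # accidental first view: same image, much shorter, recorded earlier
            short = float(rng.uniform(10_000.0, 25_000.0))
            dup, dup_truth = generate_recording(
                model_k, short, rng, participant_id=pid, image_id=iid,
                condition=cond, recording_index=0,
            )
            recordings.append(dup)
            truths[dup.key] = dup_truth
            if cond is Condition.AI:
                toggles[dup.key] = generate_toggles(toggle_model, dup.duration_ms, rng)

    return StudyData(
        layout=layout,
        recordings=recordings,
        toggles=toggles,
        error_flags=frozenset(error_flags),
        truths=truths,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
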