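"""Velocity-threshold (I-VT) fixation detection.

Raw gaze samples are classified into fixations by thresholding the angular
velocity between consecutive valid samples: inter-sample intervals slower
than the threshold (default 30 deg/s) are fixation intervals, maximal runs
of fixation intervals become candidate fixations, and candidates shorter
than the minimum duration (default 60 ms) are discarded. At 60 Hz this is
the standard event model for remote trackers; saccade-level metrics are
deliberately not derived because the sampling rate is too low to resolve
saccade dynamics.

Velocity uses plain two-point differencing with no smoothing window: at
60 Hz a multi-sample smoother would blur short saccades. Samples with
quality 0 are dropped before classification; a single missing frame inside
a stable run is bridged (gap tolerance ``max_gap_bridge``, default 25 ms
over the nominal interval, roughly 1.5 frames), while longer dropouts
terminate the run. A velocity exactly equal to the threshold is classified
as saccade (strict ``<``) — the boundary must be fixed for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .geometry import ViewingGeometry, px_to_deg
from .io import GazeRecording

__all__ = ["Fixation", "IVTParams", "VelocitySeries", "sample_velocities", "detect_fixations"]


@dataclass(frozen=True)
class Fixation:
    """A detected attentional event.

    ``onset``/``offset`` are the times (ms) of the first and last member
    sample; ``duration = offset - onset``; the centroid is the unweighted
    mean of member sample positions.
    """

    onset: float
    offset: float
    cx: float
    cy: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValidationError("fixation offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class IVTParams:
    """I-VT classifier parameters.

    velocity_threshold : deg/s, default 30.
    min_fix_duration : ms, default 60. Candidates spanning less are dropped.
    max_gap_bridge : ms of *extra* gap (beyond the nominal inter-sample
        interval) tolerated between consecutive valid samples before the
        interval is deemed unclassifiable; default 25 ms bridges a single
        dropped frame at 60 Hz.
    geometry : viewing geometry used for the pixel-to-angle conversion.
    """

    velocity_threshold: float = 30.0
    min_fix_duration: float = 60.0
    max_gap_bridge: float = 25.0
    geometry: ViewingGeometry = field(default_factory=ViewingGeometry)

    def __post_init__(self) -> None:
        if not self.velocity_threshold > 0:
            raise ValidationError("velocity_threshold must be positive")
        if not self.min_fix_duration > 0:
            raise ValidationError("min_fix_duration must be positive")
        if self.max_gap_bridge < 0:
            raise ValidationError("max_gap_bridge must be non-negative")


@dataclass(frozen=True)
class VelocitySeries:
    """Angular velocities between consecutive valid samples.

    ``velocity[i]`` is the deg/s between valid samples ``i`` and ``i+1``
    (times ``t_start[i]`` to ``t_end[i]``); ``classifiable[i]`` is False
    where the interval spans an invalid gap longer than the bridge
    tolerance. ``sample_index`` maps valid samples back to rows of the
    original recording.
    """

    t_start: np.ndarray
    t_end: np.ndarray
    velocity: np.ndarray
    classifiable: np.ndarray
    sample_index: np.ndarray


def sample_velocities(
    rec: GazeRecording,
    geom: ViewingGeometry | None = None,
    max_gap_bridge: float = 25.0,
) -> VelocitySeries:
    """Two-point angular velocity between consecutive valid samples."""
    if geom is None:
        geom = ViewingGeometry()
    valid = rec.quality > 0
    idx = np.flatnonzero(valid)
    if idx.size < 2:
        raise ValidationError("need at least 2 valid samples to estimate velocity")
    t = rec.t[idx]
    x = rec.x[idx]
    y = rec.y[idx]
    dt = np.diff(t)  # ms; positive by recording invariant
    ang = px_to_deg((x[:-1], y[:-1]), (x[1:], y[1:]), geom)
    vel = np.asarray(ang) / dt * 1000.0
    nominal_dt = 1000.0 / rec.nominal_rate
    classifiable = (dt - nominal_dt) <= max_gap_bridge + 1e-9
    return VelocitySeries(
        t_start=t[:-1],
        t_end=t[1:],
        velocity=vel,
        classifiable=classifiable,
        sample_index=idx,
    )


def detect_fixations(rec: GazeRecording, params: IVTParams | None = None) -> list[Fixation]:
    """Classify a recording into an ordered, non-overlapping fixation list.

    May return an empty list (e.g. a recording of continuous pursuit or
    too-short stable runs). Raises only if the recording has fewer than
    two valid samples.
    """
    if params is None:
        params = IVTParams()
    series = sample_velocities(rec, params.geometry, params.max_gap_bridge)
    is_fix = (series.velocity < params.velocity_threshold) & series.classifiable

    idx = series.sample_index
    t = rec.t[idx]
    x = rec.x[idx]
    y = rec.y[idx]

    fixations: list[Fixation] = []
    # maximal runs of consecutive True intervals
    padded = np.concatenate(([False], is_fix, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]  # interval index ranges [s, e)
    for s, e in zip(starts, ends):
        # intervals s..e-1 -> samples s..e inclusive
        onset = t[s]
        offset = t[e]
        if offset - onset < params.min_fix_duration:
            continue
        fixations.append(
            Fixation(
                onset=float(onset),
                offset=float(offset),
                cx=float(np.mean(x[s : e + 1])),
                cy=float(np.mean(y[s : e + 1])),
                n_samples=int(e - s + 1),
            )
        )
    return fixations
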