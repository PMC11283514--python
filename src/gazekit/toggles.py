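"""AI-overlay toggle intervals and per-interval fixation summaries.

A toggle log (alternating ON/OFF events, first ON) segments a recording
into state intervals that tile ``[0, task_end]`` exactly: OFF from onset
to the first activation, then alternating, the last interval closed at
``task_end``. Intervals are half-open ``[start, end)`` so a fixation whose
onset falls on a boundary belongs to the interval starting there; a
fixation spanning a toggle is attributed wholly to its onset interval
(fixation counts are the unit of analysis — splitting would create
sub-minimum fragments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .io import ToggleEvent, ToggleState, validate_toggle_sequence  # noqa: F401 - ToggleState re-exported

__all__ = ["StateInterval", "IntervalStats", "ToggleSummary", "build_intervals", "summarize_toggles"]


@dataclass(frozen=True)
class StateInterval:
    state: ToggleState
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError("interval end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class IntervalStats:
    """Fixation activity during one ON or OFF interval."""

    state: ToggleState
    start: float
    end: float
    fix_count: int
    median_fix_duration: float  # NaN when the interval holds no fixation


@dataclass(frozen=True)
class StateAggregate:
    """Fixation activity pooled over all intervals in one state."""

    state: ToggleState
    total_duration: float  # ms spent in this state
    fix_count: int
    ui_fix_count: int
    mean_fix_duration: float
    median_fix_duration: float
    fix_frequency: float  # fixations per second of state time


@dataclass(frozen=True)
class ToggleSummary:
    n_activations: int
    total_on: float
    pct_on: float
    first_on_latency: float  # NaN when never activated
    first_on_pct: float
    per_interval: tuple[IntervalStats, ...]
    by_state: dict = field(default_factory=dict)  # ToggleState -> StateAggregate


def build_intervals(toggles: Sequence[ToggleEvent], task_end: float) -> list[StateInterval]:
    """Expand a toggle log into state intervals tiling ``[0, task_end]``."""
    if not task_end > 0:
        raise ValidationError("task_end must be positive")
    validate_toggle_sequence(toggles)
    for ev in toggles:
        if ev.t > task_end:
            raise ValidationError(f"toggle at t={ev.t} lies beyond task end {task_end}")
    bounds = [0.0] + [ev.t for ev in toggles] + [task_end]
    # a toggle exactly at 0 or at task_end would create a zero-width span
    intervals = []
    state = ToggleState.OFF
    for start, end in zip(bounds[:-1], bounds[1:]):
        if end > start:
            intervals.append(StateInterval(state=state, start=start, end=end))
        state = ToggleState.ON if state is ToggleState.OFF else ToggleState.OFF
    return intervals


def _interval_of(onset: float, starts: np.ndarray) -> int:
    # half-open [start, end): the interval whose start is the last <= onset
    return int(np.searchsorted(starts, onset, side="right") - 1)


def summarize_toggles(
    intervals: Sequence[StateInterval],
    fixations: Sequence,
    assignments: Sequence[frozenset[str]] | None = None,
    ui_names: Iterable[str] = (),
) -> ToggleSummary:
    """Per-interval and per-state fixation summaries for one recording.

    Every fixation is assigned to exactly one interval (the one containing
    its onset). ``assignments``/``ui_names`` enable the UI-fixation count
    per state; both may be omitted.
    """
    if not intervals:
        raise ValidationError("interval list is empty")
    starts = np.array([iv.start for iv in intervals])
    ends = np.array([iv.end for iv in intervals])
    if starts[0] != 0.0 or np.any(starts[1:] != ends[:-1]):
        raise ValidationError("intervals must tile the task contiguously from 0")
    task_time = float(ends[-1])
    ui_names = set(ui_names)
    if assignments is not None and len(assignments) != len(fixations):
        raise ValidationError("fixations and assignments must align one-to-one")

    members: list[list[int]] = [[] for _ in intervals]
    for k, fix in enumerate(fixations):
        if not (0 <= fix.onset < task_time):
            raise ValidationError(f"fixation onset {fix.onset} outside task [0, {task_time})")
        members[_interval_of(fix.onset, starts)].append(k)

    per_interval = []
    for iv, idx in zip(intervals, members):
        durs = np.array([fixations[k].duration for k in idx], dtype=float)
        per_interval.append(
            IntervalStats(
                state=iv.state,
                start=iv.start,
                end=iv.end,
                fix_count=len(idx),
                median_fix_duration=float(np.median(durs)) if len(idx) else float("nan"),
            )
        )

    by_state = {}
    for state in (ToggleState.OFF, ToggleState.ON):
        sel = [k for iv, idx in zip(intervals, members) if iv.state is state for k in idx]
        durs = np.array([fixations[k].duration for k in sel], dtype=float)
        state_time = float(sum(iv.duration for iv in intervals if iv.state is state))
        ui_count = (
            sum(1 for k in sel if assignments[k] & ui_names) if assignments is not None else 0
        )
        by_state[state] = StateAggregate(
            state=state,
            total_duration=state_time,
            fix_count=len(sel),
            ui_fix_count=ui_count,
            mean_fix_duration=float(durs.mean()) if len(sel) else float("nan"),
            median_fix_duration=float(np.median(durs)) if len(sel) else float("nan"),
            fix_frequency=len(sel) / (state_time / 1000.0) if state_time > 0 else float("nan"),
        )

    on_intervals = [iv for iv in intervals if iv.state is ToggleState.ON]
    total_on = float(sum(iv.duration for iv in on_intervals))
    first_on = on_intervals[0].start if on_intervals else float("nan")
    return ToggleSummary(
        n_activations=len(on_intervals),
        total_on=total_on,
        pct_on=total_on / task_time * 100.0,
        first_on_latency=first_on,
        first_on_pct=first_on / task_time * 100.0 if on_intervals else float("nan"),
        per_interval=tuple(per_interval),
        by_state=by_state,
    )
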