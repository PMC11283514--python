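"""Readers, writers and core record types for all pipeline artifacts.

File dialects (frozen for reproducibility; all files are UTF-8 with "."
decimal separators and a mandatory header row where applicable):

* gaze CSV      — columns ``t_ms,x_px,y_px,quality``
* toggle CSV    — columns ``t_ms,state`` with state in {ON, OFF}
* AOI layout    — JSON ``{"aois": [{"name", "role", "rect": [x0,y0,x1,y1]}]}``
* fixation CSV  — columns ``onset_ms,offset_ms,duration_ms,cx_px,cy_px,n_samples``
* metric tables — plain CSV, one row per recording

Coordinates are screen pixels, origin top-left, y down. AOI rectangles are
half-open ``[x0, x1) x [y0, y1)`` so adjacent AOIs tile the screen without
a double hit at shared edges; genuinely overlapping rectangles are allowed
and handled downstream by the both-hit assignment rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Condition",
    "AOIRole",
    "ToggleState",
    "GazeRecording",
    "AOI",
    "AOILayout",
    "ToggleEvent",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_toggle_log",
    "write_toggle_log",
    "read_aoi_layout",
    "write_aoi_layout",
    "read_fixation_csv",
    "write_fixation_csv",
    "validate_toggle_sequence",
]


class Condition(str, Enum):
    """Experimental condition: AI overlay available or not."""

    AI = "AI"
    NO_AI = "NO_AI"


class AOIRole(str, Enum):
    """Functional role of a screen region in the reading interface."""

    BITEWING = "bitewing"
    AI_FINDINGS = "ai_findings"
    TOOTH_MAP = "tooth_map"
    TOOLS = "tools"
    INFO = "info"
    BROWSER = "browser"
    TOGGLE = "toggle"
    OTHER = "other"


class ToggleState(str, Enum):
    ON = "ON"
    OFF = "OFF"


GAZE_COLUMNS = ("t_ms", "x_px", "y_px", "quality")
TOGGLE_COLUMNS = ("t_ms", "state")
FIXATION_COLUMNS = ("onset_ms", "offset_ms", "duration_ms", "cx_px", "cy_px", "n_samples")


@dataclass
class GazeRecording:
    """One screen-recording's worth of timestamped gaze samples.

    ``t`` is milliseconds since recording onset and must be strictly
    increasing. ``quality`` is per-sample signal validity in [0, 1]
    (1 = fully valid); positions may lie off-screen (tracker noise) but
    must be finite wherever quality > 0. Positions are monocular
    (binocular-interpolated by the tracker); per-eye channels are out of
    scope.
    """

    participant_id: str
    image_id: str
    condition: Condition
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    quality: np.ndarray
    nominal_rate: float = 60.0
    recording_index: int = 0

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        n = self.t.size
        if n == 0:
            raise ValidationError("recording has no samples")
        if not (self.x.size == self.y.size == self.quality.size == n):
            raise ValidationError("sample columns have mismatched lengths")
        if np.any(self.t < 0):
            raise ValidationError("sample times must be non-negative")
        bad = np.flatnonzero(np.diff(self.t) <= 0)
        if bad.size:
            raise ValidationError(
                f"sample times must be strictly increasing (first violation at row {bad[0] + 1})"
            )
        if np.any((self.quality < 0) | (self.quality > 1) | ~np.isfinite(self.quality)):
            raise ValidationError("quality values must lie in [0, 1]")
        valid = self.quality > 0
        if np.any(~np.isfinite(self.x[valid])) or np.any(~np.isfinite(self.y[valid])):
            raise ValidationError("positions must be finite where quality > 0")
        if n >= 2 and not self.duration_ms > 0:
            raise ValidationError("recording duration must be positive")
        if not self.nominal_rate > 0:
            raise ValidationError("nominal_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.participant_id, self.image_id, self.recording_index)

    def mean_quality(self) -> float:
        return float(np.mean(self.quality))


@dataclass(frozen=True)
class AOI:
    """A named axis-aligned screen rectangle with an interface role."""

    name: str
    role: AOIRole
    rect: tuple[float, float, float, float]  # x0, y0, x1, y1; half-open

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", AOIRole(self.role))
        object.__setattr__(self, "rect", tuple(float(v) for v in self.rect))
        x0, y0, x1, y1 = self.rect
        if not (x0 < x1 and y0 < y1):
            raise ValidationError(f"AOI {self.name!r} has a degenerate rectangle {self.rect}")

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.rect
        return (x1 - x0) * (y1 - y0)

    def contains(self, px: float, py: float) -> bool:
        x0, y0, x1, y1 = self.rect
        return (x0 <= px < x1) and (y0 <= py < y1)


@dataclass(frozen=True)
class AOILayout:
    """A set of uniquely-named AOIs with exactly one ``bitewing`` region.

    Rectangles may overlap; the interface genuinely stacks some elements,
    and downstream assignment counts a fixation in every AOI it hits.
    """

    aois: tuple[AOI, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "aois", tuple(self.aois))
        names = [a.name for a in self.aois]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate AOI names: {dupes}")
        n_bitewing = sum(a.role is AOIRole.BITEWING for a in self.aois)
        if n_bitewing != 1:
            raise ValidationError(
                f"layout must contain exactly one bitewing AOI (found {n_bitewing})"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.aois)

    def __iter__(self):
        return iter(self.aois)

    def __len__(self) -> int:
        return len(self.aois)

    def __getitem__(self, name: str) -> AOI:
        for a in self.aois:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def bitewing(self) -> AOI:
        return next(a for a in self.aois if a.role is AOIRole.BITEWING)

    def names_with_roles(self, roles: Iterable[AOIRole]) -> tuple[str, ...]:
        roles = set(AOIRole(r) for r in roles)
        return tuple(a.name for a in self.aois if a.role in roles)


@dataclass(frozen=True)
class ToggleEvent:
    """A single AI-overlay state change at time ``t`` (ms from onset)."""

    t: float
    state: ToggleState

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", float(self.t))
        object.__setattr__(self, "state", ToggleState(self.state))
        if self.t < 0:
            raise ValidationError("toggle time must be non-negative")


def validate_toggle_sequence(events: Sequence[ToggleEvent]) -> None:
    """Enforce ordering and ON/OFF alternation starting with ON.

    Recordings begin with the overlay off, so the first event (if any)
    must be ON and consecutive events must alternate.
    """
    for i, ev in enumerate(events):
        if i == 0:
            if ev.state is not ToggleState.ON:
                raise ValidationError("first toggle event must be ON (overlay starts off)")
            continue
        prev = events[i - 1]
        if ev.t <= prev.t:
            raise ValidationError(f"toggle events must be strictly ordered in time (row {i})")
        if ev.state is prev.state:
            raise ValidationError(
                f"toggle events must alternate ON/OFF (rows {i - 1} and {i} are both {ev.state.value})"
            )


# ---------------------------------------------------------------------------
# gaze CSV


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_gaze_csv(
    path,
    participant_id: str,
    image_id: str,
    condition: Condition | str,
    nominal_rate: float = 60.0,
    recording_index: int = 0,
) -> GazeRecording:
    """Read a gaze CSV into a validated :class:`GazeRecording`.

    The header must declare ``t_ms,x_px,y_px,quality``. Rows are sorted by
    time before validation; duplicated timestamps are rejected rather than
    silently dropped.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, GAZE_COLUMNS, path)
    df = df.sort_values("t_ms", kind="stable").reset_index(drop=True)
    return GazeRecording(
        participant_id=participant_id,
        image_id=image_id,
        condition=Condition(condition),
        t=df["t_ms"].to_numpy(dtype=float),
        x=df["x_px"].to_numpy(dtype=float),
        y=df["y_px"].to_numpy(dtype=float),
        quality=df["quality"].to_numpy(dtype=float),
        nominal_rate=nominal_rate,
        recording_index=recording_index,
    )


# shortest float representation that round-trips float64 exactly
_FLOAT_FMT = lambda v: repr(float(v))  # noqa: E731


def write_gaze_csv(rec: GazeRecording, path) -> None:
    df = pd.DataFrame(
        {"t_ms": rec.t, "x_px": rec.x, "y_px": rec.y, "quality": rec.quality}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# toggle CSV


def read_toggle_log(path) -> list[ToggleEvent]:
    """Read a toggle CSV; an empty or header-only file yields an empty list.

    Alternation (ON first, strictly increasing times) is enforced; two
    consecutive events with the same state raise :class:`ValidationError`.
    """
    p = Path(path)
    if p.stat().st_size == 0:
        return []
    df = pd.read_csv(p, float_precision="round_trip")
    if df.empty:
        return []
    _require_columns(df, TOGGLE_COLUMNS, path)
    events = [
        ToggleEvent(t=float(row.t_ms), state=ToggleState(str(row.state)))
        for row in df.itertuples()
    ]
    validate_toggle_sequence(events)
    return events


def write_toggle_log(events: Sequence[ToggleEvent], path) -> None:
    validate_toggle_sequence(events)
    df = pd.DataFrame(
        {"t_ms": [e.t for e in events], "state": [e.state.value for e in events]}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# AOI layout JSON


def read_aoi_layout(path) -> AOILayout:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    entries = doc["aois"] if isinstance(doc, dict) else doc
    aois = []
    for e in entries:
        try:
            aois.append(AOI(name=e["name"], role=AOIRole(e["role"]), rect=tuple(e["rect"])))
        except KeyError as exc:
            raise FormatError(f"{path}: AOI entry missing field {exc}") from exc
    return AOILayout(tuple(aois))


def write_aoi_layout(layout: AOILayout, path) -> None:
    doc = {
        "aois": [
            {"name": a.name, "role": a.role.value, "rect": list(a.rect)} for a in layout
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# fixation CSV (the Fixation type itself lives in gazekit.events)


def write_fixation_csv(fixations, path) -> None:
    df = pd.DataFrame(
        {
            "onset_ms": [f.onset for f in fixations],
            "offset_ms": [f.offset for f in fixations],
            "duration_ms": [f.duration for f in fixations],
            "cx_px": [f.cx for f in fixations],
            "cy_px": [f.cy for f in fixations],
            "n_samples": [f.n_samples for f in fixations],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_fixation_csv(path):
    from .events import Fixation

    p = Path(path)
    if p.stat().st_size == 0:
        return []
    df = pd.read_csv(p, float_precision="round_trip")
    if df.empty:
        return []
    _require_columns(df, ("onset_ms", "offset_ms", "cx_px", "cy_px"), path)
    n_samples = df["n_samples"] if "n_samples" in df.columns else pd.Series([0] * len(df))
    return [
        Fixation(
            onset=float(r.onset_ms),
            offset=float(r.offset_ms),
            cx=float(r.cx_px),
            cy=float(r.cy_px),
            n_samples=int(n),
        )
        for r, n in zip(df.itertuples(), n_samples)
    ]
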