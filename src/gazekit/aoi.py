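"""AOI padding, fixation-to-AOI assignment, and per-recording metrics.

To absorb small spatial calibration offsets, every AOI rectangle is
expanded outward on each side by the pixel equivalent of a visual-angle
pad (default 3 degrees) before hit testing, then clipped to the screen.
A fixation is assigned by its centroid to *every* padded AOI containing
it — overlapping hits count fully in each region ("hit in both AOI") —
or to none if it lands outside all regions.

Per-recording metrics contrast attention to the radiograph itself
(the single ``bitewing`` AOI) with attention to user-interface elements
(every other AOI, browser chrome included, configurable via ``ui_roles``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .events import Fixation
from .geometry import ViewingGeometry, visual_angle_to_px
from .io import AOILayout, AOIRole, GazeRecording

__all__ = [
    "PaddedAOI",
    "MetricRow",
    "pad_aois",
    "assign_fixation",
    "assign_fixations",
    "compute_metrics",
    "metric_table",
    "METRIC_NAMES",
]

#: Metric columns compared between conditions, in report order.
METRIC_NAMES = [
    "task_time",
    "total_fix_duration_ui",
    "total_fix_duration_bitewing",
    "avg_fix_duration",
    "fix_count_total",
    "fix_count_ui",
    "fix_count_bitewing",
    "fix_frequency",
    "prop_time_ui",
    "prop_time_bitewing",
]


@dataclass(frozen=True)
class PaddedAOI:
    """An AOI rectangle expanded by a visual-angle pad and screen-clipped."""

    source: str
    role: AOIRole
    rect: tuple[float, float, float, float]

    def contains(self, px: float, py: float) -> bool:
        x0, y0, x1, y1 = self.rect
        return (x0 <= px < x1) and (y0 <= py < y1)


def pad_aois(
    layout: AOILayout,
    geom: ViewingGeometry | None = None,
    pad_deg: float = 3.0,
    pad_overrides: dict[str, float] | None = None,
) -> tuple[PaddedAOI, ...]:
    """Expand every AOI by ``pad_deg`` degrees of visual angle per side.

    The pad is converted to pixels per axis (horizontal and vertical mm/px
    differ slightly on most panels) and rounded to whole pixels; expanded
    rectangles are clipped to the screen bounds. ``pad_overrides`` maps AOI
    names to a different pad in degrees.
    """
    if geom is None:
        geom = ViewingGeometry()
    if pad_deg < 0:
        raise ValidationError("pad_deg must be non-negative")
    overrides = pad_overrides or {}
    padded = []
    for a in layout:
        deg = overrides.get(a.name, pad_deg)
        if deg < 0:
            raise ValidationError(f"pad override for {a.name!r} must be non-negative")
        px_x, px_y = visual_angle_to_px(geom, deg)
        pad_x, pad_y = round(px_x), round(px_y)
        x0, y0, x1, y1 = a.rect
        rect = (
            max(0.0, x0 - pad_x),
            max(0.0, y0 - pad_y),
            min(float(geom.res_x), x1 + pad_x),
            min(float(geom.res_y), y1 + pad_y),
        )
        padded.append(PaddedAOI(source=a.name, role=a.role, rect=rect))
    return tuple(padded)


def assign_fixation(fix: Fixation, padded: Sequence[PaddedAOI]) -> frozenset[str]:
    """Names of every padded AOI containing the fixation centroid.

    The empty set means the fixation landed outside all regions.
    """
    return frozenset(p.source for p in padded if p.contains(fix.cx, fix.cy))


def assign_fixations(
    fixations: Sequence[Fixation], padded: Sequence[PaddedAOI]
) -> list[frozenset[str]]:
    return [assign_fixation(f, padded) for f in fixations]


@dataclass(frozen=True)
class MetricRow:
    """Per-recording attention metrics.

    Durations are ms, task time is seconds, proportions are percentages of
    task time. A fixation assigned to several AOIs counts fully in every
    group it hits, so UI and bitewing columns may double-count overlap
    hits, and fixations outside all AOIs appear in neither group.
    ``avg_fix_duration`` is NaN when the recording has no fixations
    (missing, never imputed).
    """

    participant_id: str
    image_id: str
    condition: str
    recording_index: int
    task_time: float
    total_fix_duration_ui: float
    total_fix_duration_bitewing: float
    avg_fix_duration: float
    fix_count_total: int
    fix_count_ui: int
    fix_count_bitewing: int
    fix_frequency: float
    prop_time_ui: float
    prop_time_bitewing: float


def compute_metrics(
    fixations: Sequence[Fixation],
    assignments: Sequence[frozenset[str]],
    rec: GazeRecording,
    layout: AOILayout,
    ui_roles: Iterable[AOIRole] | None = None,
) -> MetricRow:
    """Aggregate one recording's fixations into a :class:`MetricRow`.

    ``ui_roles`` selects which roles form the user-interface group;
    by default every non-bitewing role (ai_findings, tooth_map, tools,
    info, browser, toggle, other).
    """
    if len(fixations) != len(assignments):
        raise ValidationError("fixations and assignments must align one-to-one")
    task_time_s = rec.duration_ms / 1000.0
    if not task_time_s > 0:
        raise ValidationError("task time must be positive")
    if ui_roles is None:
        ui_roles = [r for r in AOIRole if r is not AOIRole.BITEWING]
    ui_names = set(layout.names_with_roles(ui_roles))
    bitewing_names = {layout.bitewing.name}

    durations = np.array([f.duration for f in fixations], dtype=float)
    in_ui = np.array([bool(a & ui_names) for a in assignments], dtype=bool)
    in_bw = np.array([bool(a & bitewing_names) for a in assignments], dtype=bool)

    total_ui = float(durations[in_ui].sum()) if len(fixations) else 0.0
    total_bw = float(durations[in_bw].sum()) if len(fixations) else 0.0
    return MetricRow(
        participant_id=rec.participant_id,
        image_id=rec.image_id,
        condition=rec.condition.value,
        recording_index=rec.recording_index,
        task_time=task_time_s,
        total_fix_duration_ui=total_ui,
        total_fix_duration_bitewing=total_bw,
        avg_fix_duration=float(durations.mean()) if len(fixations) else float("nan"),
        fix_count_total=len(fixations),
        fix_count_ui=int(in_ui.sum()),
        fix_count_bitewing=int(in_bw.sum()),
        fix_frequency=len(fixations) / task_time_s,
        prop_time_ui=total_ui / (task_time_s * 1000.0) * 100.0,
        prop_time_bitewing=total_bw / (task_time_s * 1000.0) * 100.0,
    )


def metric_table(rows: Sequence[MetricRow]) -> pd.DataFrame:
    """Stack MetricRows into a DataFrame, one row per recording."""
    return pd.DataFrame([vars(r) for r in rows])
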