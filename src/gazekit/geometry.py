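"""Screen/viewing geometry and pixel <-> visual-angle conversion.

All gaze coordinates in this package are screen pixels with the origin at
the top-left corner, x increasing rightward and y increasing downward.
Visual angles are computed from the physical screen dimensions and the
eye-to-screen distance, so every angular quantity (velocity thresholds,
AOI padding) is viewing-distance aware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["ViewingGeometry", "px_to_deg", "visual_angle_to_px", "px_per_deg"]


@dataclass(frozen=True)
class ViewingGeometry:
    """Physical viewing setup of a remote eye-tracking session.

    Parameters
    ----------
    res_x, res_y
        Screen resolution in pixels. Default 1920 x 1080.
    screen_w, screen_h
        Physical screen size in millimetres. The default (531 x 299 mm)
        is a 24-inch 16:9 panel; adjust it to the monitor actually used,
        since it directly scales every deg/px conversion.
    distance
        Eye-to-screen distance in millimetres. Default 700 mm.
    """

    res_x: int = 1920
    res_y: int = 1080
    screen_w: float = 531.0
    screen_h: float = 299.0
    distance: float = 700.0

    def __post_init__(self) -> None:
        for name in ("res_x", "res_y", "screen_w", "screen_h", "distance"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"ViewingGeometry.{name} must be strictly positive")

    @property
    def mm_per_px_x(self) -> float:
        return self.screen_w / self.res_x

    @property
    def mm_per_px_y(self) -> float:
        return self.screen_h / self.res_y


def px_to_deg(p1, p2, geom: ViewingGeometry):
    """Visual angle (degrees) subtended by the segment between two screen points.

    Each point is an ``(x, y)`` pair in pixels; coordinates may be scalars
    or numpy arrays (broadcast elementwise). Pixel offsets are converted to
    millimetres with per-axis scale factors, then the chord ``d_mm`` at the
    viewing distance ``D`` subtends ``2 * arctan(d_mm / (2 * D))``.
    """
    x1, y1 = p1
    x2, y2 = p2
    dx_mm = (np.asarray(x2, dtype=float) - np.asarray(x1, dtype=float)) * geom.mm_per_px_x
    dy_mm = (np.asarray(y2, dtype=float) - np.asarray(y1, dtype=float)) * geom.mm_per_px_y
    d_mm = np.hypot(dx_mm, dy_mm)
    ang = np.degrees(2.0 * np.arctan2(d_mm, 2.0 * geom.distance))
    if np.ndim(ang) == 0:
        return float(ang)
    return ang


def visual_angle_to_px(geom: ViewingGeometry, deg: float) -> tuple[float, float]:
    """Pixels subtended by ``deg`` degrees of visual angle, per axis.

    Returns the (horizontal, vertical) pixel extents of a screen-centred
    chord of ``deg`` degrees: ``2 * D * tan(deg / 2)`` millimetres divided
    by the per-axis mm/px factor.
    """
    if deg < 0:
        raise ValidationError("visual angle must be non-negative")
    d_mm = 2.0 * geom.distance * math.tan(math.radians(deg) / 2.0)
    return d_mm / geom.mm_per_px_x, d_mm / geom.mm_per_px_y


def px_per_deg(geom: ViewingGeometry) -> tuple[float, float]:
    """Local (horizontal, vertical) px-per-degree scale at screen centre."""
    return visual_angle_to_px(geom, 1.0)
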