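import numpy as np
import pytest

from gazekit import (
    AOI,
    AOILayout,
    AOIRole,
    Condition,
    GazeRecording,
    ViewingGeometry,
)


@pytest.fixture
def geom() -> ViewingGeometry:
    return ViewingGeometry()


@pytest.fixture
def layout() -> AOILayout:
    from gazekit import default_layout

    return default_layout()


def make_recording(
    t=None, x=None, y=None, quality=None, condition=Condition.AI, rate=60.0, **kw
) -> GazeRecording:
    """Build a small recording with sensible defaults for unit tests."""
    if t is None:
        t = np.arange(10) * (1000.0 / rate)
    n = len(t)
    if x is None:
        x = np.full(n, 960.0)
    if y is None:
        y = np.full(n, 540.0)
    if quality is None:
        quality = np.ones(n)
    kw.setdefault("participant_id", "P01")
    kw.setdefault("image_id", "I001")
    return GazeRecording(
        t=np.asarray(t, dtype=float),
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        quality=np.asarray(quality, dtype=float),
        condition=condition,
        nominal_rate=rate,
        **kw,
    )


@pytest.fixture
def two_aoi_layout() -> AOILayout:
    return AOILayout(
        (
            AOI("bitewing", AOIRole.BITEWING, (400, 200, 1400, 800)),
            AOI("panel", AOIRole.AI_FINDINGS, (1500, 200, 1900, 800)),
        )
    )
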