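"""Visual-angle geometry and I-VT fixation detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazekit import (
    IVTParams,
    ValidationError,
    ViewingGeometry,
    detect_fixations,
    px_to_deg,
    sample_velocities,
)

from .conftest import make_recording

DT = 1000.0 / 60.0


def angle_oracle(p1, p2, geom):
    """Independent closed-form visual angle: 2*atan(d_mm / (2*D))."""
    dx = (p2[0] - p1[0]) * geom.screen_w / geom.res_x
    dy = (p2[1] - p1[1]) * geom.screen_h / geom.res_y
    return math.degrees(2.0 * math.atan(math.hypot(dx, dy) / (2.0 * geom.distance)))


class TestPxToDeg:
    def test_zero_distance(self, geom):
        assert px_to_deg((100, 100), (100, 100), geom) == 0.0

    def test_chord_equal_to_viewing_distance(self, geom):
        # d_mm == distance: angle = 2*atan(0.5) ~ 53.13 deg
        px = geom.distance / geom.mm_per_px_x
        ang = px_to_deg((0, 500), (px, 500), geom)
        assert ang == pytest.approx(math.degrees(2 * math.atan(0.5)), abs=1e-9)

    @settings(max_examples=200, deadline=None)
    @given(
        x1=st.floats(0, 1920), y1=st.floats(0, 1080),
        x2=st.floats(0, 1920), y2=st.floats(0, 1080),
    )
    def test_matches_trigonometric_oracle(self, x1, y1, x2, y2):
        geom = ViewingGeometry()
        assert px_to_deg((x1, y1), (x2, y2), geom) == pytest.approx(
            angle_oracle((x1, y1), (x2, y2), geom), abs=1e-9
        )

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValidationError):
            ViewingGeometry(distance=0)


class TestSampleVelocities:
    def test_static_gaze_zero_velocity(self):
        rec = make_recording(t=np.arange(20) * DT)
        v = sample_velocities(rec)
        np.testing.assert_allclose(v.velocity, 0.0)

    def test_one_degree_step_at_60hz(self, geom):
        # two samples 1 deg apart, dt = 16.67 ms -> ~60 deg/s
        px = 2 * geom.distance * math.tan(math.radians(0.5)) / geom.mm_per_px_x
        rec = make_recording(t=[0.0, DT], x=[960.0, 960.0 + px], y=[540.0, 540.0])
        v = sample_velocities(rec, geom)
        assert v.velocity[0] == pytest.approx(60.0, rel=1e-6)

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        t = np.arange(30) * DT
        x = rng.uniform(200, 1700, 30)
        y = rng.uniform(200, 900, 30)
        v1 = sample_velocities(make_recording(t=t, x=x, y=y))
        v2 = sample_velocities(make_recording(t=t, x=x + 57.0, y=y - 31.0))
        np.testing.assert_allclose(v1.velocity, v2.velocity, rtol=1e-9)

    def test_long_gap_marked_unclassifiable(self):
        q = np.ones(20)
        q[5:8] = 0.0  # 3 dropped frames: gap 50 ms over nominal
        rec = make_recording(t=np.arange(20) * DT, quality=q)
        v = sample_velocities(rec, max_gap_bridge=25.0)
        assert not v.classifiable[4]  # interval spanning the hole
        assert v.classifiable[0]

    def test_fewer_than_two_valid_samples_rejected(self):
        q = np.zeros(10)
        q[0] = 1.0
        rec = make_recording(quality=q)
        with pytest.raises(ValidationError):
            sample_velocities(rec)


def brute_force_labels(rec, params):
    """Independent per-interval classification used as the detection oracle."""
    valid = np.flatnonzero(rec.quality > 0)
    t, x, y = rec.t[valid], rec.x[valid], rec.y[valid]
    labels = []
    for i in range(len(t) - 1):
        ang = angle_oracle((x[i], y[i]), (x[i + 1], y[i + 1]), params.geometry)
        dt = t[i + 1] - t[i]
        slow = ang / dt * 1000.0 < params.velocity_threshold
        bridged = (dt - 1000.0 / rec.nominal_rate) <= params.max_gap_bridge + 1e-9
        labels.append(slow and bridged)
    # maximal runs -> candidate [start_sample, end_sample]
    fixes = []
    i = 0
    while i < len(labels):
        if labels[i]:
            j = i
            while j < len(labels) and labels[j]:
                j += 1
            if t[j] - t[i] >= params.min_fix_duration:
                fixes.append((t[i], t[j]))
            i = j
        else:
            i += 1
    return fixes


class TestDetectFixations:
    def test_single_static_cluster(self):
        n = 31  # 500 ms of static gaze
        rec = make_recording(t=np.arange(n) * DT, x=np.full(n, 700.0), y=np.full(n, 400.0))
        fixes = detect_fixations(rec)
        assert len(fixes) == 1
        assert fixes[0].cx == pytest.approx(700.0)
        assert fixes[0].cy == pytest.approx(400.0)
        assert fixes[0].duration == pytest.approx(500.0, abs=DT)

    def test_two_clusters_with_fast_saccade(self):
        t = np.arange(40) * DT
        x = np.concatenate([np.full(18, 500.0), [800.0, 1100.0, 1400.0], np.full(19, 1500.0)])
        y = np.full(40, 540.0)
        rec = make_recording(t=t, x=x, y=y)
        params = IVTParams()
        fixes = detect_fixations(rec, params)
        oracle = brute_force_labels(rec, params)
        assert len(fixes) == len(oracle) == 2
        for f, (on, off) in zip(fixes, oracle):
            assert f.onset == pytest.approx(on)
            assert f.offset == pytest.approx(off)

    def test_run_shorter_than_minimum_discarded(self):
        # 50 ms stable run (4 samples) between two saccade flights
        t = np.arange(12) * DT
        x = np.array([0, 300, 600, 900, 900, 900, 900, 1200, 1500, 1800, 1800 + 300, 1800 + 600], dtype=float)
        rec = make_recording(t=t, x=x, y=np.full(12, 540.0))
        assert detect_fixations(rec) == []

    def test_single_dropped_frame_is_bridged(self):
        n = 30
        q = np.ones(n)
        q[14] = 0.0
        rec = make_recording(t=np.arange(n) * DT, quality=q)
        fixes = detect_fixations(rec)
        assert len(fixes) == 1

    def test_two_dropped_frames_split_the_run(self):
        n = 30
        q = np.ones(n)
        q[14:16] = 0.0
        rec = make_recording(t=np.arange(n) * DT, quality=q)
        assert len(detect_fixations(rec)) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_noisy_scanpaths(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        # alternating slow/fast segments with dropouts
        x = [600.0]
        for _ in range(n - 1):
            step = rng.normal(0, 2.0) if rng.random() < 0.85 else rng.normal(0, 400.0)
            x.append(float(np.clip(x[-1] + step, 0, 1919)))
        q = (rng.random(n) > 0.03).astype(float)
        q[0] = q[-1] = 1.0
        rec = make_recording(t=np.arange(n) * DT, x=np.array(x), y=np.full(n, 540.0), quality=q)
        params = IVTParams()
        fixes = detect_fixations(rec, params)
        oracle = brute_force_labels(rec, params)
        assert [(f.onset, f.offset) for f in fixes] == pytest.approx(oracle)

    def test_fixations_disjoint_and_ordered(self):
        rng = np.random.default_rng(11)
        n = 600
        x = np.cumsum(rng.choice([0.5, 80.0], p=[0.9, 0.1], size=n)) % 1900
        rec = make_recording(t=np.arange(n) * DT, x=x, y=np.full(n, 500.0))
        fixes = detect_fixations(rec)
        for a, b in zip(fixes[:-1], fixes[1:]):
            assert a.offset <= b.onset
            assert a.onset < b.onset

    def test_lowering_threshold_never_increases_fixation_time(self):
        rng = np.random.default_rng(12)
        n = 500
        x = 900 + np.cumsum(rng.normal(0, 15.0, size=n))
        rec = make_recording(t=np.arange(n) * DT, x=x, y=np.full(n, 500.0))
        times = []
        for thr in (120.0, 60.0, 30.0, 15.0, 5.0):
            fixes = detect_fixations(rec, IVTParams(velocity_threshold=thr))
            times.append(sum(f.duration for f in fixes))
        assert times == sorted(times, reverse=True)
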