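"""AOI padding, centroid assignment and per-recording metrics."""

import math

import numpy as np
import pytest

from gazekit import (
    AOI,
    AOILayout,
    AOIRole,
    Fixation,
    ValidationError,
    ViewingGeometry,
    assign_fixation,
    assign_fixations,
    compute_metrics,
    pad_aois,
)

from .conftest import make_recording


def fix_at(x, y, onset=0.0, dur=300.0):
    return Fixation(onset=onset, offset=onset + dur, cx=x, cy=y, n_samples=18)


class TestPadAois:
    def test_zero_pad_is_identity(self, layout, geom):
        padded = pad_aois(layout, geom, pad_deg=0.0)
        for p, a in zip(padded, layout):
            assert p.rect == a.rect

    def test_three_degree_pad_matches_trig_oracle(self, layout, geom):
        # 3 deg -> 2 * 700 * tan(1.5 deg) mm, per-axis mm/px conversion
        d_mm = 2 * geom.distance * math.tan(math.radians(1.5))
        expect_x = round(d_mm / geom.mm_per_px_x)
        expect_y = round(d_mm / geom.mm_per_px_y)
        assert expect_x == 133  # ~36.7 mm on a 531 mm / 1920 px panel
        src = layout["bitewing"].rect
        padded = {p.source: p for p in pad_aois(layout, geom, pad_deg=3.0)}
        got = padded["bitewing"].rect
        assert got[0] == src[0] - expect_x
        assert got[2] == src[2] + expect_x
        assert got[1] == src[1] - expect_y
        assert got[3] == src[3] + expect_y

    def test_clipped_to_screen_bounds(self, layout, geom):
        for p in pad_aois(layout, geom, pad_deg=3.0):
            x0, y0, x1, y1 = p.rect
            assert 0 <= x0 < x1 <= geom.res_x
            assert 0 <= y0 < y1 <= geom.res_y

    def test_disjoint_aois_overlap_after_padding(self, geom):
        layout = AOILayout(
            (
                AOI("bitewing", AOIRole.BITEWING, (100, 100, 500, 500)),
                AOI("panel", AOIRole.TOOLS, (600, 100, 900, 500)),
            )
        )
        padded = {p.source: p for p in pad_aois(layout, geom, pad_deg=3.0)}
        # gap is 100 px, pad is 133 px per side
        assert padded["bitewing"].rect[2] > padded["panel"].rect[0]

    def test_negative_pad_rejected(self, layout, geom):
        with pytest.raises(ValidationError):
            pad_aois(layout, geom, pad_deg=-1.0)

    def test_padding_monotonicity(self, layout, geom):
        """Increasing the pad never loses a fixation from any AOI."""
        rng = np.random.default_rng(5)
        fixes = [fix_at(rng.uniform(0, 1920), rng.uniform(0, 1080)) for _ in range(200)]
        prev = None
        for deg in (0.0, 1.0, 3.0, 6.0):
            padded = pad_aois(layout, geom, pad_deg=deg)
            counts = {
                p.source: sum(p.source in assign_fixation(f, padded) for f in fixes)
                for p in padded
            }
            if prev is not None:
                assert all(counts[k] >= prev[k] for k in counts)
            prev = counts


class TestAssignFixation:
    def test_bitewing_center_hit(self, layout, geom):
        padded = pad_aois(layout, geom)
        x0, y0, x1, y1 = layout["bitewing"].rect
        hit = assign_fixation(fix_at((x0 + x1) / 2, (y0 + y1) / 2), padded)
        assert hit == {"bitewing"}

    def test_overlap_hits_both(self, geom):
        layout = AOILayout(
            (
                AOI("bitewing", AOIRole.BITEWING, (100, 100, 600, 600)),
                AOI("overlay", AOIRole.OTHER, (500, 100, 900, 600)),
            )
        )
        padded = pad_aois(layout, geom, pad_deg=0.0)
        assert assign_fixation(fix_at(550, 300), padded) == {"bitewing", "overlay"}

    def test_outside_all_is_empty(self, geom):
        layout = AOILayout((AOI("bitewing", AOIRole.BITEWING, (100, 100, 600, 600)),))
        padded = pad_aois(layout, geom, pad_deg=0.0)
        assert assign_fixation(fix_at(1800, 1000), padded) == frozenset()

    def test_half_open_edges(self, geom):
        layout = AOILayout(
            (
                AOI("bitewing", AOIRole.BITEWING, (0, 0, 100, 100)),
                AOI("right", AOIRole.TOOLS, (100, 0, 200, 100)),
            )
        )
        padded = pad_aois(layout, geom, pad_deg=0.0)
        # the shared edge belongs to the right AOI only: no double hit
        assert assign_fixation(fix_at(100.0, 50.0), padded) == {"right"}


class TestComputeMetrics:
    def test_single_fixation_arithmetic(self, two_aoi_layout):
        rec = make_recording(t=np.arange(0, 10001, 100, dtype=float))  # 10 s task
        fixes = [fix_at(900, 500, onset=1000.0, dur=300.0)]
        asg = [frozenset({"bitewing"})]
        row = compute_metrics(fixes, asg, rec, two_aoi_layout)
        assert row.task_time == pytest.approx(10.0)
        assert row.fix_frequency == pytest.approx(0.1)
        assert row.prop_time_bitewing == pytest.approx(3.0)
        assert row.prop_time_ui == 0.0
        assert row.fix_count_bitewing == 1
        assert row.fix_count_ui == 0

    def test_all_outside_gives_zero_groups(self, two_aoi_layout):
        rec = make_recording(t=np.arange(0, 5001, 100, dtype=float))
        fixes = [fix_at(10, 10), fix_at(20, 20, onset=500.0)]
        asg = [frozenset(), frozenset()]
        row = compute_metrics(fixes, asg, rec, two_aoi_layout)
        assert row.total_fix_duration_ui == 0.0
        assert row.total_fix_duration_bitewing == 0.0
        assert row.fix_count_ui == row.fix_count_bitewing == 0
        assert row.fix_count_total == 2

    def test_no_fixations_avg_duration_is_missing(self, two_aoi_layout):
        rec = make_recording(t=np.arange(0, 5001, 100, dtype=float))
        row = compute_metrics([], [], rec, two_aoi_layout)
        assert math.isnan(row.avg_fix_duration)
        assert row.fix_count_total == 0

    def test_matches_accumulation_oracle(self, layout, geom):
        """Every field equals an independent per-fixation re-aggregation."""
        rng = np.random.default_rng(42)
        task_ms = 60000.0
        rec = make_recording(t=np.arange(0, task_ms + 1, 500, dtype=float))
        padded = pad_aois(layout, geom)
        fixes, onset = [], 0.0
        for _ in range(50):
            onset += rng.uniform(100, 900)
            fixes.append(
                fix_at(rng.uniform(0, 1920), rng.uniform(0, 1080), onset=onset, dur=rng.uniform(80, 600))
            )
        asg = assign_fixations(fixes, padded)
        row = compute_metrics(fixes, asg, rec, layout)

        ui = set(layout.names) - {"bitewing"}
        tot_ui = tot_bw = n_ui = n_bw = 0.0
        for f, a in zip(fixes, asg):
            if a & ui:
                tot_ui += f.duration
                n_ui += 1
            if "bitewing" in a:
                tot_bw += f.duration
                n_bw += 1
        assert row.total_fix_duration_ui == pytest.approx(tot_ui)
        assert row.total_fix_duration_bitewing == pytest.approx(tot_bw)
        assert row.fix_count_ui == n_ui
        assert row.fix_count_bitewing == n_bw
        assert row.avg_fix_duration == pytest.approx(np.mean([f.duration for f in fixes]))
        assert row.fix_frequency == pytest.approx(50 / 60.0)
        assert row.prop_time_ui == pytest.approx(tot_ui / task_ms * 100)
        assert 0 <= row.prop_time_ui <= 100 and 0 <= row.prop_time_bitewing <= 100

    def test_disjoint_aois_no_double_counting(self, geom):
        layout = AOILayout(
            (
                AOI("bitewing", AOIRole.BITEWING, (0, 0, 900, 1080)),
                AOI("panel", AOIRole.TOOLS, (1000, 0, 1920, 1080)),
            )
        )
        padded = pad_aois(layout, geom, pad_deg=0.0)
        rng = np.random.default_rng(3)
        fixes = [fix_at(rng.uniform(0, 1920), rng.uniform(0, 1080)) for _ in range(300)]
        asg = assign_fixations(fixes, padded)
        per_aoi = sum(len(a) for a in asg)
        inside = sum(1 for a in asg if a)
        assert per_aoi == inside  # no fixation hits two disjoint AOIs
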