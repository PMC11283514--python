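"""Synthetic-data generator: determinism, calibration and closure."""

import numpy as np
import pytest

from gazekit import (
    Condition,
    ValidationError,
    detect_fixations,
    generate_recording,
    generate_study,
    generate_toggles,
)
from gazekit.synth import ScanpathModel, ToggleModel, ai_scanpath_model, default_layout, no_ai_scanpath_model


class TestGenerateRecording:
    def test_same_seed_bitwise_identical(self):
        m = ai_scanpath_model()
        r1, t1 = generate_recording(m, 60000, seed=42)
        r2, t2 = generate_recording(m, 60000, seed=42)
        assert np.array_equal(r1.t, r2.t)
        assert np.array_equal(r1.x, r2.x)
        assert np.array_equal(r1.y, r2.y)
        assert np.array_equal(r1.quality, r2.quality)
        assert t1.fixations == t2.fixations

    def test_different_seeds_differ(self):
        m = ai_scanpath_model()
        r1, _ = generate_recording(m, 60000, seed=1)
        r2, _ = generate_recording(m, 60000, seed=2)
        assert not np.array_equal(r1.x, r2.x)

    def test_noiseless_single_aoi_exact_recovery(self):
        from gazekit import AOI, AOILayout, AOIRole

        layout = AOILayout((AOI("bitewing", AOIRole.BITEWING, (200, 200, 1700, 900)),))
        markov = {"bitewing": {"bitewing": 1.0}}
        m = ScanpathModel(
            layout=layout, dwell_markov=markov, sample_noise_deg=0.0, dropout_rate=0.0
        )
        rec, truth = generate_recording(m, 45000, seed=7)
        fixes = detect_fixations(rec)
        assert len(fixes) == len(truth.fixations)
        for f, t in zip(fixes, truth.fixations):
            assert f.onset == pytest.approx(t.onset)
            assert f.duration == pytest.approx(t.duration)
            assert f.cx == pytest.approx(t.cx)
            assert f.cy == pytest.approx(t.cy)

    def test_ground_truth_matches_sample_grid(self):
        m = ai_scanpath_model(dropout_rate=0.0)
        rec, truth = generate_recording(m, 30000, seed=3)
        dt = 1000.0 / m.rate
        for t in truth.fixations:
            assert t.onset / dt == pytest.approx(round(t.onset / dt))
            assert t.offset <= rec.t[-1]

    def test_median_duration_calibration(self):
        """Pooled generated fixation durations hit the configured median."""
        m = ai_scanpath_model(dropout_rate=0.0)
        durations = []
        rng = np.random.default_rng(123)
        while len(durations) < 10000:
            _, truth = generate_recording(m, 300000, rng)
            durations.extend(t.duration for t in truth.fixations)
        med = float(np.median(durations))
        assert abs(med - m.fix_duration_median) / m.fix_duration_median < 0.05

    def test_iqr_brackets_target_regime(self):
        # log-sd 0.30 should put the IQR around [250, 380] ms for a ~313 ms median
        m = ai_scanpath_model(dropout_rate=0.0)
        rng = np.random.default_rng(5)
        durations = []
        for _ in range(30):
            _, truth = generate_recording(m, 200000, rng)
            durations.extend(t.duration for t in truth.fixations)
        q1, q3 = np.percentile(durations, [25, 75])
        assert 220 < q1 < 290
        assert 340 < q3 < 420

    def test_degenerate_task_time_rejected(self):
        with pytest.raises(ValidationError):
            generate_recording(ai_scanpath_model(), 50, seed=0)

    def test_invalid_markov_rejected(self):
        with pytest.raises(ValidationError, match="sums to"):
            ScanpathModel(
                layout=default_layout(),
                dwell_markov={n: {n: 0.5} for n in default_layout().names},
            )


class TestGenerateToggles:
    def test_p_use_zero_empty_log(self):
        assert generate_toggles(ToggleModel(p_use=0.0), 60000, seed=0) == []

    def test_single_activation_when_rate_zero(self):
        events = generate_toggles(ToggleModel(n_activations_rate=0.0), 60000, seed=1)
        from gazekit import ToggleState

        assert sum(e.state is ToggleState.ON for e in events) == 1

    def test_mean_on_fraction_calibrated(self):
        """1000 seeded draws land within 3 points of the configured target."""
        tm = ToggleModel()
        rng = np.random.default_rng(77)
        pcts = []
        for _ in range(1000):
            events = generate_toggles(tm, 100000, rng)
            on = 0.0
            for a, b in zip(events[:-1], events[1:]):
                if a.state.value == "ON":
                    on += b.t - a.t
            if events and events[-1].state.value == "ON":
                on += 100000 - events[-1].t
            pcts.append(on / 100000 * 100)
        assert abs(np.mean(pcts) - tm.on_frac_target * 100) < 3.0

    def test_first_on_near_configured_fraction(self):
        tm = ToggleModel()
        rng = np.random.default_rng(11)
        firsts = [generate_toggles(tm, 80000, rng)[0].t / 80000 for _ in range(500)]
        assert abs(np.mean(firsts) - tm.first_on_mean) < 0.05


class TestGenerateStudy:
    def test_study_shape_and_funnel_inputs(self):
        study = generate_study(n_participants=22, images_per_participant=20, seed=0)
        assert study.n_recordings == 445  # 440 views + 5 accidental first views
        mains = [r for r in study.recordings if r.recording_index == 1]
        assert len(mains) == 440
        n_ai = sum(r.condition is Condition.AI for r in mains)
        assert n_ai == 220
        assert len(study.error_flags) == 11
        # every AI recording has a toggle log entry
        for r in study.recordings:
            if r.condition is Condition.AI:
                assert r.key in study.toggles

    def test_no_quality_degradation_when_fraction_zero(self):
        from gazekit import apply_exclusions, funnel_counts
        from gazekit.qc import STATUS_QUALITY

        study = generate_study(
            n_participants=4,
            images_per_participant=6,
            seed=1,
            low_quality_fraction=0.0,
            n_duplicate_first_views=0,
            n_stimulus_errors=0,
        )
        f = funnel_counts(apply_exclusions(study.recordings, error_flags=study.error_flags))
        assert f[STATUS_QUALITY] == 0
        assert f["included"] == f["total"]

    def test_study_determinism(self):
        s1 = generate_study(n_participants=3, images_per_participant=4, seed=9)
        s2 = generate_study(n_participants=3, images_per_participant=4, seed=9)
        assert s1.n_recordings == s2.n_recordings
        for a, b in zip(s1.recordings, s2.recordings):
            assert a.key == b.key
            assert np.array_equal(a.x, b.x)
        assert s1.toggles == s2.toggles
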