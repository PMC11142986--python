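import numpy as np
import pytest

from coregload import gaze
from coregload.types import BlinkEvent, FixationEvent, SaccadeEvent


class TestInterpolateBlinks:
    def test_no_sentinel_identity(self, rng):
        pupil = rng.uniform(3, 5, size=500)
        out, blinks = gaze.interpolate_blinks(pupil, 250.0)
        np.testing.assert_array_equal(out, pupil)
        assert blinks == []

    def test_constant_trace_filled_with_constant(self):
        pupil = np.full(1000, 5.0)
        pupil[400:425] = 0.0  # 100 ms at 250 Hz
        out, blinks = gaze.interpolate_blinks(pupil, 250.0)
        np.testing.assert_allclose(out, 5.0)
        assert len(blinks) == 1
        assert (blinks[0].onset, blinks[0].offset) == (400, 425)

    def test_linear_fill_between_boundaries(self):
        pupil = np.concatenate([np.full(100, 2.0), np.full(100, 4.0)])
        pupil[95:105] = 0.0
        out, _ = gaze.interpolate_blinks(pupil, 1000.0, pad_ms=0.0)
        # straight line between samples 94 (2.0) and 105 (4.0)
        expected = 2.0 + (np.arange(95, 105) - 94) / (105 - 94) * 2.0
        np.testing.assert_allclose(out[95:105], expected)

    def test_edge_run_filled_with_nearest(self):
        pupil = np.full(100, 3.0)
        pupil[:10] = 0.0
        pupil[90:] = 0.0
        out, blinks = gaze.interpolate_blinks(pupil, 250.0, pad_ms=0.0)
        np.testing.assert_allclose(out, 3.0)
        assert len(blinks) == 2

    def test_untouched_samples_bit_identical(self, rng):
        pupil = rng.uniform(3, 5, size=1000)
        pupil[300:350] = 0.0
        out, _ = gaze.interpolate_blinks(pupil, 250.0, pad_ms=20.0)
        pad = int(0.020 * 250)
        outside = np.ones(1000, dtype=bool)
        outside[300 - pad: 350 + pad] = False
        np.testing.assert_array_equal(out[outside], pupil[outside])

    def test_idempotent(self, rng):
        pupil = rng.uniform(3, 5, size=1000)
        pupil[100:130] = 0.0
        pupil[700:740] = 0.0
        once, _ = gaze.interpolate_blinks(pupil, 250.0)
        twice, blinks2 = gaze.interpolate_blinks(once, 250.0)
        np.testing.assert_array_equal(once, twice)
        assert blinks2 == []

    def test_all_sentinel_error(self):
        with pytest.raises(ValueError, match="no valid"):
            gaze.interpolate_blinks(np.zeros(100), 250.0)

    def test_simulator_blink_recovery(self, reading_session):
        cfg, eeg, et, eeg_ev, et_ev, truth = reading_session
        _, blinks = gaze.interpolate_blinks(et.channel("pupil"), et.rate, pad_ms=50.0)
        assert len(blinks) == len(truth.true_blinks)
        pad_samples = int(0.050 * et.rate)
        for det, (on, off) in zip(blinks, truth.true_blinks):
            assert abs(det.onset - on) <= pad_samples
            assert abs(det.offset - off) <= pad_samples


def _reference_saccade_runs(vx, vy, lam, rate, min_ms):
    """Brute-force loop re-implementation of the elliptic threshold rule."""

    def med_sd(v):
        return np.sqrt(np.median(v**2) - np.median(v) ** 2)

    ex, ey = lam * med_sd(vx), lam * med_sd(vy)
    mask = (vx / ex) ** 2 + (vy / ey) ** 2 > 1.0
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return [r for r in runs if (r[1] - r[0]) / rate * 1000 >= min_ms]


class TestDetectSaccades:
    def test_constant_gaze_no_saccades(self):
        out = gaze.detect_saccades(np.full(500, 3.0), np.full(500, 7.0), 250.0)
        assert out == []

    def test_short_trace_error(self):
        with pytest.raises(ValueError, match="smooth_window"):
            gaze.detect_saccades(np.zeros(3), np.zeros(3), 250.0)

    def test_single_step_detected_once(self, rng):
        """One smooth 10-degree (300 px) displacement in 1 s of jittered
        fixation; brute-force thresholding on the same velocities is the
        oracle for the event boundaries."""
        rate, n = 250.0, 250
        x = 100.0 + rng.normal(0, 0.5, n)
        y = 200.0 + rng.normal(0, 0.5, n)
        ramp = np.arange(120, 130)
        x[ramp] += 300.0 * (ramp - 119) / 10.0
        x[130:] += 300.0
        events = gaze.detect_saccades(x, y, rate, min_duration_ms=12.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.onset <= 120 and ev.offset >= 129
        assert ev.amplitude == pytest.approx(300.0, abs=10.0)
        # oracle comparison on the identical velocity series
        from coregload.gaze import _window_velocity

        vx = _window_velocity(x, rate, 5)
        vy = _window_velocity(y, rate, 5)
        runs = _reference_saccade_runs(vx, vy, 6.0, rate, 12.0)
        assert len(runs) == 1
        assert (ev.onset, ev.offset) == runs[0]

    def test_scale_equivariance_exact(self, rng):
        rate, n = 250.0, 1000
        x = np.cumsum(rng.normal(0, 1, n))
        y = np.cumsum(rng.normal(0, 1, n))
        x[500:520] += np.linspace(0, 200, 20)
        base = gaze.detect_saccades(x, y, rate)
        for c in (0.25, 3.0, 117.0):
            scaled = gaze.detect_saccades(c * x, c * y, rate)
            assert [(s.onset, s.offset) for s in scaled] == [
                (s.onset, s.offset) for s in base
            ]

    def test_simulator_recovery(self, noblink_session):
        cfg, eeg, et, eeg_ev, et_ev, truth = noblink_session
        detected = gaze.detect_saccades(
            et.channel("gaze_x"), et.channel("gaze_y"), et.rate
        )
        big = [s for s in truth.true_saccades if s[2] / cfg.px_per_deg >= 1.0]
        hits = 0
        for on, off, amp in big:
            err = min(abs(d.onset - on) for d in detected)
            if err / et.rate * 1000.0 <= 8.0:
                hits += 1
        assert hits / len(big) >= 0.95


class TestDeriveFixations:
    def test_no_events_single_fixation(self):
        fx = gaze.derive_fixations([], [], 250.0, (0, 1000))
        assert len(fx) == 1
        assert (fx[0].onset, fx[0].offset) == (0, 1000)

    def test_one_saccade_two_fixations(self):
        sac = [SaccadeEvent(400, 420, peak_velocity=500.0, amplitude=50.0)]
        fx = gaze.derive_fixations(sac, [], 250.0, (0, 1000))
        assert [(f.onset, f.offset) for f in fx] == [(0, 400), (420, 1000)]

    def test_short_intervals_dropped(self):
        sac = [
            SaccadeEvent(100, 110, 1.0, 1.0),
            SaccadeEvent(112, 130, 1.0, 1.0),  # 2-sample gap -> dropped
        ]
        fx = gaze.derive_fixations(sac, [], 250.0, (0, 300), min_fix_ms=50.0)
        assert [(f.onset, f.offset) for f in fx] == [(0, 100), (130, 300)]

    def test_overlapping_events_error(self):
        sac = [SaccadeEvent(100, 150, 1.0, 1.0)]
        blk = [BlinkEvent(140, 180)]
        with pytest.raises(ValueError, match="overlapping"):
            gaze.derive_fixations(sac, blk, 250.0, (0, 300))

    def test_centroid_is_mean_gaze(self, rng):
        x = rng.uniform(0, 100, 200)
        y = rng.uniform(0, 100, 200)
        sac = [SaccadeEvent(50, 60, 1.0, 1.0)]
        fx = gaze.derive_fixations(
            sac, [], 250.0, (0, 200), gaze_x=x, gaze_y=y
        )
        assert fx[0].centroid[0] == pytest.approx(x[:50].mean())
        assert fx[1].centroid[1] == pytest.approx(y[60:].mean())

    def test_simulator_fixation_count(self, noblink_session):
        cfg, eeg, et, eeg_ev, et_ev, truth = noblink_session
        sacs = gaze.detect_saccades(et.channel("gaze_x"), et.channel("gaze_y"), et.rate)
        fx = gaze.derive_fixations(sacs, [], et.rate, (0, et.n_samples))
        n_true = len(truth.true_fixations)
        assert abs(len(fx) - n_true) / n_true <= 0.05


class TestAssignAoi:
    AOIS = [
        gaze.AOI("text", (0, 0, 100, 100)),
        gaze.AOI("picture", (200, 0, 300, 100)),
    ]

    def _fix(self, x, y):
        return FixationEvent(0, 10, 40.0, (x, y))

    def test_inside_picture(self):
        out = gaze.assign_aoi([self._fix(250, 50)], self.AOIS)
        assert out[0].aoi == "picture"

    def test_max_edge_half_open(self):
        assert gaze.assign_aoi([self._fix(100, 50)], self.AOIS)[0].aoi is None
        assert gaze.assign_aoi([self._fix(0, 0)], self.AOIS)[0].aoi == "text"

    def test_outside_all_none(self):
        assert gaze.assign_aoi([self._fix(150, 50)], self.AOIS)[0].aoi is None

    def test_overlapping_aois_error(self):
        bad = [gaze.AOI("a", (0, 0, 10, 10)), gaze.AOI("b", (5, 5, 15, 15))]
        with pytest.raises(ValueError, match="overlapping"):
            gaze.assign_aoi([], bad)

    def test_degenerate_rect_error(self):
        with pytest.raises(ValueError):
            gaze.AOI("x", (10, 0, 10, 5))


def _fix_seq(labels):
    return [
        FixationEvent(10 * i, 10 * i + 8, 32.0, (0.0, 0.0), aoi=lab)
        for i, lab in enumerate(labels)
    ]


def _brute_force_transitions(labels):
    return sum(
        1
        for a, b in zip(labels, labels[1:])
        if a is not None and b is not None and {a, b} == {"text", "picture"}
    )


class TestGazeMetrics:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (["text", "text", "text"], 0),
            (["text", "picture", "text"], 2),
            (["text", None, "picture"], 0),
        ],
    )
    def test_transition_rule(self, labels, expected):
        assert gaze.gaze_metrics(_fix_seq(labels)).n_transitions == expected

    def test_transitions_match_brute_force(self, rng):
        pool = ["text", "picture", None, "other"]
        for _ in range(50):
            labels = [pool[i] for i in rng.integers(0, 4, size=rng.integers(0, 15))]
            got = gaze.gaze_metrics(_fix_seq(labels)).n_transitions
            assert got == _brute_force_transitions(labels)

    def test_transition_bound_invariant(self, rng):
        pool = ["text", "picture", None]
        for _ in range(30):
            labels = [pool[i] for i in rng.integers(0, 3, size=rng.integers(1, 12))]
            m = gaze.gaze_metrics(_fix_seq(labels))
            n_labeled = sum(1 for lab in labels if lab is not None)
            if n_labeled >= 1:
                assert m.n_transitions <= max(0, n_labeled - 1)

    def test_counts_and_duration(self):
        fixes = _fix_seq(["text", "picture", "picture", None])
        m = gaze.gaze_metrics(fixes)
        assert m.n_fixations_per_aoi == {"text": 1, "picture": 2}
        assert m.mean_fixation_duration_ms == pytest.approx(32.0)

    def test_no_picture_fixations_nan_duration(self):
        m = gaze.gaze_metrics(_fix_seq(["text", None]))
        assert np.isnan(m.mean_fixation_duration_ms)
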