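"""Gaze processing: resampling, blink repair, event segmentation, mode
finding and goal labels."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from scsaliency.gaze import (GazeTrace, detect_saccades, extract_fixations,
                             interpolate_blinks, label_saccade_goal,
                             mean_shift_mode, resample_gaze, FixationEvent,
                             SaccadeEvent)


def _trace(x, y=None, rate=200.0, valid=None):
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size) * 1000.0 / rate
    return GazeTrace(t, x, np.zeros_like(x) if y is None else np.asarray(y, float), valid)


def _step_trace(amp=10.0, step_ms=30.0, rate=200.0, pre_ms=400.0, post_ms=400.0):
    """Stationary, smooth step over `step_ms`, stationary again."""
    dt = 1000.0 / rate
    n_pre, n_step, n_post = int(pre_ms / dt), int(step_ms / dt), int(post_ms / dt)
    ramp = amp * 0.5 * (1 - np.cos(np.pi * np.arange(1, n_step + 1) / n_step))
    x = np.concatenate([np.zeros(n_pre), ramp, np.full(n_post, amp)])
    return _trace(x, rate=rate)


class TestResample:
    def test_constant_trace(self):
        tr = _trace(np.full(1000, 3.0), np.full(1000, -2.0), rate=1000.0)
        out = resample_gaze(tr, 200.0)
        assert len(out) == 200
        assert np.all(out.x == 3.0) and np.all(out.y == -2.0)
        assert out.dt == pytest.approx(5.0)

    def test_decimation_picks_native_samples(self):
        x = np.arange(1000) / 100.0
        out = resample_gaze(_trace(x, rate=1000.0), 200.0)
        assert np.array_equal(out.x, x[::5])

    def test_blink_span_propagates(self):
        valid = np.ones(1000, bool)
        valid[200:240] = False  # 40 ms at 1 kHz
        out = resample_gaze(_trace(np.zeros(1000), rate=1000.0, valid=valid), 200.0)
        assert int((~out.valid).sum()) == 8

    def test_nonuniform_rejected_with_gap_report(self):
        t = np.arange(100, dtype=float)
        t[50:] += 3.0
        tr = GazeTrace(t, np.zeros(100), np.zeros(100))
        with pytest.raises(ValueError, match="gap"):
            resample_gaze(tr, 100.0)


class TestBlinks:
    def test_midpoint(self):
        tr = _trace([1.0, 0.0, 3.0], valid=[True, False, True])
        out = interpolate_blinks(tr)
        assert out.x[1] == pytest.approx(2.0) and out.valid.all()

    def test_identity_when_clean(self):
        tr = _trace([1.0, 2.0, 3.0])
        out = interpolate_blinks(tr)
        assert np.array_equal(out.x, tr.x) and out.valid.all()

    def test_linear_fill(self):
        tr = _trace([0.0, 9, 9, 9, 4.0], valid=[True, False, False, False, True])
        out = interpolate_blinks(tr)
        assert np.allclose(out.x[1:4], [1.0, 2.0, 3.0])

    def test_boundary_span_stays_invalid(self):
        tr = _trace([9, 9, 1.0, 2.0], valid=[False, False, True, True])
        out = interpolate_blinks(tr)
        assert not out.valid[0] and not out.valid[1] and out.valid[2:].all()


class TestSaccadeDetection:
    def test_stationary_no_saccades(self):
        assert detect_saccades(_trace(np.zeros(500))) == []

    def test_step_detected_with_amplitude(self):
        sacs = detect_saccades(_step_trace(amp=10.0, step_ms=30.0))
        assert len(sacs) == 1
        # displacement between threshold crossings: the slow tails of the
        # movement fall below criterion, so a small underestimate is expected
        assert sacs[0].amplitude == pytest.approx(10.0, rel=0.1)
        assert sacs[0].peak_velocity > 300.0

    def test_small_jitter_fails_min_amp(self):
        # 0.5 deg step at ~60 deg/s peak: supra-threshold but sub-amplitude
        sacs = detect_saccades(_step_trace(amp=0.5, step_ms=15.0))
        assert sacs == []

    def test_threshold_monotonicity(self, rng):
        x = np.cumsum(rng.standard_normal(2000)) * 0.3
        tr = _trace(x)
        counts = [len(detect_saccades(tr, vel_thresh=v)) for v in (30, 50, 80, 150, 300)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestFixations:
    def _two_saccade_trace(self, gap_ms):
        dt = 5.0
        seg = lambda n, v: np.full(n, v)
        n_gap = int(gap_ms / dt)
        x = np.concatenate([seg(60, 0.0),
                            10 * 0.5 * (1 - np.cos(np.pi * np.arange(1, 7) / 6)),
                            seg(n_gap, 10.0),
                            10 + 10 * 0.5 * (1 - np.cos(np.pi * np.arange(1, 7) / 6)),
                            seg(60, 20.0)])
        return _trace(x)

    def test_inter_saccadic_fixation_duration(self):
        tr = self._two_saccade_trace(350.0)
        sacs = detect_saccades(tr)
        assert len(sacs) == 2
        fixs = extract_fixations(tr, sacs)
        mids = [f for f in fixs if f.next_saccade is sacs[1]]
        assert len(mids) == 1 and not mids[0].excluded
        assert mids[0].duration == pytest.approx(350.0, abs=15.0)

    def test_short_fixation_flagged_excluded(self):
        tr = self._two_saccade_trace(150.0)
        sacs = detect_saccades(tr)
        fixs = extract_fixations(tr, sacs)
        mid = [f for f in fixs if f.next_saccade is sacs[1]][0]
        assert mid.excluded

    def test_final_fixation_has_no_next_saccade(self):
        tr = self._two_saccade_trace(350.0)
        fixs = extract_fixations(tr, detect_saccades(tr))
        assert fixs[-1].next_saccade is None

    def test_partition_no_overlap(self):
        tr = self._two_saccade_trace(400.0)
        sacs = detect_saccades(tr)
        fixs = extract_fixations(tr, sacs)
        spans = sorted([(s.t_on, s.t_off) for s in sacs] + [(f.t_on, f.t_off) for f in fixs])
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert b0 == pytest.approx(a1)
        assert spans[0][0] == tr.t[0] and spans[-1][1] == tr.t[-1]


def test_event_recovery_on_synthetic_gaze():
    """Planted saccades/fixations are recovered (>=95%, onset within 10 ms)."""
    from scsaliency.retina import ScreenGeometry
    from scsaliency.synth import SceneScript, simulate_gaze

    trace, log = simulate_gaze(SceneScript(), ScreenGeometry(), 60_000.0,
                               p_salient=0.0, seed=5)
    sacs = detect_saccades(trace)
    # planted saccade onsets are the fixation ends
    planted = log["t_off"].to_numpy()[:-1]
    hits = sum(1 for p in planted if np.min(np.abs(np.array([s.t_on for s in sacs]) - p)) <= 10.0)
    assert hits / planted.size >= 0.95


class TestMeanShift:
    def test_dominant_cluster_with_outliers(self, rng):
        pts = np.vstack([rng.normal([5.0, 5.0], 0.1, (50, 2)),
                         rng.normal([0.0, 0.0], 0.05, (3, 2))])
        mode = mean_shift_mode(pts)
        assert mode is not None
        assert np.hypot(mode[0] - 5.0, mode[1] - 5.0) < 0.2

    def test_single_point(self):
        assert mean_shift_mode(np.array([[1.0, 2.0]])) == (1.0, 2.0)

    def test_tied_clusters_rejected(self):
        a = np.tile([0.0, 0.0], (25, 1))
        b = np.tile([10.0, 0.0], (25, 1))
        assert mean_shift_mode(np.vstack([a, b])) is None


class TestGoalLabel:
    def _fix(self, direction_deg):
        sac = SaccadeEvent(0.0, 30.0, (0.0, 0.0),
                           (5 * np.cos(np.deg2rad(direction_deg)),
                            5 * np.sin(np.deg2rad(direction_deg))),
                           5.0, direction_deg)
        return FixationEvent(t_on=-300.0, t_off=0.0, xy=(0.0, 0.0), next_saccade=sac)

    @pytest.mark.parametrize("direction,expected", [
        (0.0, "in"), (180.0, "opposite"), (90.0, "other"), (44.0, "in"),
        (46.0, "other"), (136.0, "opposite"),
    ])
    def test_cone_geometry(self, direction, expected):
        assert label_saccade_goal(self._fix(direction), (8.0, 0.0)).value == expected

    def test_reflection_swaps_in_opposite(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            rf = rng.uniform(-10, 10, 2)
            if np.hypot(*rf) < 2.5:
                continue
            d = rng.uniform(-180, 180)
            a = label_saccade_goal(self._fix(d), tuple(rf)).value
            b = label_saccade_goal(self._fix(d), tuple(-rf)).value
            swap = {"in": "opposite", "opposite": "in", "other": "other"}
            assert b == swap[a]

    def test_foveal_rf_rejected(self):
        with pytest.raises(ValueError):
            label_saccade_goal(self._fix(0.0), (1.0, 0.5))

    def test_hemifield_mode_has_no_other(self):
        lab = label_saccade_goal(self._fix(90.0), (8.0, 0.0), mode="hemifield")
        assert lab.value in ("in", "opposite")


@given(st.integers(0, 2**31 - 1))
def test_velocity_threshold_monotone_property(seed):
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.standard_normal(400)) * 0.4
    tr = _trace(x)
    n_lo = len(detect_saccades(tr, vel_thresh=40.0))
    n_hi = len(detect_saccades(tr, vel_thresh=120.0))
    assert n_hi <= n_lo
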