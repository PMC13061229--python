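"""Window extraction and OR scoring: examples, boundaries, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apparency.io import BeatSeries, StimulusEvent
from apparency.orienting import (
    WindowPair,
    compute_or,
    extract_window_pair,
    null_salience_rate,
    score_events,
)


def grid_beats(spacing_pre=800.0, spacing_post=760.0, n_pre=6, n_post=6):
    """Beat times with constant pre spacing up to t=n_pre*spacing_pre, then
    constant post spacing."""
    onset = n_pre * spacing_pre
    pre = np.arange(n_pre + 1) * spacing_pre
    post = onset + np.arange(1, n_post + 1) * spacing_post
    return BeatSeries("p01", np.concatenate([pre, post])), onset


class TestWindowExtraction:
    def test_grid_example(self):
        beats, onset = grid_beats()
        pair = extract_window_pair(beats, onset)
        assert pair.complete
        np.testing.assert_allclose(pair.pre_rri_ms, [800.0] * 5)
        np.testing.assert_allclose(pair.post_rri_ms, [760.0] * 5)

    def test_insufficient_pre_intervals(self):
        beats = BeatSeries("p01", np.arange(0, 9) * 800.0)
        pair = extract_window_pair(beats, 2000.0)
        assert not pair.complete

    def test_onset_outside_recording_is_incomplete_not_error(self):
        beats = BeatSeries("p01", np.arange(0, 20) * 800.0)
        assert not extract_window_pair(beats, -5000.0).complete
        assert not extract_window_pair(beats, 1e9).complete

    def test_straddling_interval_belongs_to_neither_window(self):
        # distinct interval lengths 700, 710, ..., 840 so membership is visible
        rri = 700.0 + 10.0 * np.arange(15)
        t = np.concatenate([[0.0], np.cumsum(rri)])
        beats = BeatSeries("p01", t)
        onset = (t[7] + t[8]) / 2.0  # strictly inside interval 7
        pair = extract_window_pair(beats, onset)
        assert pair.complete
        # pre = intervals 2..6 (each ends at or before the onset),
        # post = intervals 8..12 (each begins at or after the onset);
        # the straddling interval 7 (length 770) is in neither
        np.testing.assert_allclose(pair.pre_rri_ms, rri[2:7])
        np.testing.assert_allclose(pair.post_rri_ms, rri[8:13])
        assert 770.0 not in pair.pre_rri_ms and 770.0 not in pair.post_rri_ms

    def test_tie_at_onset_interval_ending_at_onset_is_pre(self):
        beats, onset = grid_beats()
        pair = extract_window_pair(beats, onset)  # onset coincides with a beat
        # interval ending exactly at onset (spacing 800) is the last pre;
        # interval beginning exactly at onset (spacing 760) is the first post
        assert pair.pre_rri_ms[-1] == 800.0
        assert pair.post_rri_ms[0] == 760.0

    def test_max_span_limits_window_reach(self):
        # five 800 ms intervals span 4000 ms; a 3000 ms cap must reject them
        beats = BeatSeries("p01", np.arange(0, 16) * 800.0)
        onset = float(beats.beat_times_ms[8])
        assert extract_window_pair(beats, onset, max_span_ms=15000.0).complete
        assert not extract_window_pair(beats, onset, max_span_ms=3000.0).complete

    def test_recording_gap_invalidates_bridging_window(self):
        # an hour-long recording gap is an implausible interval: any window
        # containing it is invalid even though searchsorted would bridge it
        t = np.concatenate([np.arange(8) * 800.0, 3_600_000 + np.arange(12) * 800.0])
        beats = BeatSeries("p01", t)
        onset = 3_600_000 + 2 * 800.0  # only 2 intervals after the gap
        pair = extract_window_pair(beats, onset)
        assert not pair.complete

    def test_artifact_interval_invalidates_window(self):
        t = np.arange(0, 18) * 800.0
        t[7:] += 1500.0  # one 2300 ms interval inside the pre window
        beats = BeatSeries("p01", t)
        pair = extract_window_pair(beats, t[11])
        assert not pair.complete
        assert compute_or(pair).label == "invalid"


class TestComputeOr:
    def test_hand_computed_example(self):
        pair = WindowPair(
            np.array([800.0, 810.0, 790.0, 805.0, 795.0]),
            np.array([760.0, 765.0, 770.0, 755.0, 750.0]),
            0.0,
            True,
        )
        m = compute_or(pair)
        assert m.m1_ms == pytest.approx(800.0)
        assert m.m2_ms == pytest.approx(760.0)
        assert m.sd_ms == pytest.approx(7.9057, abs=1e-4)
        assert m.or_value == pytest.approx(5.0596, abs=1e-4)
        assert m.label == "acceleration"

    def test_identical_windows_are_unnoticed(self):
        w = np.array([800.0, 810.0, 790.0, 805.0, 795.0])
        m = compute_or(WindowPair(w, w.copy(), 0.0, True))
        assert m.or_value == 0.0 and m.label == "unnoticed"

    def test_zero_variance_pre_window_is_invalid(self):
        pre = np.full(5, 800.0)
        post = np.array([760.0, 765.0, 770.0, 755.0, 750.0])
        m = compute_or(WindowPair(pre, post, 0.0, True))
        assert m.label == "invalid" and np.isnan(m.or_value)

    def test_threshold_is_strict(self):
        pre = np.array([799.0, 800.0, 801.0])  # sd exactly 1
        m = compute_or(WindowPair(pre, np.full(3, 798.0), 0.0, True))
        assert m.or_value == 2.0 and m.label == "unnoticed"
        m = compute_or(WindowPair(pre, np.full(3, 802.0), 0.0, True))
        assert m.or_value == -2.0 and m.label == "unnoticed"

    def test_incomplete_pair_is_invalid(self):
        m = compute_or(WindowPair(np.array([800.0]), np.array([800.0]), 0.0, False))
        assert m.label == "invalid"

    @given(
        st.lists(st.floats(600, 1200), min_size=5, max_size=5),
        st.lists(st.floats(600, 1200), min_size=5, max_size=5),
        st.floats(-200, 200),
        st.floats(0.1, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_shift_and_scale_invariance(self, pre, post, shift, scale):
        pre = np.asarray(pre)
        post = np.asarray(post)
        base = compute_or(WindowPair(pre, post, 0.0, True))
        shifted = compute_or(WindowPair(pre + shift, post + shift, 0.0, True))
        scaled = compute_or(WindowPair(pre * scale, post * scale, 0.0, True))
        if base.label == "invalid":
            assert shifted.label == "invalid" and scaled.label == "invalid"
        else:
            assert shifted.or_value == pytest.approx(base.or_value, rel=1e-6)
            assert scaled.or_value == pytest.approx(base.or_value, rel=1e-6)

    def test_sign_convention_shorter_post_is_acceleration(self):
        """Shorter post-stimulus RR intervals = faster heart rate = OR > 0."""
        pre = np.array([800.0, 810.0, 790.0, 805.0, 795.0])
        m = compute_or(WindowPair(pre, pre - 100.0, 0.0, True))
        assert m.or_value > 2 and m.label == "acceleration"
        m = compute_or(WindowPair(pre, pre + 100.0, 0.0, True))
        assert m.or_value < -2 and m.label == "deceleration"


class TestScoreEvents:
    def test_no_events_empty_result(self):
        beats = BeatSeries("p01", np.arange(0, 20) * 800.0)
        assert score_events(beats, []) == []

    def test_participant_mismatch_is_error(self):
        beats = BeatSeries("p01", np.arange(0, 20) * 800.0)
        e = StimulusEvent("p02", "M01", 8000.0, "A", 1)
        with pytest.raises(ValueError, match="p02"):
            score_events(beats, [e])

    def test_every_complete_event_gets_a_definite_label(self):
        rng = np.random.default_rng(2)
        t = np.concatenate([[0.0], np.cumsum(rng.normal(850, 25, 400))])
        beats = BeatSeries("p01", t)
        events = [
            StimulusEvent("p01", "M01", float(t[20 * (i + 1)] + 1), "A", 1, i)
            for i in range(16)
        ]
        ms = score_events(beats, events)
        assert len(ms) == 16
        assert all(
            m.label in ("acceleration", "deceleration", "unnoticed") for m in ms
        )

    def test_injected_shift_recovers_expected_or(self):
        """A -40 ms shift on the 5 post-onset beats with 8 ms pre noise gives
        OR on the delta/sigma = 5 scale and an acceleration label.

        The mean OR exceeds 5 by the small-sample reciprocal-SD bias:
        E[sigma/S] = sqrt(2)*Gamma(3/2)/Gamma(2) ~ 1.2533 at k = 5, so
        E[OR] ~ 5 * 1.2533 = 6.27.
        """
        rng = np.random.default_rng(4)
        ors = []
        for _ in range(200):
            rri = rng.normal(850, 8, 30)
            t = np.concatenate([[0.0], np.cumsum(rri)])
            onset = float(t[15]) + 1.0
            b = 16  # first beat at/after onset
            rri2 = rri.copy()
            rri2[b : b + 5] -= 40.0
            beats = BeatSeries("p01", np.concatenate([[0.0], np.cumsum(rri2)]))
            m = score_events(beats, [StimulusEvent("p01", "M01", onset, "A", 1)])[0]
            ors.append(m.or_value)
        expected = 5.0 * np.sqrt(2) * 0.8862269254527581  # 5 * E[sigma/S]
        assert np.mean(ors) == pytest.approx(expected, abs=0.6)
        assert np.mean([o > 2 for o in ors]) > 0.95

    def test_deterministic_given_inputs(self):
        rng = np.random.default_rng(6)
        t = np.concatenate([[0.0], np.cumsum(rng.normal(850, 25, 200))])
        beats = BeatSeries("p01", t)
        events = [StimulusEvent("p01", "M01", float(t[50] + 3), "A", 1)]
        a = score_events(beats, events)
        b = score_events(beats, events)
        assert a[0] == b[0]


def test_closed_form_null_rate_value():
    """P(|OR| > 2) under the Gaussian null equals 2*SF_t4(sqrt(10)) ~ 0.0341."""
    from scipy import stats

    assert null_salience_rate() == pytest.approx(
        2 * stats.t.sf(np.sqrt(10), 4), rel=1e-12
    )
    assert null_salience_rate() == pytest.approx(0.0341, abs=5e-4)
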