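"""Apparency rates, pooled response ratios, diurnal pairing, bathing rule."""

import numpy as np
import pandas as pd
import pytest

from apparency.aggregate import (
    compute_apparency,
    diurnal_split,
    interpolate_bathing_hour,
    response_ratios,
    round_half_up,
)
from apparency.protocol import DEFAULT_LAYOUT, HOUR_MS

from conftest import make_measurements


def _labels(n_acc, n_dec, n_unnoticed, n_invalid=0):
    return (
        ["acceleration"] * n_acc
        + ["deceleration"] * n_dec
        + ["unnoticed"] * n_unnoticed
        + ["invalid"] * n_invalid
    )


class TestComputeApparency:
    def test_fourteen_valid_two_acc_two_dec(self):
        rows = [("p01", "M01", 1, "A", lab) for lab in _labels(2, 2, 10)]
        out = compute_apparency(make_measurements(rows), scope="period")
        assert len(out) == 1
        r = out.iloc[0]
        assert r["n_valid"] == 14 and r["n_salient"] == 4
        assert r["apparency_pct"] == pytest.approx(100 * 4 / 14, abs=1e-9)
        assert r["apparency_pct"] == pytest.approx(28.571, abs=1e-3)

    def test_all_unnoticed_gives_zero(self):
        rows = [("p01", "M01", 1, "A", "unnoticed")] * 14
        out = compute_apparency(make_measurements(rows))
        assert out.iloc[0]["apparency_pct"] == 0.0

    def test_invalid_excluded_from_both_numerator_and_denominator(self):
        rows = [("p01", "M01", 1, "A", lab) for lab in _labels(2, 1, 9, 2)]
        out = compute_apparency(make_measurements(rows))
        r = out.iloc[0]
        assert r["n_valid"] == 12 and r["n_salient"] == 3
        assert r["apparency_pct"] == pytest.approx(25.0)

    def test_zero_valid_flagged_undefined(self):
        rows = [("p01", "M01", 1, "A", "invalid")] * 3
        out = compute_apparency(make_measurements(rows))
        r = out.iloc[0]
        assert not r["defined"] and np.isnan(r["apparency_pct"])

    def test_percentages_sum_to_100_exactly(self):
        rows = [("p01", "M01", 1, "A", lab) for lab in _labels(3, 2, 9)]
        r = compute_apparency(make_measurements(rows)).iloc[0]
        assert r["acc_pct"] + r["dec_pct"] + r["unnoticed_pct"] == pytest.approx(
            100.0, abs=1e-9
        )

    def test_union_of_disjoint_scopes_is_count_weighted_mean(self):
        rows = [("p01", "M01", 1, "A", lab) for lab in _labels(3, 0, 4)] + [
            ("p01", "M01", 1, "D", lab) for lab in _labels(0, 1, 6)
        ]
        df = make_measurements(rows)
        by_seg = compute_apparency(df, scope="segment")
        overall = compute_apparency(df, scope="period").iloc[0]
        weighted = (
            by_seg["apparency_pct"] * by_seg["n_valid"]
        ).sum() / by_seg["n_valid"].sum()
        assert overall["apparency_pct"] == pytest.approx(weighted, abs=1e-9)

    def test_scope_filters(self):
        rows = [("p01", "M01", 1, "A", "acceleration"), ("p01", "M01", 2, "B", "unnoticed")]
        df = make_measurements(rows)
        only_p2 = compute_apparency(df, scope="period", period=2)
        assert len(only_p2) == 1 and only_p2.iloc[0]["period"] == 2
        evening = compute_apparency(df, scope="daypart", daypart="evening")
        assert set(evening["daypart"]) == {"evening"}


class TestResponseRatios:
    def test_all_unnoticed(self):
        rows = [("p01", "M01", 1, "A", "unnoticed")] * 10
        out = response_ratios(make_measurements(rows))
        r = out.iloc[0]
        assert (r["acc_pct"], r["dec_pct"], r["unnoticed_pct"]) == (0.0, 0.0, 100.0)

    def test_pooled_counts_example(self):
        # 100 valid pooled over two participants: 16 acc / 15 dec / 69 unnoticed
        rows = [("p01", "M01", 1, "A", lab) for lab in _labels(10, 5, 35)] + [
            ("p02", "M01", 1, "A", lab) for lab in _labels(6, 10, 34)
        ]
        r = response_ratios(make_measurements(rows)).iloc[0]
        assert r["n_valid"] == 100
        assert (r["acc_pct"], r["dec_pct"], r["unnoticed_pct"]) == (16.0, 15.0, 69.0)

    def test_pooling_counts_differs_from_participant_mean(self):
        # unbalanced valid counts: pooled != mean of per-participant percentages
        rows = [("p01", "M01", 1, "A", lab) for lab in _labels(1, 0, 1)] + [
            ("p02", "M01", 1, "A", lab) for lab in _labels(0, 0, 8)
        ]
        df = make_measurements(rows)
        pooled = response_ratios(df, pooling="counts").iloc[0]["acc_pct"]
        averaged = response_ratios(df, pooling="participants").iloc[0]["acc_pct"]
        assert pooled == pytest.approx(10.0)
        assert averaged == pytest.approx(25.0)

    def test_absent_sound_warns_and_is_omitted(self):
        rows = [("p01", "M01", 1, "A", "unnoticed")] * 5
        with pytest.warns(UserWarning, match="C16"):
            out = response_ratios(make_measurements(rows), sounds=["M01", "C16"])
        assert list(out["sound_code"]) == ["M01"]

    def test_rows_sum_to_100_after_one_decimal_rounding(self, small_scored):
        out = response_ratios(small_scored)
        for _, r in out.iterrows():
            total = (
                round_half_up(r["acc_pct"])
                + round_half_up(r["dec_pct"])
                + round_half_up(r["unnoticed_pct"])
            )
            # each rounded term errs by at most 0.05, so the rounded sum is
            # one of {99.9, 100.0, 100.1}
            assert total == pytest.approx(100.0, abs=0.1 + 1e-9)


class TestDiurnalSplit:
    def test_equal_rates_both_sides(self):
        rows = [("p01", "M01", 1, "A", lab) for lab in _labels(1, 1, 5)] + [
            ("p01", "M01", 1, "D", lab) for lab in _labels(2, 0, 5)
        ]
        out = diurnal_split(make_measurements(rows))
        r = out.iloc[0]
        assert r["daytime_pct"] == pytest.approx(100 * 2 / 7, abs=1e-9)
        assert r["evening_pct"] == pytest.approx(100 * 2 / 7, abs=1e-9)

    def test_missing_evening_excludes_participant(self):
        rows = [("p01", "M01", 1, "A", "acceleration")] * 7
        out = diurnal_split(make_measurements(rows))
        assert out.empty

    def test_all_zero(self):
        rows = [("p01", "M01", 1, "A", "unnoticed")] * 7 + [
            ("p01", "M01", 1, "D", "unnoticed")
        ] * 7
        r = diurnal_split(make_measurements(rows)).iloc[0]
        assert (r["daytime_pct"], r["evening_pct"]) == (0.0, 0.0)

    def test_pools_counts_across_periods_within_daypart(self):
        rows = [("p01", "M01", 1, "A", lab) for lab in _labels(1, 0, 6)] + [
            ("p01", "M01", 2, "C", lab) for lab in _labels(3, 0, 4)
        ] + [("p01", "M01", 1, "D", "unnoticed")] * 7
        r = diurnal_split(make_measurements(rows)).iloc[0]
        assert r["daytime_pct"] == pytest.approx(100 * 4 / 14, abs=1e-9)


class TestBathingRule:
    def _segment_b_measurements(self):
        """One participant, 6 physical stimulus hours in segment B (21:00
        bathing hour empty), one sound per hour."""
        seg = DEFAULT_LAYOUT.segments["B"]
        recs = []
        for hour in DEFAULT_LAYOUT.stimulus_hours("B"):
            start, _ = seg.hour_window_ms(hour)
            label = "acceleration" if hour == 6 else "unnoticed"  # 22:00 hour salient
            recs.append(
                {
                    "participant_id": "p01",
                    "sound_code": "M01",
                    "period": 1,
                    "segment": "B",
                    "onset_ms": start + 600_000.0,
                    "m1_ms": 800.0,
                    "m2_ms": 780.0,
                    "sd_ms": 10.0,
                    "or_value": 3.0 if label == "acceleration" else 1.0,
                    "label": label,
                }
            )
        return pd.DataFrame(recs)

    def test_duplication_restores_seven_presentations(self):
        df = interpolate_bathing_hour(self._segment_b_measurements())
        assert len(df) == 7
        assert df["interpolated"].sum() == 1
        dup = df[df["interpolated"]].iloc[0]
        lo, hi = DEFAULT_LAYOUT.bathing_window_ms
        assert lo <= dup["onset_ms"] < hi
        assert dup["label"] == "acceleration"  # copied from the 22:00 hour

    def test_bathing_onsets_are_dropped(self):
        df = self._segment_b_measurements()
        lo, _ = DEFAULT_LAYOUT.bathing_window_ms
        bath_row = df.iloc[[0]].assign(onset_ms=lo + 1000.0)
        out = interpolate_bathing_hour(pd.concat([df, bath_row], ignore_index=True))
        assert len(out) == 7  # the injected bathing-hour row vanished

    def test_disabled_rule_only_drops(self):
        df = interpolate_bathing_hour(self._segment_b_measurements(), enabled=False)
        assert len(df) == 6 and not df["interpolated"].any()

    def test_full_period_denominator_is_fourteen(self, small_scored):
        per = compute_apparency(small_scored, scope="period")
        assert (per["n_valid"] <= 14).all()
        # most cells keep the full denominator (losses only from window edges)
        assert (per["n_valid"] == 14).mean() > 0.9


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.05, 0.1), (2.25, 2.3), (2.24, 2.2), (28.5714, 28.6), (0.0, 0.0)],
    )
    def test_half_up(self, value, expected):
        assert round_half_up(value) == expected

    def test_array_input(self):
        np.testing.assert_allclose(round_half_up([0.05, 0.14]), [0.1, 0.1])
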