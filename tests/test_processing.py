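"""Cleaning chain: clock correction, filters, pairing, scope, labels."""

import numpy as np
import pandas as pd
import pytest

from codactivity import (
    ReceiverSpec,
    STANDARD_TAG,
    assign_depth_category,
    assign_season,
    correct_clock,
    dedup_multireceiver,
    filter_dead_fish,
    filter_single_daily,
    pair_depth,
    process_detections,
    restrict_scope,
    trim_high_rate,
)

T0 = 1.6121376e9  # 2021-02-01 UTC


def make_records(rows):
    """rows: (receiver, t_offset_s, fish, sensor, value)"""
    return pd.DataFrame(
        {
            "receiver_id": [r[0] for r in rows],
            "timestamp": [T0 + r[1] for r in rows],
            "fish_id": [r[2] for r in rows],
            "sensor": [r[3] for r in rows],
            "value": [float(r[4]) for r in rows],
        }
    )


class TestClockCorrection:
    def test_zero_drift_identity(self):
        rec = ReceiverSpec("A", T0, T0 + 1000.0, drift_total=0.0)
        records = make_records([("A", 500, "f", "depth", 10)])
        out = correct_clock(records, rec)
        assert out["timestamp"].iloc[0] == T0 + 500

    def test_midpoint_half_correction(self):
        rec = ReceiverSpec("A", T0, T0 + 1000.0, drift_total=2.0)
        records = make_records([("A", 500, "f", "depth", 10)])
        out = correct_clock(records, rec)
        assert out["timestamp"].iloc[0] == pytest.approx(T0 + 499.0)

    def test_endpoint_full_correction(self):
        rec = ReceiverSpec("A", T0, T0 + 1000.0, drift_total=2.0)
        records = make_records([("A", 1000, "f", "depth", 10)])
        out = correct_clock(records, rec)
        assert out["timestamp"].iloc[0] == pytest.approx(T0 + 998.0)

    def test_outside_deployment_passthrough_with_warning(self):
        rec = ReceiverSpec("A", T0, T0 + 1000.0, drift_total=5.0)
        records = make_records([("A", 2000, "f", "depth", 10)])
        with pytest.warns(UserWarning, match="outside"):
            out = correct_clock(records, rec)
        assert out["timestamp"].iloc[0] == T0 + 2000

    def test_monotone_order_preserved(self, rng):
        rec = ReceiverSpec("A", T0, T0 + 1e6, drift_total=40.0)
        t = np.sort(rng.uniform(0, 1e6, 500))
        records = make_records([("A", ti, "f", "depth", 10) for ti in t])
        out = correct_clock(records, rec)
        assert np.all(np.diff(out["timestamp"]) >= 0)


class TestDeadFish:
    def test_constant_depth_fish_fully_removed(self):
        rows = [("A", i * 3600, "f", "depth", 10.0) for i in range(72)]
        rows += [("A", i * 3600 + 100, "f", "accel", 1.0) for i in range(72)]
        out, log = filter_dead_fish(make_records(rows))
        assert len(out) == 0
        assert log["reason"].iloc[0] == "no_vertical_movement"

    def test_moving_fish_untouched(self):
        rows = [("A", i * 3600, "f", "depth", 10.0 + 5 * (i % 2)) for i in range(72)]
        out, log = filter_dead_fish(make_records(rows))
        assert len(out) == 72 and len(log) == 0

    def test_movement_cessation_truncates_tail(self):
        active = [("A", i * 3600, "f", "depth", 10.0 + 5 * (i % 2)) for i in range(240)]
        flat = [("A", (240 + i) * 3600, "f", "depth", 12.0) for i in range(30)]
        out, log = filter_dead_fish(make_records(active + flat))
        assert log["reason"].iloc[0] == "movement_ceased"
        # everything from the first flat record on is removed
        assert len(out) == 240
        assert out["timestamp"].max() < T0 + 240 * 3600

    def test_short_terminal_flat_stretch_kept(self):
        active = [("A", i * 3600, "f", "depth", 10.0 + 5 * (i % 2)) for i in range(240)]
        flat = [("A", (240 + i) * 3600, "f", "depth", 12.0) for i in range(10)]  # 10 h
        out, _ = filter_dead_fish(make_records(active + flat))
        assert len(out) == 250

    def test_fish_without_depth_records_dropped(self):
        rows = [("A", i * 3600, "f", "accel", 1.0) for i in range(48)]
        out, log = filter_dead_fish(make_records(rows))
        assert len(out) == 0
        assert log["reason"].iloc[0] == "no_depth_records"


class TestDedup:
    def test_echo_within_min_delay_collapsed(self):
        records = make_records(
            [("A", 0, "f", "accel", 1.5), ("B", 50, "f", "accel", 1.5)]
        )
        out = dedup_multireceiver(records, STANDARD_TAG)
        assert len(out) == 1
        assert out["receiver_id"].iloc[0] == "A"

    def test_same_value_beyond_min_delay_kept(self):
        records = make_records(
            [("A", 0, "f", "accel", 1.5), ("A", 250, "f", "accel", 1.5)]
        )
        out = dedup_multireceiver(records, STANDARD_TAG)
        assert len(out) == 2

    def test_different_sensor_or_value_not_grouped(self):
        records = make_records(
            [
                ("A", 0, "f", "accel", 1.5),
                ("B", 10, "f", "depth", 1.5),
                ("B", 20, "f", "accel", 1.6),
            ]
        )
        assert len(dedup_multireceiver(records, STANDARD_TAG)) == 3

    def test_idempotent(self, small_study):
        once = dedup_multireceiver(small_study.detections, STANDARD_TAG)
        twice = dedup_multireceiver(once, STANDARD_TAG)
        pd.testing.assert_frame_equal(once, twice)

    def test_perfect_recovery_against_truth(self, small_study):
        # with echoes only (no clock error), dedup recovers one record per
        # detected transmission
        det = small_study.detections.query("tx_id >= 0").copy()
        det["timestamp"] = det["true_time"]  # undistorted timestamps
        out = dedup_multireceiver(det, STANDARD_TAG)
        assert len(out) == det["tx_id"].nunique()


class TestSingleDaily:
    def test_lone_daily_detection_removed(self):
        rows = [("A", 3600, "f", "accel", 1.0)]  # single record on day 1
        rows += [("A", 86400 + i * 600, "f", "accel", 1.0) for i in range(50)]
        out = filter_single_daily(make_records(rows))
        assert len(out) == 50
        assert out["timestamp"].min() >= T0 + 86400

    def test_two_records_per_day_kept(self):
        rows = [("A", d * 86400 + h * 3600, "f", "depth", 5) for d in range(5) for h in (1, 2)]
        out = filter_single_daily(make_records(rows))
        assert len(out) == 10

    def test_local_midnight_boundary(self):
        # 22:30 and 23:30 UTC share a UTC day but straddle Oslo midnight
        # (UTC+1 in winter), so locally each is a lone daily detection
        rows = [("A", 22.5 * 3600, "f", "depth", 5), ("A", 23.5 * 3600, "f", "depth", 5)]
        out = filter_single_daily(make_records(rows), timezone="Europe/Oslo")
        assert len(out) == 0
        out_utc = filter_single_daily(make_records(rows), timezone="UTC")
        assert len(out_utc) == 2


class TestPairing:
    def test_nearest_depth_wins(self):
        records = make_records(
            [
                ("A", 1000 - 240, "f", "depth", 15.0),
                ("A", 1000, "f", "accel", 1.0),
                ("A", 1000 + 260, "f", "depth", 30.0),
            ]
        )
        pairs, stats = pair_depth(records)
        assert len(pairs) == 1
        assert pairs["depth"].iloc[0] == 15.0
        assert pairs["pair_gap"].iloc[0] == -240.0
        assert stats["pairing_fraction"] == 1.0

    def test_beyond_1800s_dropped(self):
        records = make_records(
            [("A", 0, "f", "depth", 15.0), ("A", 1900, "f", "accel", 1.0)]
        )
        pairs, stats = pair_depth(records)
        assert len(pairs) == 0
        assert stats["n_accel"] == 1

    def test_exact_tie_prefers_earlier(self):
        records = make_records(
            [
                ("A", 700, "f", "depth", 11.0),
                ("A", 1000, "f", "accel", 1.0),
                ("A", 1300, "f", "depth", 22.0),
            ]
        )
        pairs, _ = pair_depth(records)
        assert pairs["depth"].iloc[0] == 11.0

    def test_zero_gap_pairs(self):
        records = make_records(
            [("A", 1000, "f", "depth", 9.0), ("A", 1000, "f", "accel", 1.0)]
        )
        pairs, _ = pair_depth(records)
        assert pairs["pair_gap"].iloc[0] == 0.0

    def test_fish_without_depth_dropped(self):
        records = make_records(
            [("A", 0, "g", "depth", 9.0), ("A", 10, "f", "accel", 1.0)]
        )
        pairs, stats = pair_depth(records)
        assert len(pairs) == 0
        assert stats["dropped_by_fish"] == {"f": 1}


class TestScopeTrimSeason:
    def _pairs(self, rows):
        # rows: (t_offset, fish, accel, depth)
        return pd.DataFrame(
            {
                "fish_id": [r[1] for r in rows],
                "timestamp": [T0 + r[0] for r in rows],
                "accel": [r[2] for r in rows],
                "depth": [float(r[3]) for r in rows],
            }
        )

    def _meta(self):
        return pd.DataFrame(
            {
                "fish_id": ["f", "h"],
                "year": [2021, 2021],
                "tag_spec_name": ["standard", "high-rate-2024"],
            }
        )

    def test_depth_boundary_inclusive_at_60(self):
        pairs = self._pairs([(0, "f", 1.0, 60.0), (10, "f", 1.0, 61.0)])
        out = restrict_scope(pairs, self._meta())
        assert list(out["depth"]) == [60.0]

    def test_year_restriction(self):
        pairs = self._pairs([(0, "f", 1.0, 10.0), (400 * 86400, "f", 1.0, 10.0)])
        out = restrict_scope(pairs, self._meta())
        assert len(out) == 1

    def test_exclusion_windows(self):
        pairs = self._pairs([(0, "f", 1.0, 10.0), (5000, "f", 1.0, 10.0)])
        windows = pd.DataFrame({"start": [T0 + 4000], "end": [T0 + 6000]})
        out = restrict_scope(pairs, self._meta(), windows)
        assert len(out) == 1
        out2 = restrict_scope(pairs, self._meta(), None)
        assert len(out2) == 2

    @pytest.mark.parametrize("n,kept", [(100, 20), (4, 1), (11, 3)])
    def test_trim_high_rate_counts(self, n, kept):
        pairs = self._pairs([(i * 60, "h", 1.0, 10.0) for i in range(n)])
        out = trim_high_rate(pairs, self._meta())
        assert len(out) == kept

    def test_trim_leaves_standard_tags_alone(self):
        pairs = self._pairs([(i * 60, "f", 1.0, 10.0) for i in range(100)])
        out = trim_high_rate(pairs, self._meta())
        assert len(out) == 100

    @pytest.mark.parametrize(
        "iso,season",
        [
            ("2021-02-15", "spawning"),
            ("2021-03-31", "spawning"),
            ("2021-04-01", "omitted"),
            ("2021-01-20", "omitted"),
            ("2021-05-01", "feeding"),
            ("2021-12-31", "feeding"),
        ],
    )
    def test_assign_season(self, iso, season):
        t = pd.Timestamp(iso, tz="UTC").timestamp()
        pairs = pd.DataFrame({"timestamp": [t], "fish_id": ["f"], "depth": [10.0]})
        assert assign_season(pairs)["season"].iloc[0] == season

    def test_depth_category_boundary(self):
        pairs = pd.DataFrame(
            {"timestamp": [T0] * 3, "fish_id": ["f"] * 3, "depth": [19.9, 20.0, 20.1]}
        )
        out = assign_depth_category(pairs)
        assert list(out["depth_category"]) == ["shallow", "deep", "deep"]


class TestFullChain:
    def test_ledger_reconciles(self, small_study):
        pairs, ledger, stats = process_detections(
            small_study.detections_public,
            small_study.fish,
            small_study.receivers,
        )
        assert (ledger["n_in"] - ledger["n_out"] == ledger["n_removed"]).all()
        assert (ledger["n_removed"] >= 0).all()
        assert len(pairs) > 0
        assert {"season", "depth_category", "pair_gap"} <= set(pairs.columns)

    def test_pair_gaps_concentrate_at_tag_delay(self, small_study):
        pairs, _, _ = process_detections(
            small_study.detections_public, small_study.fish, small_study.receivers
        )
        gaps = pairs["pair_gap"].abs()
        # the neighbouring depth transmission sits one tag delay away
        assert 150 <= gaps.median() <= 350

    def test_input_frame_not_mutated(self, small_study):
        before = small_study.detections_public
        snapshot = before.copy(deep=True)
        process_detections(before, small_study.fish, small_study.receivers)
        pd.testing.assert_frame_equal(before, snapshot)
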