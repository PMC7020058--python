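"""Tests of the keypoint and annotation file dialects."""

import numpy as np
import pytest

from bitekit.analytics import MealSummary, meal_summary
from bitekit.keypoint_io import (
    AnnotationLog,
    KeypointIOError,
    KeypointSequence,
    SchemaError,
    read_annotations,
    read_keypoints,
    write_annotations,
    write_behavior_log,
    write_keypoints,
)
from bitekit.synth import SimConfig, simulate_meal


@pytest.mark.parametrize("dialect", ["json_frames", "csv_flat"])
class TestKeypointRoundTrip:
    def test_write_read_identity(self, dialect, noisy_meal, tmp_path):
        (seq, _), _ = noisy_meal
        path = tmp_path / "kp"
        write_keypoints(seq, path, dialect)
        assert read_keypoints(path, dialect) == seq

    def test_write_read_write_byte_identity(self, dialect, noisy_meal, tmp_path):
        (seq, _), _ = noisy_meal
        p1, p2 = tmp_path / "a", tmp_path / "b"
        write_keypoints(seq, p1, dialect)
        write_keypoints(read_keypoints(p1, dialect), p2, dialect)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_point_stays_missing(self, dialect, tmp_path):
        seq, _ = simulate_meal(SimConfig(duration_s=2.0, rate_profile=(0, 0, 0), seed=1))
        seq.body[1, 7] = [np.nan, np.nan, 0.0]  # wrist missing at frame 1
        path = tmp_path / "kp"
        write_keypoints(seq, path, dialect)
        loaded = read_keypoints(path, dialect)
        assert loaded.missing_mask()[1, 7]
        assert np.isnan(loaded.body[1, 7, 0]) and loaded.body[1, 7, 2] == 0.0

    def test_out_of_bounds_points_kept_but_flagged(self, dialect, tmp_path):
        seq, _ = simulate_meal(SimConfig(duration_s=2.0, rate_profile=(0, 0, 0), seed=1))
        seq.body[0, 4, :2] = [900.0, 700.0]
        path = tmp_path / "kp"
        write_keypoints(seq, path, dialect)
        with pytest.warns(UserWarning, match="outside frame bounds"):
            loaded = read_keypoints(path, dialect)
        assert loaded.body[0, 4, 0] == 900.0
        assert loaded.out_of_bounds_mask()[0, 4]


class TestKeypointErrors:
    def test_missing_fps_json(self, tmp_path):
        path = tmp_path / "kp.json"
        path.write_text('{"frame_size":[720,576],"frames":[]}')
        with pytest.raises(SchemaError, match="fps"):
            read_keypoints(path, "json_frames")

    def test_missing_fps_csv(self, tmp_path):
        path = tmp_path / "kp.csv"
        path.write_text("frame,point_name,x,y,confidence\n")
        with pytest.raises(SchemaError, match="fps"):
            read_keypoints(path, "csv_flat")

    def test_non_monotone_frames_rejected(self, tmp_path):
        seq, _ = simulate_meal(SimConfig(duration_s=1.0, rate_profile=(0, 0, 0), seed=1))
        path = tmp_path / "kp.csv"
        write_keypoints(seq, path, "csv_flat")
        lines = path.read_text().splitlines()
        header, rows = lines[:4], lines[4:]
        rows.reverse()
        path.write_text("\n".join(header + rows) + "\n")
        with pytest.raises(SchemaError, match="non-decreasing"):
            read_keypoints(path, "csv_flat")

    def test_inconsistent_point_count_rejected(self, tmp_path):
        seq, _ = simulate_meal(SimConfig(duration_s=1.0, rate_profile=(0, 0, 0), seed=1))
        path = tmp_path / "kp.csv"
        write_keypoints(seq, path, "csv_flat")
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # drop one point row
        with pytest.raises(SchemaError, match="12 schema points"):
            read_keypoints(path, "csv_flat")

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            read_keypoints(tmp_path, "parquet")


class TestAnnotations:
    def test_two_event_log(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("time_s,event\n0.0,meal_start\n5.2,bite\n")
        log = read_annotations(path)
        assert log.n_events == 2
        assert log.kinds == ("meal_start", "bite")

    def test_shuffled_rows_sorted_with_warning(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("time_s,event\n5.2,bite\n0.0,meal_start\n2.0,spoonful\n")
        with pytest.warns(UserWarning, match="out of order"):
            log = read_annotations(path)
        assert np.all(np.diff(log.times) >= 0)

    def test_unknown_event_kind_rejected(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("time_s,event\n3.0,chew\n")
        with pytest.raises(KeypointIOError, match="chew"):
            read_annotations(path)

    def test_negative_time_rejected(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("time_s,event\n-1.0,bite\n")
        with pytest.raises(KeypointIOError, match="negative"):
            read_annotations(path)

    def test_duplicate_meal_start_rejected(self):
        with pytest.raises(KeypointIOError, match="meal_start"):
            AnnotationLog.from_events([(0.0, "meal_start"), (1.0, "meal_start")])

    def test_round_trip(self, noisy_meal, tmp_path):
        (_, log), _ = noisy_meal
        path = tmp_path / "ann.csv"
        write_annotations(log, path)
        assert read_annotations(path) == log


class TestBehaviorLog:
    def test_two_bite_summary_arithmetic(self, tmp_path):
        events = AnnotationLog.from_events(
            [(10.0, "bite"), (310.0, "bite")], source="detected"
        )
        summary = meal_summary(events)
        path = tmp_path / "meal.csv"
        write_behavior_log(summary, events, path)
        import json

        doc = json.loads((tmp_path / "meal.csv.summary.json").read_text())
        assert doc["duration_min"] == 5.0
        assert doc["total_bites"] == 2

    def test_empty_log_flags_undefined_duration(self, tmp_path):
        events = AnnotationLog.from_events([], source="detected")
        summary = MealSummary.empty(source="detected")
        path = tmp_path / "meal.csv"
        write_behavior_log(summary, events, path)
        import json

        doc = json.loads((tmp_path / "meal.csv.summary.json").read_text())
        assert doc["total_bites"] == 0
        assert doc["duration_defined"] is False

    def test_write_read_write_byte_identity(self, tmp_path):
        _, log = simulate_meal(SimConfig(duration_s=120.0,
                                         rate_profile=(1.5, 0, 0), seed=3))
        summary = meal_summary(log)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_behavior_log(summary, log, p1)
        reread = read_annotations(p1, source="manual")
        write_behavior_log(meal_summary(reread), reread, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert (
            (tmp_path / "a.csv.summary.json").read_bytes()
            == (tmp_path / "b.csv.summary.json").read_bytes()
        )

    def test_inconsistent_summary_rejected(self, tmp_path):
        events = AnnotationLog.from_events([(10.0, "bite")], source="detected")
        bad = MealSummary.empty(source="detected")
        with pytest.raises(ValueError, match="inconsistent"):
            write_behavior_log(bad, events, tmp_path / "x.csv")
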