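import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from swimclass.presets import DEFAULT_ARENA, ETHANOL_PRESETS
from swimclass.simulate import RegimeSchedule, simulate_fish
from swimclass.trajectory import (ArenaGeometry, ClassLabel, Trajectory,
                                  ValidationError, average_speed, fill_gaps,
                                  load_trajectory, segment_index, segment_trajectory,
                                  step_speeds)

CTRL = ClassLabel.control()


def _traj(positions, fps=25.0, arena=DEFAULT_ARENA):
    return Trajectory("f0", CTRL, fps, np.asarray(positions, float), arena)


class TestClassLabel:
    def test_control_concentration_coupling(self):
        with pytest.raises(ValidationError):
            ClassLabel(kind="control", concentration=1.0)
        with pytest.raises(ValidationError):
            ClassLabel(kind="drug", concentration=0.0, drug_name="ethanol")
        assert ClassLabel.drug("ethanol", 0.0) == CTRL

    def test_labels_sort_by_concentration(self):
        labels = [ClassLabel.drug("ethanol", c) for c in (2.0, 0.5, 1.0)] + [CTRL]
        assert [l.concentration for l in sorted(labels)] == [0.0, 0.5, 1.0, 2.0]


class TestLoadTrajectory:
    def test_reads_rows_one_per_frame(self, tmp_path):
        p = tmp_path / "fish.csv"
        p.write_text("frame,x,y\n0,10,20\n1,11,21\n2,12,22\n")
        traj = load_trajectory(p, fps=25, arena=DEFAULT_ARENA, label=CTRL)
        assert len(traj) == 3 and traj.n_missing == 0
        assert np.allclose(traj.positions[1], [11, 21])

    def test_nan_coordinates_marked_missing(self, tmp_path):
        p = tmp_path / "fish.csv"
        p.write_text("frame,x,y\n0,10,20\n1,,\n2,12,22\n")
        traj = load_trajectory(p, fps=25, arena=DEFAULT_ARENA, label=CTRL)
        assert len(traj) == 3 and traj.n_missing == 1

    def test_absent_frames_marked_missing(self, tmp_path):
        p = tmp_path / "fish.csv"
        p.write_text("frame,x,y\n0,10,20\n3,12,22\n")
        traj = load_trajectory(p, fps=25, arena=DEFAULT_ARENA, label=CTRL)
        assert len(traj) == 4 and traj.n_missing == 2

    def test_non_monotone_frames_rejected(self, tmp_path):
        p = tmp_path / "fish.csv"
        p.write_text("frame,x,y\n0,1,1\n2,2,2\n1,3,3\n")
        with pytest.raises(ValidationError, match="increasing"):
            load_trajectory(p, fps=25, arena=DEFAULT_ARENA, label=CTRL)

    def test_simulator_roundtrip_bit_exact(self, tmp_path):
        from swimclass.simulate import write_cohort

        sched = RegimeSchedule.constant(ETHANOL_PRESETS[1.0], 60)
        traj = simulate_fish(sched, 60, 25, DEFAULT_ARENA, seed=5, fish_id="sim0")
        manifest = pd.DataFrame([{"fish_id": "sim0", "label": "control",
                                  "concentration": 0.0, "fps": 25.0}])
        write_cohort([traj], manifest, tmp_path)
        back = load_trajectory(tmp_path / "sim0.csv", fps=25, arena=DEFAULT_ARENA,
                               label=CTRL, fish_id="sim0")
        assert np.array_equal(back.positions, traj.positions)


class TestFillGaps:
    def test_no_gaps_identity(self):
        traj = _traj([[1, 1], [2, 2], [3, 3]])
        assert np.array_equal(fill_gaps(traj).positions, traj.positions)

    def test_single_gap_linear_midpoint(self):
        traj = _traj([[0, 0], [np.nan, np.nan], [2, 2]])
        assert np.allclose(fill_gaps(traj).positions[1], [1, 1])

    def test_gap_longer_than_max_stays_missing(self):
        pos = [[0, 0]] + [[np.nan, np.nan]] * 3 + [[4, 4]]
        filled = fill_gaps(_traj(pos), max_gap=2)
        assert filled.n_missing == 3
        filled2 = fill_gaps(_traj(pos), max_gap=3)
        assert filled2.n_missing == 0
        assert np.allclose(filled2.positions[:, 0], [0, 1, 2, 3, 4])

    def test_leading_gap_not_interpolable(self):
        traj = _traj([[np.nan, np.nan], [1, 1], [2, 2]])
        assert fill_gaps(traj, max_gap=5).n_missing == 1


class TestSegmentation:
    def test_90min_25fps_30s_yields_180_segments(self):
        sched = RegimeSchedule.constant(ETHANOL_PRESETS[0.0], 90 * 60)
        traj = simulate_fish(sched, 90 * 60, 25, DEFAULT_ARENA, seed=0)
        assert len(segment_trajectory(traj, 30)) == 180

    @pytest.mark.parametrize("seconds,expected", [(29, 0), (300, 10), (45, 1)])
    def test_partial_windows_discarded(self, seconds, expected):
        n = int(seconds * 25)
        traj = _traj(np.tile([[50.0, 50.0]], (n, 1)))
        assert len(segment_trajectory(traj, 30)) == expected

    def test_invalid_window_rejected(self):
        traj = _traj([[1, 1]] * 10)
        with pytest.raises(ValidationError):
            segment_trajectory(traj, 0)

    def test_windows_with_gaps_dropped_and_reported(self):
        n = 75  # 3 windows of 25 frames at 1-s windows, fps 25
        pos = np.tile([[10.0, 10.0]], (n, 1))
        pos[30] = np.nan
        traj = _traj(pos)
        segs, dropped = segment_trajectory(traj, 1.0, return_dropped=True)
        assert len(segs) == 2 and dropped == [1]

    def test_partition_reproduces_prefix_exactly(self):
        rng = np.random.default_rng(3)
        pos = 120 + rng.normal(0, 5, size=(260, 2)).cumsum(axis=0) * 0.1
        traj = _traj(pos)
        segs = segment_trajectory(traj, 4.0)  # 100-frame windows
        joined = np.vstack([s.coords for s in segs])
        assert np.array_equal(joined, pos[: len(joined)])
        assert len(joined) == (len(pos) // 100) * 100
        assert [s.start_time for s in segs] == [0.0, 4.0]


class TestKinematics:
    def test_stationary_segment_zero_speeds(self, make_segment):
        seg = make_segment(np.tile([[50.0, 50.0]], (25, 1)), window_seconds=1.0)
        assert np.all(step_speeds(seg) == 0)
        assert average_speed(seg) == 0

    def test_constant_step_speed(self, make_segment):
        coords = np.column_stack([40 + 2.0 * np.arange(25), np.full(25, 120.0)])
        seg = make_segment(coords, window_seconds=1.0)
        assert np.allclose(step_speeds(seg), 50.0)  # 2 px/frame * 25 fps
        assert average_speed(seg) == pytest.approx(50.0)

    def test_matches_brute_force_distance_oracle(self, make_segment):
        rng = np.random.default_rng(11)
        coords = 120 + rng.uniform(-40, 40, size=(25, 2))
        seg = make_segment(coords, window_seconds=1.0)
        expected = [
            np.sqrt((coords[i + 1, 0] - coords[i, 0]) ** 2
                    + (coords[i + 1, 1] - coords[i, 1]) ** 2) * 25.0
            for i in range(24)
        ]
        assert np.allclose(step_speeds(seg), expected)
        assert average_speed(seg) == pytest.approx(float(np.mean(expected)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-30, 30), st.floats(-30, 30),
           st.floats(0.1, 4.0))
    def test_translation_invariant_scale_equivariant(self, seed, dx, dy, scale):
        from swimclass.trajectory import TrackSegment

        big = ArenaGeometry(center=(0.0, 0.0), radius=1e6)

        def seg(coords):
            return TrackSegment("f0", CTRL, 0.0, coords, 1.0, 25.0, big)

        rng = np.random.default_rng(seed)
        coords = 120 + rng.uniform(-20, 20, size=(25, 2))
        base = step_speeds(seg(coords))
        shifted = step_speeds(seg(coords + [dx, dy]))
        scaled = step_speeds(seg(coords * scale))
        assert np.allclose(shifted, base)
        assert np.allclose(scaled, base * scale, rtol=1e-9)


def test_segment_index_columns(make_segment):
    seg = make_segment(np.tile([[50.0, 50.0]], (25, 1)), window_seconds=1.0)
    df = segment_index([seg])
    assert list(df.columns) == ["fish_id", "segment_id", "start_time", "label",
                                "concentration", "mean_speed"]
    assert df.loc[0, "mean_speed"] == 0
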