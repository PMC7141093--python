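"""Gaze parsing, frame alignment and I-DT classification."""

import io
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazemux.model import (
    ColumnSpec,
    GazeParseError,
    GazeSample,
    GazeTrajectory,
    VideoMeta,
    canonical_spec,
    classify_events,
    frame_index,
    frame_interval,
    parse_gaze,
    read_config,
    write_config,
    write_gaze,
)
from gazemux.synthetic import GazeGenSpec, gen_gaze


class TestParseGaze:
    def test_basic_header_skip(self):
        traj = parse_gaze("t,x,y\n0,10,20\n0.02,12,22",
                          ColumnSpec(header_lines=1), sampling_rate=50.0)
        assert len(traj) == 2
        assert traj.samples[0] == GazeSample(0.0, 10.0, 20.0)

    def test_header_only_yields_empty_trajectory(self):
        traj = parse_gaze("t,x,y\n", ColumnSpec(header_lines=1), 50.0)
        assert len(traj) == 0

    def test_milliseconds_against_naive_reparse(self):
        # oracle: an independent line-by-line parser of the same text
        lines = ["time_ms\tx\ty"]
        for i in range(1000):
            lines.append(f"{4 * i}\t{i % 640}\t{i % 480}")
        text = "\n".join(lines)
        spec = ColumnSpec(header_lines=1, delimiter="\t", time_unit="milliseconds")
        traj = parse_gaze(text, spec, 250.0)

        naive = [
            (float(parts[0]) / 1000.0, float(parts[1]), float(parts[2]))
            for parts in (ln.split("\t") for ln in lines[1:])
        ]
        assert len(traj) == len(naive) == 1000
        assert traj.samples[-1].t == pytest.approx(naive[-1][0])
        assert max(s.t for s in traj.samples) == pytest.approx(4 * 999 / 1000.0)
        for s, (t, x, y) in zip(traj.samples, naive):
            assert (s.t, s.x, s.y) == pytest.approx((t, x, y))

    def test_sample_index_unit_divides_by_rate(self):
        traj = parse_gaze("0,1,2\n1,3,4\n2,5,6",
                          ColumnSpec(time_unit="sample_index"), sampling_rate=250.0)
        assert [s.t for s in traj.samples] == pytest.approx([0, 1 / 250, 2 / 250])

    def test_malformed_row_names_line(self):
        with pytest.raises(GazeParseError, match="line 3"):
            parse_gaze("t,x,y\n0,1,2\n0.1,oops,2", ColumnSpec(header_lines=1), 50.0)

    def test_non_monotonic_reports_offending_pair(self):
        with pytest.raises(GazeParseError, match=r"t=0\.2 followed by t=0\.1"):
            parse_gaze("0,1,1\n0.2,2,2\n0.1,3,3", ColumnSpec(), 50.0)

    def test_offscreen_samples_kept_and_flagged(self, video):
        traj = parse_gaze("0,-5,10\n0.1,100,100", ColumnSpec(), 50.0)
        assert len(traj) == 2
        assert traj.offscreen_mask(video) == [True, False]

    def test_writer_parse_round_trip(self, trajectory):
        buf = io.StringIO()
        write_gaze(trajectory, buf)
        back = parse_gaze(buf.getvalue(), canonical_spec(has_pupil=True),
                          trajectory.sampling_rate)
        assert len(back) == len(trajectory)
        for a, b in zip(trajectory.samples, back.samples):
            assert (b.t, b.x, b.y, b.pupil) == pytest.approx(
                (a.t, a.x, a.y, a.pupil), abs=1e-6)


class TestFrameInterval:
    def test_first_frame(self, video):
        assert frame_interval(0.0, video) == (0.0, pytest.approx(0.04))

    def test_boundary_belongs_to_next_frame(self, video):
        t0, t1 = frame_interval(0.04, video)
        assert t0 <= 0.04 < t1
        assert frame_index(0.04, video) == 1

    def test_negative_time_rejected(self, video):
        with pytest.raises(ValueError):
            frame_interval(-0.001, video)

    def test_against_brute_force_scan_ntsc(self):
        # oracle: scan frame indices for the one whose half-open interval holds t
        video = VideoMeta(720, 480, 29.97)
        import numpy as np

        rng = np.random.default_rng(42)
        for t in rng.uniform(0.0, 60.0, 500):
            n = frame_index(t, video)
            hits = [m for m in range(int(t * video.fps) + 3)
                    if m / video.fps <= t < (m + 1) / video.fps]
            assert hits == [n]

    @given(st.floats(min_value=0.0, max_value=1e4, allow_nan=False),
           st.floats(min_value=1.0, max_value=120.0))
    @settings(max_examples=200, deadline=None)
    def test_intervals_tile_time(self, t, fps):
        video = VideoMeta(64, 64, fps)
        t0, t1 = frame_interval(t, video)
        assert t0 <= t < t1
        # the neighbouring intervals meet exactly at the boundaries
        n = frame_index(t, video)
        assert t0 == n / fps and t1 == (n + 1) / fps


class TestClassifyEvents:
    def test_stationary_gaze_all_fixation(self):
        samples = [GazeSample(i * 0.01, 100.0, 100.0) for i in range(50)]
        traj = GazeTrajectory("s", samples, 100.0)
        out = classify_events(traj, dispersion_px=10.0, min_duration_s=0.1)
        assert all(s.label == "fixation" for s in out.samples)

    def test_alternating_jumps_all_saccade(self):
        samples = [GazeSample(i * 0.01, 0.0 if i % 2 == 0 else 500.0,
                              0.0 if i % 2 == 0 else 500.0) for i in range(50)]
        traj = GazeTrajectory("s", samples, 100.0)
        out = classify_events(traj, dispersion_px=10.0, min_duration_s=0.1)
        assert all(s.label == "saccade" for s in out.samples)

    def test_every_sample_labeled_exactly_once(self, trajectory, video):
        out = classify_events(trajectory, 0.02 * max(video.width, video.height), 0.1)
        assert all(s.label in ("fixation", "saccade") for s in out.samples)
        assert len(out) == len(trajectory)

    def test_fixation_runs_respect_min_duration(self, trajectory, video):
        out = classify_events(trajectory, 0.02 * max(video.width, video.height), 0.1)
        runs = []
        start = None
        for i, s in enumerate(out.samples):
            if s.label == "fixation" and start is None:
                start = i
            elif s.label != "fixation" and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(out) - 1))
        for a, b in runs:
            assert out.samples[b].t - out.samples[a].t >= 0.1 - 1e-9

    def test_recovers_generated_fixations(self, video):
        # oracle: the generator's own ground-truth segments
        spec = GazeGenSpec(n_fixations=5, seed=11, video=video)
        traj, truth = gen_gaze(spec)
        out = classify_events(traj, dispersion_px=0.02 * max(video.width, video.height),
                              min_duration_s=0.1)
        fix_windows = [(g.t_start, g.t_end) for g in truth if g.kind == "fixation"]
        in_fix = [any(a <= s.t < b for a, b in fix_windows) for s in traj.samples]
        total = sum(in_fix)
        hit = sum(1 for s, f in zip(out.samples, in_fix) if f and s.label == "fixation")
        assert hit / total >= 0.9

    def test_overwrite_flag_preserves_existing_labels(self):
        samples = [GazeSample(i * 0.01, 100.0, 100.0, label="saccade") for i in range(50)]
        traj = GazeTrajectory("s", samples, 100.0)
        kept = classify_events(traj, 10.0, 0.1, overwrite=False)
        assert all(s.label == "saccade" for s in kept.samples)
        redone = classify_events(traj, 10.0, 0.1, overwrite=True)
        assert all(s.label == "fixation" for s in redone.samples)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            classify_events(GazeTrajectory("s", [], 100.0), 10.0, 0.1)


class TestConfig:
    def test_round_trip(self, tmp_path, video):
        spec = ColumnSpec(header_lines=2, delimiter="\t", t_col=1, x_col=2, y_col=3,
                          pupil_col=4, time_unit="microseconds")
        path = tmp_path / "run.ini"
        write_config(path, spec, video)
        spec2, video2 = read_config(path)
        assert spec2 == spec
        assert video2 == video

    def test_duplicate_columns_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ColumnSpec(t_col=0, x_col=0, y_col=1)
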