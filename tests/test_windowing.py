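"""The analysis engine: window enumeration, guard, single and batch runs."""

import math

import numpy as np
import pytest

from entrokit import (
    AnalysisConfig,
    EmbeddingParams,
    FixtureSpec,
    GapSet,
    TimeSeries,
    ToleranceSpec,
    WindowSpec,
    analyze_batch,
    analyze_single,
    enumerate_windows,
    generate,
    sampen,
    write_signal_ascii,
)
from entrokit.errors import (
    EmptyListError,
    GuardRefusalError,
    InvalidOverlapError,
    InvalidParameterError,
    WindowTooLongError,
)
from entrokit.windowing import DEFAULT_GUARD_THRESHOLD


class TestWindowSpec:
    def test_step_rounding(self):
        assert WindowSpec(4, 50.0).step == 2
        assert WindowSpec(300, 50.0).step == 150
        assert WindowSpec(10, 0.0).step == 10
        # half-away-from-zero: 25% of 10 = 2.5 -> overlap 3 -> step 7
        assert WindowSpec(10, 25.0).step == 7

    def test_invalid_overlap(self):
        with pytest.raises(InvalidOverlapError):
            WindowSpec(10, 100.0)
        with pytest.raises(InvalidOverlapError):
            WindowSpec(10, 99.0)  # step would be 0


class TestEnumerateWindows:
    def test_fifty_percent_overlap(self):
        assert enumerate_windows(10, WindowSpec(4, 50.0)) == [(1, 4), (3, 6), (5, 8), (7, 10)]

    def test_long_series_example(self):
        windows = enumerate_windows(1000, WindowSpec(300, 50.0))
        assert len(windows) == 5
        assert windows[-1] == (601, 900)

    def test_no_overlap_drops_tail(self):
        assert enumerate_windows(10, WindowSpec(4, 0.0)) == [(1, 4), (5, 8)]

    def test_window_too_long(self):
        with pytest.raises(WindowTooLongError):
            enumerate_windows(5, WindowSpec(6, 0.0))


class TestGuard:
    def test_refuses_above_threshold(self):
        series = TimeSeries(np.sin(np.arange(DEFAULT_GUARD_THRESHOLD + 1) * 0.1))
        with pytest.raises(GuardRefusalError, match="workstation"):
            analyze_single(series, AnalysisConfig(metrics=("permen",)))

    def test_workstation_flag_overrides(self):
        series = TimeSeries(np.sin(np.arange(DEFAULT_GUARD_THRESHOLD + 1) * 0.1))
        table = analyze_single(series, AnalysisConfig(metrics=("permen",), workstation=True))
        assert len(table) == 1

    def test_window_mode_exempt(self):
        series = TimeSeries(np.sin(np.arange(12_000) * 0.1))
        cfg = AnalysisConfig(metrics=("permen",), window=WindowSpec(1000, 0.0))
        assert len(analyze_single(series, cfg)) == 12

    def test_guard_monotonicity(self):
        cfg = AnalysisConfig(metrics=("permen",), guard_threshold=500)
        accepted = TimeSeries(np.sin(np.arange(500) * 0.1))
        analyze_single(accepted, cfg)  # boundary N == threshold accepted
        shorter = TimeSeries(np.sin(np.arange(100) * 0.1))
        analyze_single(shorter, cfg)
        with pytest.raises(GuardRefusalError):
            analyze_single(TimeSeries(np.sin(np.arange(501) * 0.1)), cfg)


class TestAnalyzeSingle:
    def test_window_count_and_schema(self):
        series = generate(FixtureSpec("gaussian_noise", 1000, seed=3))
        cfg = AnalysisConfig(metrics=("sampen",), window=WindowSpec(300, 50.0))
        table = analyze_single(series, cfg)
        assert len(table) == 5
        assert table.columns == ("file", "window", "start", "end", "n_valid", "sampen", "error")
        assert [r.window_index for r in table.records] == [1, 2, 3, 4, 5]
        assert all(math.isfinite(r.values["sampen"]) for r in table.records)

    def test_single_full_window_equals_whole_series(self):
        series = generate(FixtureSpec("gaussian_noise", 400, seed=9))
        base = analyze_single(series, AnalysisConfig())
        windowed = analyze_single(
            series, AnalysisConfig(window=WindowSpec(400, 50.0))
        )
        assert base.records[0].values == windowed.records[0].values

    def test_window_inside_gap_is_undefined_not_fatal(self):
        series = generate(FixtureSpec("gaussian_noise", 300, seed=2))
        cfg = AnalysisConfig(
            metrics=("sampen", "permen"),
            window=WindowSpec(100, 0.0),
            enable_gap=True,
            tolerance=ToleranceSpec(0.2, "absolute"),
        )
        table = analyze_single(series, cfg, gaps=GapSet(((101, 200),)))
        assert len(table) == 3
        middle = table.records[1]
        assert middle.n_valid == 0
        assert all(math.isnan(v) for v in middle.values.values())
        assert math.isfinite(table.records[0].values["sampen"])

    def test_deterministic(self):
        series = generate(FixtureSpec("ar1", 500, seed=8, params={"phi": 0.7}))
        cfg = AnalysisConfig(window=WindowSpec(200, 50.0))
        t1 = analyze_single(series, cfg)
        t2 = analyze_single(series, cfg)
        for a, b in zip(t1.records, t2.records):
            assert a == b

    def test_per_recording_tolerance_scope(self):
        series = generate(FixtureSpec("ar1", 600, seed=4, params={"phi": 0.9}))
        win = WindowSpec(200, 0.0)
        per_window = analyze_single(series, AnalysisConfig(metrics=("sampen",), window=win))
        per_rec = analyze_single(
            series,
            AnalysisConfig(metrics=("sampen",), window=win, tolerance_scope="recording"),
        )
        # a strongly autocorrelated signal has window SDs differing from the
        # recording SD, so the two scopes must disagree somewhere
        a = [r.values["sampen"] for r in per_window.records]
        b = [r.values["sampen"] for r in per_rec.records]
        assert a != b

    def test_requires_a_metric(self):
        with pytest.raises(InvalidParameterError):
            AnalysisConfig(metrics=())


class TestAnalyzeBatch:
    @pytest.fixture
    def data_dir(self, tmp_path):
        for i, seed in enumerate((1, 2, 3)):
            series = generate(FixtureSpec("gaussian_noise", 200, seed=seed))
            write_signal_ascii(series, tmp_path / f"rec{i}.txt")
        return tmp_path

    def test_orders_records_by_list(self, data_dir):
        cfg = AnalysisConfig(metrics=("sampen",))
        table = analyze_batch(["rec2.txt", "rec0.txt", "rec1.txt"], data_dir, cfg)
        assert [r.source for r in table.records] == ["rec2.txt", "rec0.txt", "rec1.txt"]

    def test_batch_equals_single(self, data_dir):
        from entrokit import read_signal_ascii

        cfg = AnalysisConfig()
        table = analyze_batch(["rec1.txt"], data_dir, cfg)
        single = analyze_single(read_signal_ascii(data_dir / "rec1.txt"), cfg, source="rec1.txt")
        assert table.records == single.records

    def test_missing_file_becomes_error_row(self, data_dir):
        cfg = AnalysisConfig(metrics=("sampen",))
        table = analyze_batch(["rec0.txt", "ghost.txt", "rec1.txt"], data_dir, cfg)
        assert len(table) == 3
        err = table.records[1]
        assert err.source == "ghost.txt"
        assert err.error != ""
        assert math.isnan(err.values["sampen"])
        assert table.records[2].error == ""

    def test_empty_list_refused(self, data_dir):
        with pytest.raises(EmptyListError):
            analyze_batch([], data_dir, AnalysisConfig())

    def test_write_while_analyze_streams_per_file(self, data_dir):
        class RecordingSink:
            def __init__(self):
                self.batches = []

            def write_records(self, table):
                self.batches.append([r.source for r in table.records])

        sink = RecordingSink()
        cfg = AnalysisConfig(metrics=("sampen",), write_while_analyze=True)
        table = analyze_batch(["rec0.txt", "rec1.txt"], data_dir, cfg, sink=sink)
        assert sink.batches == [["rec0.txt"], ["rec1.txt"]]
        # streaming keeps only the last file in memory
        assert [r.source for r in table.records] == ["rec1.txt"]

    def test_gap_discovery_in_batch(self, data_dir):
        gap_dir = data_dir / "Gap"
        gap_dir.mkdir()
        (gap_dir / "rec0.gap").write_text("50,150\n")
        cfg = AnalysisConfig(metrics=("sampen",), enable_gap=True)
        table = analyze_batch(["rec0.txt", "rec1.txt"], data_dir, cfg)
        assert table.records[0].n_valid == 99
        assert table.records[1].n_valid == 200
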