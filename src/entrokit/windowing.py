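"""The analysis engine: sliding windows, the single-recording pipeline with
its long-recording guard, and the multi-recording batch runner.

The pipeline for one recording is: apply gaps (when enabled and a gap set
is available) -> normalize -> analyze the whole series or each sliding
window -> compute every selected metric.  A whole-series analysis of a
recording longer than the guard threshold (default 10,000 points) is
refused unless the caller opts into workstation mode or windows the data —
a self-protective default for personal computers.  Metric failures inside
a window never abort a run; they are recorded as undefined (NaN) values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from .embedding import EmbeddingParams
from .entropy_core import ToleranceSpec, apen, fuzzyen, resolve_tolerance, sampen
from .entropy_dist import DEFAULT_BINS, disten
from .entropy_symbolic import QuantizationSpec, conditional_entropy, permen
from .errors import (
    EmptyListError,
    EntrokitError,
    GuardRefusalError,
    InvalidOverlapError,
    InvalidParameterError,
    WindowTooLongError,
)
from .signal_model import GapSet, TimeSeries, apply_gaps, normalize

__all__ = [
    "DEFAULT_GUARD_THRESHOLD",
    "METRIC_NAMES",
    "WindowSpec",
    "AnalysisConfig",
    "ResultRecord",
    "ResultTable",
    "enumerate_windows",
    "analyze_single",
    "analyze_batch",
]

logger = logging.getLogger("entrokit")

#: Whole-recording length above which an un-windowed analysis is refused.
DEFAULT_GUARD_THRESHOLD = 10_000

#: The metrics the engine knows, in canonical column order.
METRIC_NAMES = ("apen", "sampen", "fuzzyen", "ce", "permen", "disten")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding window of *length* samples advanced by
    ``step = length - round(length * overlap_percent / 100)``."""

    length: int
    overlap_percent: float = 0.0

    def __post_init__(self) -> None:
        if int(self.length) < 2:
            raise InvalidParameterError(f"window length must be >= 2 samples, got {self.length}")
        if not (0.0 <= float(self.overlap_percent) < 100.0):
            raise InvalidOverlapError(
                f"overlap must be in [0, 100) percent, got {self.overlap_percent}"
            )
        object.__setattr__(self, "length", int(self.length))
        object.__setattr__(self, "overlap_percent", float(self.overlap_percent))
        if self.step < 1:
            raise InvalidOverlapError(
                f"overlap {self.overlap_percent}% of a {self.length}-sample window leaves a step < 1"
            )

    @property
    def step(self) -> int:
        # half-away-from-zero rounding of the overlap in samples
        return self.length - int(math.floor(self.length * self.overlap_percent / 100.0 + 0.5))


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the engine needs for one deterministic run."""

    metrics: tuple[str, ...] = METRIC_NAMES
    embedding: EmbeddingParams = EmbeddingParams(2, 1)
    tolerance: ToleranceSpec = ToleranceSpec(0.2, "relative_to_sd")
    xi: QuantizationSpec = QuantizationSpec(6)
    bins: int = DEFAULT_BINS
    normalization: str = "none"
    enable_gap: bool = False
    window: WindowSpec | None = None
    workstation: bool = False
    write_while_analyze: bool = False
    guard_threshold: int = DEFAULT_GUARD_THRESHOLD
    tolerance_scope: str = "window"  # resolve relative r per "window" or per "recording"

    def __post_init__(self) -> None:
        metrics = tuple(self.metrics)
        if not metrics:
            raise InvalidParameterError("at least one metric must be selected")
        unknown = [m for m in metrics if m not in METRIC_NAMES]
        if unknown:
            raise InvalidParameterError(f"unknown metric(s) {unknown}; choose from {METRIC_NAMES}")
        if int(self.guard_threshold) < 1:
            raise InvalidParameterError("guard threshold must be >= 1")
        if self.tolerance_scope not in ("window", "recording"):
            raise InvalidParameterError("tolerance_scope must be 'window' or 'recording'")
        object.__setattr__(self, "metrics", metrics)


@dataclass(frozen=True)
class ResultRecord:
    """One analyzed segment: a window of a recording, or the whole recording
    (window_index 0)."""

    source: str
    window_index: int
    start: int
    end: int
    n_valid: int
    values: dict[str, float] = field(default_factory=dict)
    error: str = ""


@dataclass
class ResultTable:
    """Ordered result records plus the fixed column schema of the run."""

    metrics: tuple[str, ...]
    records: list[ResultRecord] = field(default_factory=list)

    @property
    def columns(self) -> tuple[str, ...]:
        return ("file", "window", "start", "end", "n_valid") + self.metrics + ("error",)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self):
        """The table as a pandas DataFrame (one column per schema field)."""
        import pandas as pd

        rows = []
        for r in self.records:
            row = {
                "file": r.source,
                "window": r.window_index,
                "start": r.start,
                "end": r.end,
                "n_valid": r.n_valid,
            }
            for m in self.metrics:
                row[m] = r.values.get(m, float("nan"))
            row["error"] = r.error
            rows.append(row)
        return pd.DataFrame(rows, columns=list(self.columns))


def enumerate_windows(n: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """1-based inclusive (start, end) pairs: starts 1, 1+step, 1+2*step, ...;
    windows running past sample *n* are dropped.

    Raises
    ------
    WindowTooLongError
        When the window is longer than the series.
    """
    if spec.length > n:
        raise WindowTooLongError(f"window of {spec.length} samples exceeds series length N={n}")
    windows = []
    start = 1
    while start + spec.length - 1 <= n:
        windows.append((start, start + spec.length - 1))
        start += spec.step
    return windows


def _compute_metric(name: str, segment: TimeSeries, config: AnalysisConfig,
                    tolerance: ToleranceSpec) -> float:
    if name == "apen":
        return apen(segment, config.embedding, tolerance)
    if name == "sampen":
        return sampen(segment, config.embedding, tolerance)
    if name == "fuzzyen":
        return fuzzyen(segment, config.embedding, tolerance)
    if name == "ce":
        return conditional_entropy(segment, config.embedding.m, config.xi)
    if name == "permen":
        return permen(segment, config.embedding)
    if name == "disten":
        return disten(segment, config.embedding, config.bins)
    raise InvalidParameterError(f"unknown metric {name!r}")


def analyze_single(
    series: TimeSeries,
    config: AnalysisConfig,
    gaps: GapSet | None = None,
    source: str = "<series>",
    sink=None,
) -> ResultTable:
    """Analyze one recording and return its :class:`ResultTable`.

    With no window configured the whole series is one segment
    (``window_index`` 0); otherwise each enumerated window is analyzed
    independently.  Relative tolerances are resolved per segment by
    default (``tolerance_scope='window'``) or once per recording.  A
    metric failing on a segment yields a NaN value and a warning, never an
    aborted run.

    Raises
    ------
    GuardRefusalError
        Whole-series mode, N above the guard threshold, and workstation
        mode off.
    """
    if config.window is None and series.n > config.guard_threshold and not config.workstation:
        raise GuardRefusalError(
            f"recording {source!r} has N={series.n} > {config.guard_threshold} points; "
            "refusing a whole-series analysis on a personal computer. Either "
            "(1) enable a sliding window, (2) set the workstation flag to force "
            "the computation, or (3) analyze a shorter recording."
        )
    if config.enable_gap and gaps is not None:
        series = apply_gaps(series, gaps)
    series = normalize(series, config.normalization)

    tolerance = config.tolerance
    if config.tolerance_scope == "recording" and tolerance.mode == "relative_to_sd":
        tolerance = ToleranceSpec(resolve_tolerance(series, tolerance), "absolute")

    if config.window is None:
        segments = [(0, 1, series.n)]
    else:
        segments = [
            (k, s, e) for k, (s, e) in enumerate(enumerate_windows(series.n, config.window), start=1)
        ]

    table = ResultTable(metrics=config.metrics)
    logger.info("analyzing %s: N=%d, %d segment(s)", source, series.n, len(segments))
    for index, start, end in segments:
        segment = TimeSeries(series.values[start - 1 : end])
        n_valid = int(segment.unmasked.size)
        values: dict[str, float] = {}
        for name in config.metrics:
            try:
                values[name] = float(_compute_metric(name, segment, config, tolerance))
            except EntrokitError as exc:
                logger.warning("%s window %d [%d, %d]: %s undefined: %s",
                               source, index, start, end, name, exc)
                values[name] = float("nan")
        logger.debug("%s window %d [%d, %d] done", source, index, start, end)
        table.records.append(
            ResultRecord(source=source, window_index=index, start=start, end=end,
                         n_valid=n_valid, values=values)
        )
    if sink is not None:
        sink.write_records(table)
    return table


def analyze_batch(names, data_dir, config: AnalysisConfig, sink=None) -> ResultTable:
    """Analyze every recording named in *names* (in order) under *data_dir*.

    Gap files are discovered per recording when ``enable_gap`` is set.  A
    missing or unreadable recording becomes an error record and the run
    continues.  With ``write_while_analyze`` and a sink, each file's
    records are flushed as soon as they are computed and only the current
    file's records stay in memory; the returned table then holds the last
    file processed.
    """
    from .io_formats import discover_gap_file, read_gap_file, read_signal_ascii

    names = list(names)
    if not names:
        raise EmptyListError("batch list contains no recording names")
    data_dir = Path(data_dir)
    if not data_dir.is_dir():
        raise FileNotFoundError(f"data directory {data_dir} does not exist")

    table = ResultTable(metrics=config.metrics)
    streaming = config.write_while_analyze and sink is not None
    failed = 0
    for name in names:
        path = data_dir / name
        try:
            series = read_signal_ascii(path)
            gaps = None
            if config.enable_gap:
                gap_path = discover_gap_file(path)
                if gap_path is not None:
                    try:
                        gaps = read_gap_file(gap_path)
                    except EntrokitError as exc:
                        logger.warning("gap file %s unreadable, ignored: %s", gap_path, exc)
            file_table = analyze_single(series, config, gaps=gaps, source=name)
        except (EntrokitError, OSError) as exc:
            logger.warning("recording %s failed: %s", name, exc)
            failed += 1
            file_table = ResultTable(metrics=config.metrics)
            file_table.records.append(
                ResultRecord(source=name, window_index=0, start=0, end=0, n_valid=0,
                             values={m: float("nan") for m in config.metrics},
                             error=str(exc))
            )
        if streaming:
            sink.write_records(file_table)
            table = file_table
        else:
            table.records.extend(file_table.records)
    if sink is not None and not streaming:
        sink.write_records(table)
    logger.info("batch complete: %d file(s) processed, %d failed", len(names), failed)
    return table
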