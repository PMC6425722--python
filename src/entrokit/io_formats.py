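"""ASCII interchange formats: signal, gap, list and results files.

* Signal file: one real sample per non-blank line, single column.
* Gap file: two numeric columns (comma or whitespace separated) of 1-based
  inclusive start/end sample indices, one gap per row; discovered next to
  a signal as ``<dir>/Gap/<stem>.gap``.
* List file: one recording name per non-blank line (batch input).
* Results file: comma-separated with a header line; numeric fields are
  rendered with 17 significant digits so every float64 round-trips
  exactly; undefined metric values are empty fields.

Encoding is UTF-8; CR-LF and LF are both accepted on read, LF is written.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .errors import EmptyFileError, EmptyListError, MalformedGapError, SignalParseError
from .signal_model import GapSet, TimeSeries
from .windowing import ResultRecord, ResultTable

__all__ = [
    "read_signal_ascii",
    "write_signal_ascii",
    "discover_gap_file",
    "read_gap_file",
    "read_list_file",
    "write_results_csv",
    "CsvResultSink",
]

logger = logging.getLogger("entrokit")


def read_signal_ascii(path) -> TimeSeries:
    """Read a single-column ASCII signal file into a :class:`TimeSeries`.

    Blank lines and surrounding whitespace are ignored.  A non-numeric or
    non-finite line raises :class:`SignalParseError` citing the 1-based
    line number; a file with no samples raises :class:`EmptyFileError`.
    """
    path = Path(path)
    samples: list[float] = []
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            # tolerate the unicode minus some editors produce
            token = token.replace("−", "-")
            try:
                value = float(token)
            except ValueError as exc:
                raise SignalParseError(
                    f"{path}: line {lineno}: {token!r} is not a number"
                ) from exc
            if not np.isfinite(value):
                raise SignalParseError(f"{path}: line {lineno}: sample {token!r} is not finite")
            samples.append(value)
    if not samples:
        raise EmptyFileError(f"{path}: no samples found")
    return TimeSeries(np.asarray(samples))


def write_signal_ascii(series: TimeSeries, path) -> Path:
    """Write *series* as a single-column ASCII file (gap samples must be
    unmasked; write the raw series plus a gap file instead)."""
    if series.gap_mask.any():
        raise ValueError("cannot serialize masked samples; write the raw series and a gap file")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for value in series.values:
            fh.write(format(value, ".17g") + "\n")
    return path


def discover_gap_file(signal_path) -> Path | None:
    """The companion gap file ``<dir>/Gap/<stem>.gap`` of *signal_path*, or
    None when absent (absence is not an error)."""
    signal_path = Path(signal_path)
    candidate = signal_path.parent / "Gap" / (signal_path.stem + ".gap")
    if candidate.is_file():
        return candidate
    logger.debug("no gap file for %s (looked at %s)", signal_path, candidate)
    return None


def read_gap_file(path) -> GapSet:
    """Parse a two-column gap file into a :class:`GapSet` (file order).

    Rows may be comma- or whitespace-separated.  An empty file is an empty
    gap set; a malformed row (wrong column count, non-integer, start > end)
    rejects the file whole.
    """
    path = Path(path)
    intervals: list[tuple[int, int]] = []
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            tokens = stripped.replace(",", " ").split()
            if len(tokens) != 2:
                raise MalformedGapError(
                    f"{path}: line {lineno}: expected two columns, got {len(tokens)}"
                )
            try:
                start_f, end_f = float(tokens[0]), float(tokens[1])
            except ValueError as exc:
                raise MalformedGapError(f"{path}: line {lineno}: non-numeric gap bound") from exc
            if start_f != int(start_f) or end_f != int(end_f):
                raise MalformedGapError(
                    f"{path}: line {lineno}: gap bounds must be integer sample indices"
                )
            start, end = int(start_f), int(end_f)
            if start < 1 or start > end:
                raise MalformedGapError(
                    f"{path}: line {lineno}: invalid interval ({start}, {end})"
                )
            intervals.append((start, end))
    return GapSet(tuple(intervals))


def read_list_file(path) -> list[str]:
    """Recording names, one per non-blank line, order preserved, trimmed."""
    path = Path(path)
    names: list[str] = []
    with open(path, encoding="utf-8", newline=None) as fh:
        for line in fh:
            name = line.strip()
            if name:
                names.append(name)
    if not names:
        raise EmptyListError(f"{path}: list file contains no recording names")
    return names


def _format_value(value: float) -> str:
    if value != value:  # NaN: the undefined marker
        return ""
    return format(value, ".17g")


def _record_row(record: ResultRecord, metrics: tuple[str, ...]) -> str:
    fields = [
        record.source,
        str(record.window_index),
        str(record.start),
        str(record.end),
        str(record.n_valid),
    ]
    fields += [_format_value(record.values.get(m, float("nan"))) for m in metrics]
    fields.append(record.error)
    return ",".join(fields)


def write_results_csv(table: ResultTable, path) -> Path:
    """Write a :class:`ResultTable` as a comma-separated file with a header
    line; columns are source/window fields, then metrics in config order,
    then the error column."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(table.columns) + "\n")
        for record in table.records:
            fh.write(_record_row(record, table.metrics) + "\n")
    return path


class CsvResultSink:
    """Streaming results writer for write-while-analyze runs.

    The header is emitted on the first write; each :meth:`write_records`
    call appends and flushes, so results for file k reach the disk before
    file k+1 is read.
    """

    def __init__(self, path):
        self.path = Path(path)
        self._fh = None
        self._metrics: tuple[str, ...] | None = None

    def write_records(self, table: ResultTable) -> None:
        if self._fh is None:
            self._fh = open(self.path, "w", encoding="utf-8", newline="\n")
            self._metrics = table.metrics
            self._fh.write(",".join(table.columns) + "\n")
        for record in table.records:
            self._fh.write(_record_row(record, self._metrics) + "\n")
        self._fh.flush()

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False
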