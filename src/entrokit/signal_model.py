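"""In-memory signal model: a recording, its gap mask, and normalization.

A recording is an ordered sequence of real samples ``u(i), i = 1..N``.
Samples that fall inside an artifact/missing-data *gap* are re-defined as
NaN and excluded from every downstream statistic; the gap mask is simply
``isnan`` of the stored values.  Gap intervals use 1-based indices,
inclusive on both ends, matching the two-column gap-file convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSeriesError, GapRangeError, MalformedGapError

__all__ = [
    "TimeSeries",
    "GapSet",
    "NORMALIZATION_MODES",
    "normalize",
    "apply_gaps",
]

#: Accepted normalization mode tokens.
NORMALIZATION_MODES = ("zscore", "minmax", "none")


@dataclass(frozen=True)
class TimeSeries:
    """An immutable recording of ``N >= 1`` samples.

    Parameters
    ----------
    values
        One-dimensional sequence of samples.  NaN marks a masked gap
        sample; infinities are rejected.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.array(self.values, dtype=np.float64, copy=True)
        if arr.ndim != 1:
            raise ValueError("a TimeSeries holds a one-dimensional sample sequence")
        if arr.size < 1:
            raise ValueError("a TimeSeries needs at least one sample")
        if np.isinf(arr).any():
            raise ValueError("samples must be finite (NaN marks a gap)")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        """Number of samples N (masked gaps included)."""
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n

    @property
    def gap_mask(self) -> np.ndarray:
        """Boolean array, True where the sample is a masked gap."""
        return np.isnan(self.values)

    @property
    def unmasked(self) -> np.ndarray:
        """The finite (non-gap) samples, in order."""
        return self.values[~np.isnan(self.values)]


@dataclass(frozen=True)
class GapSet:
    """A set of gap intervals, 1-based and inclusive on both ends.

    Overlapping or duplicate intervals are legal; masking is a set
    operation, so they merge silently.
    """

    intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        cleaned = []
        for iv in self.intervals:
            try:
                start, end = int(iv[0]), int(iv[1])
            except (TypeError, ValueError) as exc:
                raise MalformedGapError(f"gap interval {iv!r} is not a pair of integers") from exc
            if start < 1:
                raise MalformedGapError(f"gap interval ({start}, {end}): indices are 1-based")
            if start > end:
                raise MalformedGapError(f"gap interval ({start}, {end}): start exceeds end")
            cleaned.append((start, end))
        object.__setattr__(self, "intervals", tuple(cleaned))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def normalize(series: TimeSeries, mode: str) -> TimeSeries:
    """Return a normalized copy of *series*.

    ``zscore`` maps unmasked samples to ``(u - mean) / SD`` with the sample
    (N-1 denominator) standard deviation; ``minmax`` maps them to
    ``(u - min) / (max - min)``; ``none`` is the identity.  Statistics are
    computed over unmasked samples only and masked positions stay masked.

    Raises
    ------
    DegenerateSeriesError
        For a constant series (SD = 0 or range = 0) under zscore/minmax,
        or when fewer than two unmasked samples exist.
    ValueError
        For an unknown mode token.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}; expected one of {NORMALIZATION_MODES}")
    if mode == "none":
        return series
    finite = series.unmasked
    if finite.size < 2:
        raise DegenerateSeriesError("normalization needs at least two unmasked samples")
    if mode == "zscore":
        sd = float(np.std(finite, ddof=1))
        if sd == 0.0:
            raise DegenerateSeriesError("zscore normalization undefined: standard deviation is zero")
        return TimeSeries((series.values - float(np.mean(finite))) / sd)
    lo, hi = float(np.min(finite)), float(np.max(finite))
    if hi == lo:
        raise DegenerateSeriesError("min-max normalization undefined: range is zero")
    return TimeSeries((series.values - lo) / (hi - lo))


def apply_gaps(series: TimeSeries, gaps: GapSet) -> TimeSeries:
    """Mask every sample covered by *gaps* (1-based, inclusive) as NaN.

    Idempotent; an empty gap set returns the series unchanged.

    Raises
    ------
    GapRangeError
        If any interval extends past sample N.
    """
    if len(gaps) == 0:
        return series
    values = np.array(series.values, copy=True)
    n = series.n
    for start, end in gaps:
        if end > n:
            raise GapRangeError(f"gap interval ({start}, {end}) exceeds series length N={n}")
        values[start - 1 : end] = np.nan
    return TimeSeries(values)
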