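"""Symbolic-dynamics entropies: conditional entropy and permutation entropy.

Conditional entropy (CE) coarse-grains the signal into ``xi`` amplitude
levels, codifies consecutive level motifs of length m and m+1 as decimal
integers (first element weighted ``xi**(m-1)``), and reports the Shannon
entropy difference SE(m+1) - SE(m): the information carried by one new
sample given the previous m.

Permutation entropy (PermEn) replaces amplitude levels with ordinal
patterns: each tau-spaced motif of length m is reduced to the permutation
that sorts it ascending (ties broken by position), and PermEn is the
Shannon entropy of the pattern distribution, bounded by ln(m!).

Both default to the natural logarithm; the base is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingParams
from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    NonNormalizedDistributionError,
)
from .signal_model import TimeSeries

__all__ = [
    "QuantizationSpec",
    "MotifDistribution",
    "OrdinalPatternDistribution",
    "coarse_grain",
    "codify_motifs",
    "shannon_entropy",
    "conditional_entropy",
    "ordinal_pattern",
    "ordinal_distribution",
    "permen",
]


@dataclass(frozen=True)
class QuantizationSpec:
    """Quantification level xi: number of equal-width amplitude bins."""

    xi: int = 6

    def __post_init__(self) -> None:
        if int(self.xi) < 1:
            raise InvalidParameterError(f"quantification level xi must be >= 1, got {self.xi}")
        object.__setattr__(self, "xi", int(self.xi))


@dataclass(frozen=True)
class MotifDistribution:
    """Observed decimal motif codes with their empirical frequencies."""

    dimension: int
    codes: np.ndarray
    frequencies: np.ndarray


@dataclass(frozen=True)
class OrdinalPatternDistribution:
    """Observed ordinal patterns (rows) with their empirical frequencies."""

    dimension: int
    patterns: np.ndarray
    frequencies: np.ndarray


def coarse_grain(series: TimeSeries, q: QuantizationSpec) -> np.ndarray:
    """Quantize unmasked samples into levels 0..xi-1.

    The resolution is ``(max - min) / xi`` over unmasked samples; the
    maximum clips into the top level.  A constant series (or xi = 1) maps
    everything to level 0 so CE stays defined on degenerate windows.
    Masked samples remain NaN.  Returns a float array of integer levels.
    """
    values = series.values
    finite = series.unmasked
    if finite.size < 1:
        raise InsufficientDataError("coarse graining needs at least one unmasked sample")
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo or q.xi == 1:
        levels = np.where(np.isnan(values), np.nan, 0.0)
        return levels
    delta = (hi - lo) / q.xi
    levels = np.floor((values - lo) / delta)
    return np.minimum(levels, q.xi - 1)  # minimum (not fmin) keeps NaN masked


def codify_motifs(levels: np.ndarray, d: int, q: QuantizationSpec) -> MotifDistribution:
    """Decimal codification of consecutive (delay-1) level motifs of length d.

    A motif ``(l_0, ..., l_{d-1})`` codes to ``sum l_k * xi**(d-1-k)``;
    motifs overlapping masked samples are dropped and frequencies are
    normalized over the remaining motifs.
    """
    levels = np.asarray(levels, dtype=np.float64)
    if d < 1:
        raise InvalidParameterError(f"motif length must be >= 1, got {d}")
    if levels.size < d:
        raise InsufficientDataError(f"no complete motif of length {d} in {levels.size} samples")
    windows = np.lib.stride_tricks.sliding_window_view(levels, d)
    valid = ~np.isnan(windows).any(axis=1)
    if not valid.any():
        raise InsufficientDataError(f"all motifs of length {d} overlap masked samples")
    weights = float(q.xi) ** np.arange(d - 1, -1, -1)
    codes = np.rint(windows[valid] @ weights).astype(np.int64)
    uniq, counts = np.unique(codes, return_counts=True)
    return MotifDistribution(dimension=d, codes=uniq, frequencies=counts / counts.sum())


def shannon_entropy(frequencies, base: float = math.e) -> float:
    """Shannon entropy ``-sum p log(p)`` with ``0 log 0 = 0``.

    Raises
    ------
    NonNormalizedDistributionError
        If the frequencies are negative or do not sum to 1 within 1e-9.
    """
    p = np.asarray(frequencies, dtype=np.float64)
    if (p < 0).any():
        raise NonNormalizedDistributionError("negative probability mass")
    total = float(p.sum())
    if abs(total - 1.0) > 1e-9:
        raise NonNormalizedDistributionError(f"frequencies sum to {total}, expected 1")
    nz = p[p > 0]
    h = -float(np.sum(nz * np.log(nz)))
    if base != math.e:
        h /= math.log(base)
    return h


def conditional_entropy(
    series: TimeSeries,
    m: int,
    q: QuantizationSpec = QuantizationSpec(),
    base: float = math.e,
) -> float:
    """CE = SE(motifs of length m+1) - SE(motifs of length m) on the
    coarse-grained series."""
    if m < 1:
        raise InvalidParameterError(f"CE motif length m must be >= 1, got {m}")
    levels = coarse_grain(series, q)
    se_m1 = shannon_entropy(codify_motifs(levels, m + 1, q).frequencies, base)
    se_m = shannon_entropy(codify_motifs(levels, m, q).frequencies, base)
    return se_m1 - se_m


def ordinal_pattern(motif) -> tuple[int, ...]:
    """The permutation indexing *motif*'s elements in ascending order.

    Ties rank by original position (stable), so ``(2, 2) -> (0, 1)``.
    """
    arr = np.asarray(motif, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 2:
        raise InvalidParameterError("an ordinal pattern needs a 1-D motif of length >= 2")
    if np.isnan(arr).any():
        raise InvalidParameterError("ordinal pattern undefined for motifs with masked samples")
    return tuple(int(i) for i in np.argsort(arr, kind="stable"))


def ordinal_distribution(series: TimeSeries, params: EmbeddingParams) -> OrdinalPatternDistribution:
    """Empirical distribution of ordinal patterns over all valid tau-spaced
    motifs of length m (N - (m-1)*tau motifs on a gap-free series)."""
    m, tau = params.m, params.tau
    if m < 2:
        raise InvalidParameterError(f"permutation patterns need m >= 2, got m={m}")
    count = series.n - (m - 1) * tau
    if count < 1:
        raise InsufficientDataError(
            f"series of N={series.n} samples has no motif of length {m} with delay {tau}"
        )
    idx = np.arange(count)[:, None] + np.arange(m)[None, :] * tau
    motifs = series.values[idx]
    valid = ~np.isnan(motifs).any(axis=1)
    if not valid.any():
        raise InsufficientDataError("all motifs overlap masked samples")
    patterns = np.argsort(motifs[valid], axis=1, kind="stable")
    uniq, counts = np.unique(patterns, axis=0, return_counts=True)
    return OrdinalPatternDistribution(dimension=m, patterns=uniq, frequencies=counts / counts.sum())


def permen(series: TimeSeries, params: EmbeddingParams, base: float = math.e) -> float:
    """Permutation entropy: Shannon entropy of the ordinal-pattern
    distribution, unnormalized, in ``[0, ln(m!)]``."""
    return shannon_entropy(ordinal_distribution(series, params).frequencies, base)
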