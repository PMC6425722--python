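"""Similarity-based entropy metrics: ApEn, SampEn and FuzzyEn.

All three compare the state-space vectors at dimensions m and m+1.  ApEn
counts matches (Chebyshev distance <= r) *including* the self-match and
averages log match fractions; SampEn excludes self-matches and takes
-ln of the ratio of the (m+1)- to m-dimensional match probabilities;
FuzzyEn replaces the hard match indicator with the Gaussian membership
degree ``exp(-ln(2) * (d/r)^2)``, which keeps the estimate finite on short
series where SampEn's match counts can hit zero.

The tolerance r is conventionally a fraction of the series standard
deviation; :class:`ToleranceSpec` makes that convention explicit and also
supports an absolute r for exactness tests.

Counting is chunked (see :func:`entrokit.embedding.pairwise_chebyshev`) so
recordings near the 10,000-point guard fit comfortably in memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingParams, pairwise_chebyshev, reconstruct
from .errors import DegenerateSeriesError, InsufficientVectorsError, InvalidParameterError
from .signal_model import TimeSeries

__all__ = [
    "UNDEFINED",
    "ToleranceSpec",
    "SimilarityProfile",
    "resolve_tolerance",
    "fuzzy_membership",
    "similarity_profile",
    "apen",
    "sampen",
    "fuzzyen",
]

#: Marker for an undefined metric value (e.g. SampEn with zero matches).
#: NaN rather than an exception, so windowed/batch runs carry on.
UNDEFINED = float("nan")

_LN2 = math.log(2.0)

_VARIANTS = ("include_self_log_mean", "exclude_self_mean", "fuzzy_membership_mean")

_CHUNK = 1024  # templates per block in the pairwise sweep


@dataclass(frozen=True)
class ToleranceSpec:
    """Similarity tolerance r.

    ``relative_to_sd`` (the field convention and the default) scales
    ``value`` by the sample SD of the unmasked series it is applied to;
    ``absolute`` uses ``value`` as-is, in signal units.
    """

    value: float = 0.2
    mode: str = "relative_to_sd"

    def __post_init__(self) -> None:
        if self.mode not in ("relative_to_sd", "absolute"):
            raise InvalidParameterError(f"tolerance mode must be 'relative_to_sd' or 'absolute', got {self.mode!r}")
        if not self.value > 0:
            raise InvalidParameterError(f"tolerance value must be > 0, got {self.value}")


@dataclass(frozen=True)
class SimilarityProfile:
    """Per-template match statistics at one dimension.

    ``match_fractions`` holds C_i (self-matches included), A_i (excluded)
    or the mean fuzzy membership, depending on ``variant``; ``aggregate``
    is the mean of ln C_i for the include-self variant and the plain mean
    otherwise.
    """

    dimension: int
    variant: str
    match_counts: np.ndarray
    match_fractions: np.ndarray
    aggregate: float


def resolve_tolerance(series: TimeSeries, spec: ToleranceSpec) -> float:
    """Turn a :class:`ToleranceSpec` into an absolute r for *series*."""
    if spec.mode == "absolute":
        return float(spec.value)
    finite = series.unmasked
    if finite.size < 2:
        raise DegenerateSeriesError("relative tolerance needs at least two unmasked samples")
    sd = float(np.std(finite, ddof=1))
    if sd == 0.0:
        raise DegenerateSeriesError("relative tolerance undefined: series standard deviation is zero")
    return float(spec.value) * sd


def fuzzy_membership(d, r: float):
    """Gaussian membership degree ``exp(-ln(2) * (d/r)^2)``.

    Equals 1 at d = 0 and exactly 0.5 at d = r; strictly positive for all
    finite distances.  Accepts scalars or arrays.
    """
    d = np.asarray(d, dtype=np.float64)
    out = np.exp(-_LN2 * (d / r) ** 2)
    return float(out) if out.ndim == 0 else out


def _valid_templates(series: TimeSeries, params: EmbeddingParams, dimension: int) -> np.ndarray:
    vs = reconstruct(series, params, dimension)
    valid = vs.valid_vectors
    if valid.shape[0] < 2:
        raise InsufficientVectorsError(
            f"similarity profile at dimension {dimension} needs at least 2 valid vectors, "
            f"got {valid.shape[0]}"
        )
    return valid


def similarity_profile(
    series: TimeSeries,
    params: EmbeddingParams,
    dimension: int,
    r: float,
    variant: str,
) -> SimilarityProfile:
    """Match statistics of every template against every other at *dimension*.

    With V valid templates:

    - ``include_self_log_mean``: C_i = N_i / V with j ranging over all
      templates (including i); aggregate = mean of ln C_i.
    - ``exclude_self_mean``: A_i = N_i / (V - 1) with j != i;
      aggregate = mean of A_i.
    - ``fuzzy_membership_mean``: A_i = mean over j != i of the Gaussian
      membership of d_ij; aggregate = mean of A_i.

    V equals N - dimension*tau when the series has no gaps.
    """
    if variant not in _VARIANTS:
        raise InvalidParameterError(f"unknown similarity variant {variant!r}")
    if not r > 0:
        raise InvalidParameterError(f"tolerance r must be > 0, got {r}")
    templates = _valid_templates(series, params, dimension)
    v = templates.shape[0]
    fuzzy = variant == "fuzzy_membership_mean"
    counts = np.empty(v, dtype=np.int64)
    sums = np.empty(v, dtype=np.float64) if fuzzy else None
    for i0 in range(0, v, _CHUNK):
        i1 = min(i0 + _CHUNK, v)
        dists = pairwise_chebyshev(templates[i0:i1], templates)
        counts[i0:i1] = np.count_nonzero(dists <= r, axis=1)
        if fuzzy:
            np.exp(-_LN2 * (dists / r) ** 2, out=dists)
            # zero the self-membership before summing: subtracting the 1.0
            # afterwards would cancel away tiny memberships
            dists[np.arange(i1 - i0), np.arange(i0, i1)] = 0.0
            sums[i0:i1] = dists.sum(axis=1)

    if variant == "include_self_log_mean":
        fractions = counts / v
        aggregate = float(np.mean(np.log(fractions)))
    elif variant == "exclude_self_mean":
        counts = counts - 1  # the zero self-distance always matched
        fractions = counts / (v - 1)
        aggregate = float(np.mean(fractions))
    else:
        counts = counts - 1
        fractions = sums / (v - 1)
        aggregate = float(np.mean(fractions))
    return SimilarityProfile(
        dimension=dimension,
        variant=variant,
        match_counts=counts,
        match_fractions=fractions,
        aggregate=aggregate,
    )


def _check_length(series: TimeSeries, params: EmbeddingParams) -> None:
    # all three metrics need vectors at dimension m+1
    from .errors import TooShortSeriesError

    needed = (params.m + 1) * params.tau + 1
    if series.n < needed:
        raise TooShortSeriesError(
            f"series of N={series.n} samples is too short for dimension {params.m + 1} "
            f"with delay {params.tau}; at least N={needed} samples are required"
        )


def _resolve(series: TimeSeries, r: ToleranceSpec | float) -> float:
    if isinstance(r, ToleranceSpec):
        return resolve_tolerance(series, r)
    if not float(r) > 0:
        raise InvalidParameterError(f"tolerance r must be > 0, got {r}")
    return float(r)


def apen(series: TimeSeries, params: EmbeddingParams, r: ToleranceSpec | float = ToleranceSpec()) -> float:
    """Approximate entropy: Phi^(m)(r) - Phi^(m+1)(r).

    Self-matches keep every C_i >= 1/V, so the logarithms are always
    finite.  A bare float *r* is taken as an absolute tolerance.
    """
    _check_length(series, params)
    r_abs = _resolve(series, r)
    phi_m = similarity_profile(series, params, params.m, r_abs, "include_self_log_mean").aggregate
    phi_m1 = similarity_profile(series, params, params.m + 1, r_abs, "include_self_log_mean").aggregate
    return phi_m - phi_m1


def sampen(series: TimeSeries, params: EmbeddingParams, r: ToleranceSpec | float = ToleranceSpec()) -> float:
    """Sample entropy: -ln(Psi^(m+1)(r) / Psi^(m)(r)), self-matches excluded.

    Returns the :data:`UNDEFINED` NaN marker instead of raising when either
    match probability is zero, so sliding-window and batch runs continue.
    """
    _check_length(series, params)
    r_abs = _resolve(series, r)
    psi_m = similarity_profile(series, params, params.m, r_abs, "exclude_self_mean").aggregate
    psi_m1 = similarity_profile(series, params, params.m + 1, r_abs, "exclude_self_mean").aggregate
    if psi_m == 0.0 or psi_m1 == 0.0:
        return UNDEFINED
    return -math.log(psi_m1 / psi_m)


def fuzzyen(series: TimeSeries, params: EmbeddingParams, r: ToleranceSpec | float = ToleranceSpec()) -> float:
    """Fuzzy entropy: the SampEn ratio with Gaussian membership degrees.

    Memberships are strictly positive, so the result is finite wherever the
    embedding itself is feasible.
    """
    _check_length(series, params)
    r_abs = _resolve(series, r)
    a_m = similarity_profile(series, params, params.m, r_abs, "fuzzy_membership_mean").aggregate
    a_m1 = similarity_profile(series, params, params.m + 1, r_abs, "fuzzy_membership_mean").aggregate
    if a_m <= 0.0 or a_m1 <= 0.0:
        # memberships are strictly positive in exact arithmetic but can
        # underflow to zero at extreme d/r ratios
        return UNDEFINED
    return -math.log(a_m1 / a_m)
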