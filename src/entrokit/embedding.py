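"""Time-delay embedding and Chebyshev distance machinery.

A series ``u(1..N)`` is reconstructed into d-dimensional state-space
vectors ``X_d(i) = (u(i), u(i+tau), ..., u(i+(d-1)tau))`` for
``i = 1 .. N - d*tau``; similarity between vectors is measured with the
Chebyshev (maximum-coordinate) distance.  Vectors touching a masked gap
sample are flagged invalid and excluded from every pairwise computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    DimensionMismatchError,
    InsufficientVectorsError,
    InvalidParameterError,
    TooShortSeriesError,
)
from .signal_model import TimeSeries

__all__ = [
    "EmbeddingParams",
    "VectorSet",
    "DistanceMatrix",
    "reconstruct",
    "chebyshev_distance",
    "pairwise_chebyshev",
    "distance_matrix",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Embedding dimension (motif length) m and time delay tau, in samples."""

    m: int = 2
    tau: int = 1

    def __post_init__(self) -> None:
        if int(self.m) < 1:
            raise InvalidParameterError(f"embedding dimension m must be >= 1, got {self.m}")
        if int(self.tau) < 1:
            raise InvalidParameterError(f"time delay tau must be >= 1, got {self.tau}")
        object.__setattr__(self, "m", int(self.m))
        object.__setattr__(self, "tau", int(self.tau))


@dataclass(frozen=True)
class VectorSet:
    """The reconstructed vectors at one dimension.

    ``vectors[i, k] = u(origin_index[i] + k*tau)`` (1-based origins);
    ``valid_mask[i]`` is False when any element of vector i is NaN.
    """

    dimension: int
    tau: int
    vectors: np.ndarray
    origin_index: np.ndarray
    valid_mask: np.ndarray

    @property
    def n_vectors(self) -> int:
        return int(self.vectors.shape[0])

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid_mask))

    @property
    def valid_vectors(self) -> np.ndarray:
        return self.vectors[self.valid_mask]

    @property
    def valid_origin_index(self) -> np.ndarray:
        return self.origin_index[self.valid_mask]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise Chebyshev distances between the valid
    vectors of one :class:`VectorSet`, ordered by origin index."""

    dimension: int
    entries: np.ndarray
    origin_index: np.ndarray

    @property
    def size(self) -> int:
        return int(self.entries.shape[0])


def reconstruct(series: TimeSeries, params: EmbeddingParams, dimension: int | None = None) -> VectorSet:
    """Embed *series* at *dimension* (default ``params.m``) with delay tau.

    Produces exactly ``N - dimension*tau`` vectors.

    Raises
    ------
    TooShortSeriesError
        When ``N - dimension*tau < 1``; the message names the minimum N.
    """
    d = params.m if dimension is None else int(dimension)
    if d < 1:
        raise InvalidParameterError(f"dimension must be >= 1, got {d}")
    tau = params.tau
    count = series.n - d * tau
    if count < 1:
        raise TooShortSeriesError(
            f"series of N={series.n} samples is too short for dimension {d} with "
            f"delay {tau}; at least N={d * tau + 1} samples are required"
        )
    idx = np.arange(count)[:, None] + np.arange(d)[None, :] * tau
    vectors = series.values[idx]
    valid = ~np.isnan(vectors).any(axis=1)
    return VectorSet(
        dimension=d,
        tau=tau,
        vectors=vectors,
        origin_index=np.arange(1, count + 1),
        valid_mask=valid,
    )


def chebyshev_distance(a, b) -> float:
    """Maximum absolute coordinate difference between two equal-length vectors."""
    av = np.asarray(a, dtype=np.float64)
    bv = np.asarray(b, dtype=np.float64)
    if av.shape != bv.shape:
        raise DimensionMismatchError(f"vector dimensions differ: {av.shape} vs {bv.shape}")
    return float(np.max(np.abs(av - bv)))


def pairwise_chebyshev(block: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Chebyshev distances between every row of *block* and every row of
    *others*, returned as a ``len(block) x len(others)`` array.

    Accumulates the coordinate-wise maximum in place so peak memory is one
    block-by-others buffer regardless of dimension; this is what lets the
    similarity profiles run on ~10,000-vector recordings without holding a
    full distance matrix.
    """
    out = np.abs(block[:, None, 0] - others[None, :, 0])
    for k in range(1, block.shape[1]):
        np.maximum(out, np.abs(block[:, None, k] - others[None, :, k]), out=out)
    return out


def distance_matrix(vs: VectorSet) -> DistanceMatrix:
    """Full symmetric Chebyshev distance matrix over the valid vectors.

    Raises
    ------
    InsufficientVectorsError
        When fewer than two valid vectors exist.
    """
    valid = vs.valid_vectors
    if valid.shape[0] < 2:
        raise InsufficientVectorsError(
            f"distance matrix needs at least 2 valid vectors, got {valid.shape[0]}"
        )
    entries = cdist(valid, valid, metric="chebyshev")
    np.fill_diagonal(entries, 0.0)
    return DistanceMatrix(dimension=vs.dimension, entries=entries, origin_index=vs.valid_origin_index)
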