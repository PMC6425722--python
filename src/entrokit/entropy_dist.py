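"""Distribution entropy and the intermediate diagnostic products.

DistEn summarizes the *whole* inter-vector distance structure instead of
thresholding it: the off-diagonal Chebyshev distances are binned into a
fixed number B of equal-width bins and DistEn is their Shannon entropy in
base 2, normalized by log2(B) so the result lies in [0, 1].

The same machinery exposes the diagnostics a practitioner inspects while
tuning parameters: the distance maps at dimensions m and m+1, the distance
PDF/CDF at both dimensions, and the motif / ordinal-pattern probability
tables.  These are first-class arrays with optional CSV/PNG export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .embedding import (
    DistanceMatrix,
    EmbeddingParams,
    distance_matrix,
    pairwise_chebyshev,
    reconstruct,
)
from .errors import InsufficientDataError, InvalidParameterError
from .entropy_symbolic import (
    MotifDistribution,
    OrdinalPatternDistribution,
    QuantizationSpec,
    coarse_grain,
    codify_motifs,
    ordinal_distribution,
)
from .signal_model import TimeSeries

__all__ = [
    "DEFAULT_BINS",
    "DistanceHistogram",
    "IntermediateBundle",
    "distance_histogram",
    "distance_cdf",
    "disten",
    "intermediate_bundle",
    "export_bundle",
]

#: Default histogram bin count B.
DEFAULT_BINS = 512

# above this many vectors the full distance matrix is not materialized
_FULL_MATRIX_LIMIT = 3000
_CHUNK = 1024


@dataclass(frozen=True)
class DistanceHistogram:
    """Equal-width histogram of off-diagonal distances: B+1 edges and B
    bin probabilities summing to 1."""

    edges: np.ndarray
    probabilities: np.ndarray

    @property
    def bin_count(self) -> int:
        return int(self.probabilities.size)


@dataclass(frozen=True)
class IntermediateBundle:
    """Diagnostics at dimensions m and m+1 for one analyzed segment."""

    distance_map_m: DistanceMatrix
    distance_map_m1: DistanceMatrix
    pdf_m: DistanceHistogram
    pdf_m1: DistanceHistogram
    cdf_m: np.ndarray
    cdf_m1: np.ndarray
    motif_probabilities: MotifDistribution
    ordinal_probabilities: OrdinalPatternDistribution | None


def _histogram_from_distances(dists: np.ndarray, bins: int) -> DistanceHistogram:
    lo, hi = float(dists.min()), float(dists.max())
    if hi == lo:
        # degenerate range: all mass in the first bin
        p = np.zeros(bins)
        p[0] = 1.0
        return DistanceHistogram(edges=np.full(bins + 1, lo), probabilities=p)
    counts, edges = np.histogram(dists, bins=bins, range=(lo, hi))
    return DistanceHistogram(edges=edges, probabilities=counts / counts.sum())


def distance_histogram(dm: DistanceMatrix, bins: int = DEFAULT_BINS) -> DistanceHistogram:
    """Histogram of the upper-triangle (i < j) distances of *dm* with *bins*
    equal-width bins spanning their [min, max]; the top bin is right-closed.

    Each unordered pair is counted once; by symmetry the probabilities are
    identical to double counting.
    """
    if bins < 2:
        raise InvalidParameterError(f"bin count B must be >= 2, got {bins}")
    v = dm.size
    if v < 2:
        raise InsufficientDataError("distance histogram needs at least 2 valid vectors")
    dists = dm.entries[np.triu_indices(v, k=1)]
    return _histogram_from_distances(dists, bins)


def distance_cdf(h: DistanceHistogram) -> np.ndarray:
    """Cumulative distribution over the histogram bins (non-decreasing,
    final element 1)."""
    return np.cumsum(h.probabilities)


def _upper_triangle_blocks(templates: np.ndarray):
    v = templates.shape[0]
    for i0 in range(0, v, _CHUNK):
        i1 = min(i0 + _CHUNK, v)
        dists = pairwise_chebyshev(templates[i0:i1], templates)
        rows = [dists[i - i0, i + 1 :] for i in range(i0, i1)]
        yield np.concatenate(rows) if rows else np.empty(0)


def disten(series: TimeSeries, params: EmbeddingParams, bins: int = DEFAULT_BINS) -> float:
    """Distribution entropy ``-(1/log2 B) * sum p_t log2 p_t`` over the
    B-bin histogram of all inter-vector distances at dimension m.

    Always in [0, 1]; 0 for a constant series (single occupied bin).
    Large vector sets are processed in two chunked passes (range, then
    binning) instead of materializing the full distance matrix.
    """
    if bins < 2:
        raise InvalidParameterError(f"bin count B must be >= 2, got {bins}")
    vs = reconstruct(series, params, params.m)
    templates = vs.valid_vectors
    v = templates.shape[0]
    if v < 2:
        raise InsufficientDataError("DistEn needs at least 2 valid vectors")
    if v <= _FULL_MATRIX_LIMIT:
        hist = distance_histogram(distance_matrix(vs), bins)
    else:
        lo = math.inf
        hi = -math.inf
        for block in _upper_triangle_blocks(templates):
            lo = min(lo, float(block.min()))
            hi = max(hi, float(block.max()))
        if hi == lo:
            return 0.0
        counts = np.zeros(bins, dtype=np.int64)
        edges = np.linspace(lo, hi, bins + 1)
        for block in _upper_triangle_blocks(templates):
            c, _ = np.histogram(block, bins=edges)
            counts += c
        hist = DistanceHistogram(edges=edges, probabilities=counts / counts.sum())
    p = hist.probabilities
    nz = p[p > 0]
    return -float(np.sum(nz * np.log2(nz))) / math.log2(bins)


def intermediate_bundle(
    series: TimeSeries,
    params: EmbeddingParams,
    bins: int = DEFAULT_BINS,
    q: QuantizationSpec = QuantizationSpec(),
) -> IntermediateBundle:
    """Distance maps, PDFs and CDFs at dimensions m and m+1, plus the motif
    and ordinal-pattern probability tables for one segment.

    Materializes full distance matrices — intended for windows and short
    recordings, which is where these diagnostics are inspected.
    """
    dm_m = distance_matrix(reconstruct(series, params, params.m))
    dm_m1 = distance_matrix(reconstruct(series, params, params.m + 1))
    pdf_m = distance_histogram(dm_m, bins)
    pdf_m1 = distance_histogram(dm_m1, bins)
    levels = coarse_grain(series, q)
    motifs = codify_motifs(levels, params.m, q)
    ordinals = ordinal_distribution(series, params) if params.m >= 2 else None
    return IntermediateBundle(
        distance_map_m=dm_m,
        distance_map_m1=dm_m1,
        pdf_m=pdf_m,
        pdf_m1=pdf_m1,
        cdf_m=distance_cdf(pdf_m),
        cdf_m1=distance_cdf(pdf_m1),
        motif_probabilities=motifs,
        ordinal_probabilities=ordinals,
    )


def _write_two_column(path: Path, x: np.ndarray, y: np.ndarray) -> None:
    np.savetxt(path, np.column_stack([x, y]), delimiter=",", fmt="%.17g")


def export_bundle(bundle: IntermediateBundle, directory, stem: str, png: bool = False) -> list[Path]:
    """Write the bundle to *directory* as comma-separated files (and
    optionally grayscale PNG distance maps); returns the paths written.

    PDFs/CDFs are two-column (bin center, probability) files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for tag, dm in (("m", bundle.distance_map_m), ("m1", bundle.distance_map_m1)):
        p = directory / f"{stem}_distmap_{tag}.csv"
        np.savetxt(p, dm.entries, delimiter=",", fmt="%.17g")
        written.append(p)
        if png:
            import matplotlib.image as mpimg

            img = directory / f"{stem}_distmap_{tag}.png"
            mpimg.imsave(img, dm.entries, cmap="gray")
            written.append(img)
    for tag, pdf, cdf in (
        ("m", bundle.pdf_m, bundle.cdf_m),
        ("m1", bundle.pdf_m1, bundle.cdf_m1),
    ):
        centers = (pdf.edges[:-1] + pdf.edges[1:]) / 2.0
        p = directory / f"{stem}_pdf_{tag}.csv"
        _write_two_column(p, centers, pdf.probabilities)
        written.append(p)
        p = directory / f"{stem}_cdf_{tag}.csv"
        _write_two_column(p, centers, cdf)
        written.append(p)
    p = directory / f"{stem}_motifs.csv"
    _write_two_column(p, bundle.motif_probabilities.codes, bundle.motif_probabilities.frequencies)
    written.append(p)
    return written
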