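"""Independent naive reference implementations used as test oracles.

Everything here is deliberately written as plain Python loops over the
defining formulas — no numpy vectorization, no code shared with the
package — so agreement with the library is a genuine cross-check.
"""

from __future__ import annotations

import math
from bisect import bisect_right


def embed(u, d, tau):
    """Vectors (u[i], u[i+tau], ..., u[i+(d-1)tau]) for i = 0..N-d*tau-1."""
    count = len(u) - d * tau
    return [[u[i + k * tau] for k in range(d)] for i in range(count)]


def cheb(a, b):
    return max(abs(x - y) for x, y in zip(a, b))


def naive_apen(u, m, tau, r):
    phis = []
    for d in (m, m + 1):
        vectors = embed(u, d, tau)
        v = len(vectors)
        logs = []
        for i in range(v):
            count = sum(1 for j in range(v) if cheb(vectors[i], vectors[j]) <= r)
            logs.append(math.log(count / v))
        phis.append(sum(logs) / v)
    return phis[0] - phis[1]


def naive_sampen(u, m, tau, r):
    psis = []
    for d in (m, m + 1):
        vectors = embed(u, d, tau)
        v = len(vectors)
        fractions = []
        for i in range(v):
            count = sum(1 for j in range(v) if j != i and cheb(vectors[i], vectors[j]) <= r)
            fractions.append(count / (v - 1))
        psis.append(sum(fractions) / v)
    if psis[0] == 0.0 or psis[1] == 0.0:
        return float("nan")
    return -math.log(psis[1] / psis[0])


def naive_fuzzyen(u, m, tau, r):
    ln2 = math.log(2.0)
    means = []
    for d in (m, m + 1):
        vectors = embed(u, d, tau)
        v = len(vectors)
        fractions = []
        for i in range(v):
            total = sum(
                math.exp(-ln2 * (cheb(vectors[i], vectors[j]) / r) ** 2)
                for j in range(v)
                if j != i
            )
            fractions.append(total / (v - 1))
        means.append(sum(fractions) / v)
    return -math.log(means[1] / means[0])


def naive_coarse_grain(u, xi):
    lo, hi = min(u), max(u)
    if hi == lo or xi == 1:
        return [0] * len(u)
    delta = (hi - lo) / xi
    return [min(int(math.floor((x - lo) / delta)), xi - 1) for x in u]


def _naive_shannon(counts):
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def naive_ce(u, m, tau_unused, xi):
    levels = naive_coarse_grain(u, xi)
    entropies = []
    for d in (m, m + 1):
        counts = {}
        for i in range(len(levels) - d + 1):
            code = 0
            for k in range(d):
                code = code * xi + levels[i + k]
            counts[code] = counts.get(code, 0) + 1
        entropies.append(_naive_shannon(counts))
    return entropies[1] - entropies[0]


def naive_permen(u, m, tau):
    counts = {}
    for i in range(len(u) - (m - 1) * tau):
        motif = [u[i + k * tau] for k in range(m)]
        pattern = tuple(sorted(range(m), key=lambda k: (motif[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    return _naive_shannon(counts)


def naive_pair_distances(u, m, tau):
    vectors = embed(u, m, tau)
    v = len(vectors)
    return [cheb(vectors[i], vectors[j]) for i in range(v) for j in range(i + 1, v)]


def naive_bin_counts(dists, bins):
    """Per-pair binning over equal-width bins spanning [min, max]; top bin
    right-closed."""
    lo, hi = min(dists), max(dists)
    counts = [0] * bins
    if hi == lo:
        counts[0] = len(dists)
        return counts
    step = (hi - lo) / bins
    edges = [lo + step * i for i in range(bins)] + [hi]
    for d in dists:
        idx = bisect_right(edges, d) - 1
        if idx == bins:  # d == hi
            idx = bins - 1
        counts[idx] += 1
    return counts


def naive_disten(u, m, tau, bins):
    dists = naive_pair_distances(u, m, tau)
    counts = naive_bin_counts(dists, bins)
    total = sum(counts)
    h = -sum((c / total) * math.log2(c / total) for c in counts if c > 0)
    return h / math.log2(bins)
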