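# Methods

## The problem

Physiological recordings (heart-beat intervals, EEG, blood-pressure
series) carry structure that moments and spectra miss. Entropy statistics
quantify the *irregularity* of a series — how unpredictable the next
sample is given short histories — and have become standard descriptors in
biomedical signal analysis. entrokit implements six of these statistics
and the machinery that makes them usable on real recordings: gap masking,
normalization, sliding windows, batch runs and CSV export.

## State-space embedding

A series `u(1..N)` is embedded into delay vectors

    X_d(i) = (u(i), u(i+τ), ..., u(i+(d-1)τ)),   i = 1 .. N − d·τ,

and vector similarity is measured by the Chebyshev distance
`d_ij = max_k |u(i+kτ) − u(j+kτ)|`. The `i ≤ N − d·τ` index range is used
verbatim for the similarity-based metrics. Note this differs from the
Richman–Moorman convention (`N − (m−1)τ` templates compared over a common
index range at both dimensions); users comparing against other SampEn
implementations should expect small finite-size differences that vanish
as N grows. Permutation entropy is the exception: its motif range is the
standard Bandt–Pompe `i ≤ N − (m−1)τ`, which is what the ordinal-pattern
literature and the worked example in the test-suite use.

Vectors that touch a masked (NaN) sample are excluded entirely — never
imputed — and all per-template denominators use the count of *valid*
templates V (identical to `N − d·τ` on gap-free data).

## The six metrics

- **ApEn(m, τ, r)** = Φ⁽ᵐ⁾(r) − Φ⁽ᵐ⁺¹⁾(r), where
  Φ⁽ᵈ⁾ = mean over i of ln C_i, C_i = (matches of template i, self
  included)/V. Self-matches keep every C_i > 0 so ApEn is always finite.
- **SampEn(m, τ, r)** = −ln(Ψ⁽ᵐ⁺¹⁾/Ψ⁽ᵐ⁾), Ψ⁽ᵈ⁾ = mean of
  A_i = (matches, self excluded)/(V−1). When either Ψ is zero the value
  is *undefined*; entrokit returns NaN rather than raising so windowed
  and batch runs continue (the CSV writer renders it as an empty field).
- **FuzzyEn(m, τ, r)**: SampEn with the hard indicator `d ≤ r` replaced
  by the Gaussian membership `exp(−ln2 · (d/r)²)` (1 at d = 0, ½ at
  d = r). Memberships are strictly positive, which is what makes the
  statistic usable on short windows.
- **CE(m, ξ)**: the series is coarse-grained into ξ amplitude levels of
  width (max−min)/ξ (max clips into the top level; a constant series maps
  to level 0 so CE is defined, and zero, on degenerate windows). Motifs of
  consecutive levels (delay 1) of lengths m and m+1 are codified as
  decimal integers with the first element weighted ξ^(m−1), and
  CE = SE(m+1) − SE(m) with SE the Shannon entropy of the code
  frequencies.
- **PermEn(m, τ)**: the Shannon entropy (unnormalized) of the ordinal
  patterns of the τ-spaced motifs, ties broken by position. Bounded by
  ln(m!), zero for monotone series, invariant under any strictly
  increasing transform of the amplitudes.
- **DistEn(m, τ, B)**: the off-diagonal Chebyshev distances at dimension
  m are binned into B equal-width bins spanning their observed
  [min, max] (top bin right-closed; every unordered pair counted once —
  symmetry makes this identical to counting both triangles), and
  DistEn = −(1/log₂B) Σ p_t log₂ p_t ∈ [0, 1].

CE and PermEn use the natural logarithm by default (base configurable);
DistEn is defined with base 2 and its 1/log₂B normalization.

## Parameter defaults and units

| parameter | meaning | default | notes |
|---|---|---|---|
| m | embedding dimension / motif length | 2 | community standard for short physiological series |
| τ | time delay (samples) | 1 | |
| r | similarity tolerance | 0.2·SD | sample SD (N−1); `absolute` mode takes r in signal units |
| ξ | CE quantification levels | 6 | typical coarse-graining choice for CE |
| B | DistEn histogram bins | 512 | entropy is normalized by log₂B, so B mainly sets resolution |
| guard | whole-series length limit | 10,000 points | strict `>` comparison; window or workstation mode bypasses |
| window overlap→step | `step = W − round(W·p/100)` | p = 0 | half-away-from-zero rounding; trailing partial windows are dropped (a window at a different N is not comparable) |

The relative tolerance is resolved per window by default (each window is
an independent analysis with its own SD); `tolerance_scope="recording"`
switches to a single recording-wide r.

Normalization (`zscore`, sample SD; `minmax`; or `none`, the default)
uses unmasked samples only and is applied after gap masking and before
windowing.

## The analysis engine

Gap files (`Gap/<stem>.gap` next to the signal, two integer columns,
1-based inclusive start/end) mark artifact intervals; masked samples are
NaN throughout and excluded from every statistic. A missing gap file is
silently ignored; an unreadable one is logged and ignored.

A whole-series analysis of more than 10,000 points is refused with a
message naming the three remedies (window, workstation flag, shorter
recording) — a memory-protective default; the threshold is configurable
and windowed runs are exempt. Batch runs process a list file in order;
a missing or unparsable recording becomes an error row (the fixed CSV
schema carries a trailing `error` column for exactly this) and the run
continues. With write-while-analyze, each file's rows are flushed to the
results file before the next file is read and only the current file is
held in memory.

Everything is deterministic: identical inputs and configuration give a
bit-identical result table.

## Numerical choices

- Pairwise distances are computed in fixed-size template blocks,
  accumulating the coordinate-wise maximum in place, so memory stays
  ~block×V instead of V²; a 10,000-point recording with all six metrics
  runs in well under a minute on one CPU core.
- Fuzzy memberships are summed with the self-term zeroed *before* the
  sum — subtracting the self-membership 1.0 afterwards would cancel away
  memberships below machine epsilon. If every membership underflows to
  zero (astronomically large d/r), FuzzyEn returns the undefined marker.
- DistEn above 3,000 vectors switches to a two-pass chunked histogram
  (range sweep, then binning) with results identical to the
  materialized-matrix path.
- Results CSV renders floats with 17 significant digits, so every value
  round-trips exactly; undefined values are empty fields.
- Degenerate inputs: constant series raise a degenerate-series error
  under zscore/minmax and relative tolerance; coarse-graining maps them
  to level 0 (CE = 0); an all-equal distance set puts all histogram mass
  in one bin (DistEn = 0).

## The synthetic generator

`entrokit.fixtures` generates the signal families the metrics are
sensitive to: constant, period-2 alternating, sine, iid Gaussian and
uniform noise, AR(1) (burn-in of 1,000 samples to wash out the initial
condition), and the logistic map. Stochastic kinds are driven by numpy's
PCG64 (`default_rng`), pinned for cross-release stability. These fixtures
exercise the known closed forms — e.g. iid data has
SampEn → −ln(2Φ(r/σ√2) − 1) for any m, PermEn → ln m!, CE → ln ξ — and
the engine's gap/window plumbing.

What they do not emulate: nonstationarity, 1/f scaling, measurement
quantization, ectopic-beat artifacts, or any physiological waveform
morphology. Passing tests demonstrate correctness of the computations,
not that any metric discriminates clinical conditions.

## Problem sizes

Analytic-limit checks use N = 10,000 (where the iid closed forms are
tight) averaged over 10 fixed seeds; oracle-equivalence checks use 200
randomized instances of N ≤ 120 against pure-Python loop
implementations at 1e−12; bound invariants use 1,000 draws of N ≤ 80.

## Known limitations

- Exact numeric parity with other entropy toolboxes is not promised:
  the template-count convention (above), the DistEn bin-edge convention
  ([min, max] of observed distances), and CE's lack of a correction term
  for singleton motifs are all documented choices on points where
  conventions in the literature differ.
- No multivariate or multiscale variants, no automatic selection of m/τ,
  no resampling/detrending/artifact detection — gaps are the only data-
  quality mechanism.
- Input is restricted to single-column ASCII recordings (plus gap/list
  companions); no EDF/WFDB/binary readers.
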