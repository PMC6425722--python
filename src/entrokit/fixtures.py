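"""Deterministic synthetic test signals.

Generates the signal families the entropy metrics are sensitive to —
constant, period-2 alternating, sinusoidal, iid Gaussian/uniform noise,
AR(1), and the logistic map — plus gap-file companions, so the whole
pipeline is exercisable without any recorded data.  Stochastic kinds are
driven by numpy's PCG64 generator (``numpy.random.default_rng``), pinned
so a given :class:`FixtureSpec` is bit-identical across runs and
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .errors import InvalidParameterError
from .signal_model import GapSet, TimeSeries, apply_gaps

__all__ = ["FIXTURE_KINDS", "FixtureSpec", "generate", "insert_gaps", "emit"]

FIXTURE_KINDS = (
    "constant",
    "alternating",
    "sine",
    "gaussian_noise",
    "uniform_noise",
    "ar1",
    "logistic_map",
)

_STOCHASTIC = ("gaussian_noise", "uniform_noise", "ar1")

#: AR(1) samples discarded to wash out the initial condition.
AR1_BURN_IN = 1000


@dataclass(frozen=True)
class FixtureSpec:
    """A reproducible recipe for one synthetic signal.

    ``params`` carries kind-specific settings: ``value`` (constant),
    ``a``/``b`` (alternating), ``amplitude``/``frequency``/``phase``
    (sine; frequency in cycles per sample), ``mean``/``sd`` (gaussian),
    ``low``/``high`` (uniform), ``phi``/``sd`` (AR(1)), ``r``/``x0``
    (logistic map).
    """

    kind: str
    n: int
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise InvalidParameterError(f"unknown fixture kind {self.kind!r}; choose from {FIXTURE_KINDS}")
        if int(self.n) < 1:
            raise InvalidParameterError(f"fixture length must be >= 1, got {self.n}")
        if self.kind in _STOCHASTIC and self.seed is None:
            raise InvalidParameterError(f"fixture kind {self.kind!r} requires a seed")
        object.__setattr__(self, "n", int(self.n))


def generate(spec: FixtureSpec) -> TimeSeries:
    """Materialize *spec* into a :class:`TimeSeries` (bit-reproducible)."""
    n, p = spec.n, spec.params
    if spec.kind == "constant":
        return TimeSeries(np.full(n, float(p.get("value", 1.0))))
    if spec.kind == "alternating":
        a, b = float(p.get("a", 1.0)), float(p.get("b", 2.0))
        values = np.empty(n)
        values[0::2] = a
        values[1::2] = b
        return TimeSeries(values)
    if spec.kind == "sine":
        amp = float(p.get("amplitude", 1.0))
        freq = float(p.get("frequency", 0.05))
        phase = float(p.get("phase", 0.0))
        t = np.arange(n)
        return TimeSeries(amp * np.sin(2.0 * np.pi * freq * t + phase))
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "gaussian_noise":
        return TimeSeries(rng.normal(float(p.get("mean", 0.0)), float(p.get("sd", 1.0)), n))
    if spec.kind == "uniform_noise":
        return TimeSeries(rng.uniform(float(p.get("low", 0.0)), float(p.get("high", 1.0)), n))
    if spec.kind == "ar1":
        phi = float(p.get("phi", 0.5))
        if not abs(phi) < 1.0:
            raise InvalidParameterError(f"AR(1) coefficient must satisfy |phi| < 1, got {phi}")
        eps = rng.normal(0.0, float(p.get("sd", 1.0)), n + AR1_BURN_IN)
        x = lfilter([1.0], [1.0, -phi], eps)
        return TimeSeries(x[AR1_BURN_IN:])
    # logistic_map
    r = float(p.get("r", 4.0))
    x0 = float(p.get("x0", 0.3))
    if not (0.0 < x0 < 1.0):
        raise InvalidParameterError(f"logistic map needs x0 in (0, 1), got {x0}")
    values = np.empty(n)
    x = x0
    for i in range(n):
        values[i] = x
        x = r * x * (1.0 - x)
    return TimeSeries(values)


def insert_gaps(series: TimeSeries, gaps: GapSet) -> tuple[TimeSeries, str]:
    """Mask *gaps* into *series* and return the masked series together with
    the exact two-column gap-file text that parses back to the same set."""
    masked = apply_gaps(series, gaps)
    text = "".join(f"{start},{end}\n" for start, end in gaps)
    return masked, text


def emit(spec: FixtureSpec, path, gaps: GapSet | None = None) -> Path:
    """Write the fixture as a single-column ASCII file; with *gaps*, also
    write the companion ``Gap/<stem>.gap`` file.  Returns the signal path."""
    from .io_formats import write_signal_ascii

    path = Path(path)
    series = generate(spec)
    write_signal_ascii(series, path)
    if gaps is not None and len(gaps) > 0:
        _, text = insert_gaps(series, gaps)
        gap_dir = path.parent / "Gap"
        gap_dir.mkdir(parents=True, exist_ok=True)
        (gap_dir / (path.stem + ".gap")).write_text(text, encoding="utf-8")
    return path
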