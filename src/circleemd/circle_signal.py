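"""Circular-sequence primitives.

A spatial channel vector is treated as a ring: index arithmetic is modulo the
length N, so the "first" and "last" channels are neighbours.  All envelope and
extrema machinery in the rest of the package is built on the operations here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "CircularSignal",
    "ExtremaSet",
    "find_circular_extrema",
    "count_zero_crossings",
    "rotate",
    "boundary_discontinuity",
]


@dataclass(frozen=True)
class CircularSignal:
    """A real-valued vector whose index is understood modulo its length."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise InvalidInputError("CircularSignal requires a non-empty 1-D vector")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("CircularSignal values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, i: int) -> float:
        return float(self.values[i % self.n])


@dataclass(frozen=True)
class ExtremaSet:
    """Sorted strict local maxima/minima indices under circular neighbours."""

    maxima: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    minima: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_extrema(self) -> int:
        return self.maxima.size + self.minima.size


def find_circular_extrema(signal: CircularSignal) -> ExtremaSet:
    """Locate strict circular local maxima and minima.

    Plateaus (runs of equal values) are collapsed to a single representative
    index: the middle of the run, taking the left-middle for even run lengths.
    This tie-break is rotation-consistent.  A constant signal has no extrema.
    """
    v = signal.values
    n = v.size
    if n < 3:
        raise InvalidInputError(f"extrema detection needs at least 3 samples, got {n}")

    is_run_start = v != np.roll(v, 1)
    if not is_run_start.any():  # constant on the whole circle
        return ExtremaSet()

    starts = np.flatnonzero(is_run_start)
    run_vals = v[starts]
    nruns = starts.size
    maxima: list[int] = []
    minima: list[int] = []
    for i in range(nruns):
        prev_val = run_vals[(i - 1) % nruns]
        next_val = run_vals[(i + 1) % nruns]
        start = starts[i]
        end = starts[(i + 1) % nruns]
        run_len = (end - start) % n
        if run_len == 0:
            run_len = n
        rep = (start + (run_len - 1) // 2) % n
        if run_vals[i] > prev_val and run_vals[i] > next_val:
            maxima.append(rep)
        elif run_vals[i] < prev_val and run_vals[i] < next_val:
            minima.append(rep)
    return ExtremaSet(
        maxima=np.array(sorted(maxima), dtype=int),
        minima=np.array(sorted(minima), dtype=int),
    )


def count_zero_crossings(signal: CircularSignal) -> int:
    """Count circular sign changes, skipping exactly-zero samples.

    Zero-valued samples are dropped and the nearest nonzero neighbours on each
    side are compared, so a sign change across a zero run counts once.  The
    result is always even: the sign sequence returns to its start on a circle.
    """
    v = signal.values
    if v.size < 2:
        raise InvalidInputError("zero-crossing count needs at least 2 samples")
    nz = v[v != 0.0]
    if nz.size < 2:
        return 0
    signs = np.sign(nz)
    return int(np.count_nonzero(signs != np.roll(signs, 1)))


def rotate(signal: CircularSignal, k: int) -> CircularSignal:
    """Rotate so that output[i] = input[(i + k) mod N]."""
    return CircularSignal(np.roll(signal.values, -k))


def boundary_discontinuity(signal: CircularSignal) -> float:
    """The end-to-end jump |x[0] - x[N-1]|.

    Used to compare end behaviour of the circular decomposition against the
    classic one: components of a ring signal should close up smoothly.
    """
    v = signal.values
    if v.size < 2:
        raise InvalidInputError("boundary discontinuity needs at least 2 samples")
    return float(abs(v[0] - v[-1]))
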