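"""C2-periodic cubic spline interpolation on circular knots.

Envelopes in the circular decomposition are periodic cubic splines: the second
derivatives (moments M_j) at the knots solve a cyclic tridiagonal system

    mu_j M_{j-1} + 2 M_j + lambda_j M_{j+1} = 6 f[t_{j-1}, t_j, t_{j+1}],

with mu_j = h_{j-1}/(h_{j-1}+h_j), lambda_j = h_j/(h_{j-1}+h_j), and f[.,.,.]
the second divided difference, all indices cyclic.  Closing the ring replaces
the usual natural/clamped boundary rows with the wrap-around rows, which is
what removes the end effect: there is no boundary at which the envelope has to
extrapolate.

Knot gaps are general (envelope knots sit at extrema, which are not
equispaced); the wrap gap is period - t_{m-1} + t_0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidKnotsError

__all__ = ["PeriodicSpline", "fit_periodic_spline", "evaluate_spline"]


@dataclass(frozen=True)
class PeriodicSpline:
    """A C2-periodic piecewise cubic defined by knots, values and moments."""

    knot_positions: np.ndarray  # strictly increasing, in [0, period)
    knot_values: np.ndarray
    period: float
    moments: np.ndarray  # second derivatives M_j at the knots

    @property
    def m(self) -> int:
        return self.knot_positions.size

    def __call__(self, query: np.ndarray | float) -> np.ndarray:
        return evaluate_spline(self, query)


def _cyclic_gaps(t: np.ndarray, period: float) -> np.ndarray:
    """h_j = t_{j+1} - t_j for j < m-1; the wrap gap closes the circle."""
    h = np.empty(t.size)
    h[:-1] = np.diff(t)
    h[-1] = period - t[-1] + t[0]
    return h


def fit_periodic_spline(
    knot_positions: np.ndarray,
    knot_values: np.ndarray,
    period: float,
) -> PeriodicSpline:
    """Fit the periodic cubic spline through circularly arranged knots.

    Solves the cyclic moment system directly (the systems here have at most a
    few dozen knots, so a dense solve is both simple and accurate).  One knot
    gives the constant spline; two knots remain well-posed because the cyclic
    system reduces to a nonsingular 2x2.
    """
    t = np.asarray(knot_positions, dtype=float)
    y = np.asarray(knot_values, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InvalidInputError("at least one knot is required")
    if t.shape != y.shape:
        raise InvalidInputError("knot positions and values must have equal length")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise InvalidInputError("knots must be finite")
    if not (period > 0 and np.isfinite(period)):
        raise InvalidInputError("period must be positive and finite")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise InvalidKnotsError("knot positions must be strictly increasing")
    if t[0] < 0 or t[-1] >= period:
        raise InvalidKnotsError("knot positions must lie in [0, period)")

    m = t.size
    if m == 1:
        return PeriodicSpline(t, y, float(period), np.zeros(1))

    h = _cyclic_gaps(t, period)
    yc = y  # cyclic value lookup via modular indexing
    A = np.zeros((m, m))
    rhs = np.empty(m)
    for j in range(m):
        hm = h[(j - 1) % m]  # gap entering knot j
        hp = h[j]            # gap leaving knot j
        mu = hm / (hm + hp)
        lam = hp / (hm + hp)
        A[j, j] += 2.0
        A[j, (j - 1) % m] += mu
        A[j, (j + 1) % m] += lam
        d2 = ((yc[(j + 1) % m] - yc[j]) / hp - (yc[j] - yc[(j - 1) % m]) / hm) / (hm + hp)
        rhs[j] = 6.0 * d2
    moments = np.linalg.solve(A, rhs)
    return PeriodicSpline(t, y, float(period), moments)


def evaluate_spline(spline: PeriodicSpline, query: np.ndarray | float) -> np.ndarray:
    """Evaluate the periodic piecewise cubic; queries are reduced mod period."""
    q = np.atleast_1d(np.asarray(query, dtype=float))
    t, y, M, p = spline.knot_positions, spline.knot_values, spline.moments, spline.period
    m = t.size
    if m == 1:
        out = np.full(q.shape, y[0])
        return out if np.ndim(query) else float(out[0])

    # map each query into [t0, t0 + period)
    x = (q - t[0]) % p + t[0]
    seg = np.clip(np.searchsorted(t, x, side="right") - 1, 0, m - 1)
    h = _cyclic_gaps(t, p)
    xl = t[seg]
    hs = h[seg]
    yl = y[seg]
    yr = y[(seg + 1) % m]
    Ml = M[seg]
    Mr = M[(seg + 1) % m]
    a = (xl + hs - x) / hs  # distance to right knot, normalised
    b = (x - xl) / hs
    out = (
        Ml * (a**3) * hs**2 / 6.0
        + Mr * (b**3) * hs**2 / 6.0
        + (yl - Ml * hs**2 / 6.0) * a
        + (yr - Mr * hs**2 / 6.0) * b
    )
    return out if np.ndim(query) else float(out[0])
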