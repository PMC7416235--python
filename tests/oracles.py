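"""Independent brute-force oracles used only by the tests.

The periodic-spline oracle builds the full piecewise-cubic coefficient system
(4 unknowns per segment; interpolation, C1 and C2 continuity at every knot
including the wrap joint) and solves it densely.  It shares no code with the
moment-based implementation under test.
"""

from __future__ import annotations

import numpy as np


def periodic_spline_bruteforce(
    t: np.ndarray, y: np.ndarray, period: float, queries: np.ndarray
) -> np.ndarray:
    """Evaluate the C2-periodic cubic interpolant by solving for all
    segment coefficients a_j + b_j u + c_j u^2 + d_j u^3, u = x - t_j."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    m = t.size
    if m == 1:
        return np.full(np.asarray(queries).shape, y[0])
    h = np.empty(m)
    h[:-1] = np.diff(t)
    h[-1] = period - t[-1] + t[0]

    a_mat = np.zeros((4 * m, 4 * m))
    rhs = np.zeros(4 * m)
    row = 0
    for j in range(m):
        jn = (j + 1) % m
        base = 4 * j
        nbase = 4 * jn
        # interpolation at both ends of segment j
        a_mat[row, base] = 1.0
        rhs[row] = y[j]
        row += 1
        a_mat[row, base : base + 4] = [1.0, h[j], h[j] ** 2, h[j] ** 3]
        rhs[row] = y[jn]
        row += 1
        # C1 continuity into the next segment
        a_mat[row, base + 1 : base + 4] = [1.0, 2 * h[j], 3 * h[j] ** 2]
        a_mat[row, nbase + 1] -= 1.0
        row += 1
        # C2 continuity into the next segment
        a_mat[row, base + 2 : base + 4] = [2.0, 6 * h[j]]
        a_mat[row, nbase + 2] -= 2.0
        row += 1
    coef = np.linalg.solve(a_mat, rhs).reshape(m, 4)

    q = np.atleast_1d(np.asarray(queries, dtype=float))
    x = (q - t[0]) % period + t[0]
    seg = np.clip(np.searchsorted(t, x, side="right") - 1, 0, m - 1)
    u = x - t[seg]
    c = coef[seg]
    return c[:, 0] + c[:, 1] * u + c[:, 2] * u**2 + c[:, 3] * u**3


def linear_detrend_oracle(series: np.ndarray) -> np.ndarray:
    """Least-squares line removal via polyfit, keeping the mean."""
    x = np.arange(series.size, dtype=float)
    slope, intercept = np.polyfit(x, series, 1)
    return series - (slope * x + intercept) + series.mean()
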