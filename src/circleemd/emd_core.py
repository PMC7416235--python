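"""Sifting loop and decomposition drivers.

Two variants are provided:

* :func:`circle_emd` — the circular decomposition: envelopes are periodic
  cubic splines through the extrema of the ring signal, so no boundary
  extrapolation ever happens and the components close up smoothly end-to-end.
* :func:`classic_emd` — the conventional baseline: natural cubic splines
  through the extrema with no data extension, which deliberately exhibits the
  end effect the circular construction removes.

Both drivers preserve the decomposition identity
``input = sum(IMFs) + residual`` exactly up to floating-point cancellation,
because each component is obtained by subtraction from the running residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .circle_signal import (
    CircularSignal,
    count_zero_crossings,
    find_circular_extrema,
)
from .errors import InvalidInputError, InvalidSelectionError, TooFewExtremaError
from .periodic_spline import evaluate_spline, fit_periodic_spline

__all__ = [
    "SiftConfig",
    "IMFSet",
    "envelope_mean_circular",
    "is_valid_imf",
    "sift",
    "circle_emd",
    "classic_emd",
    "combine_imfs",
]


@dataclass(frozen=True)
class SiftConfig:
    """Stopping thresholds for sifting and decomposition.

    mean_env_tol
        An IMF candidate's mean envelope must stay below this fraction of the
        candidate's peak amplitude (zero-mean-envelope condition, relaxed).
    sd_tol
        Cauchy criterion: sifting stops once
        sum((h_prev - h_new)^2) / sum(h_prev^2) falls below this value.
    max_sift_iters
        Hard cap on envelope subtractions per component.
    max_imfs
        Hard cap on extracted components.
    residual_amp_tol
        Decomposition stops when the residual's peak-to-peak amplitude drops
        below this fraction of the input's peak-to-peak amplitude.
    """

    mean_env_tol: float = 0.05
    sd_tol: float = 0.2
    max_sift_iters: int = 100
    max_imfs: int = 10
    residual_amp_tol: float = 1e-12

    def __post_init__(self) -> None:
        if min(self.mean_env_tol, self.sd_tol, self.residual_amp_tol) < 0:
            raise InvalidInputError("tolerances must be nonnegative")
        if self.max_sift_iters < 1 or self.max_imfs < 1:
            raise InvalidInputError("iteration caps must be >= 1")


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus the residual.

    ``sum(imfs) + residual`` reproduces the decomposed input; ``sift_counts``
    records the number of envelope subtractions spent on each component (0 if
    the running residual already satisfied the IMF conditions).
    """

    imfs: list[np.ndarray] = field(default_factory=list)
    residual: np.ndarray = field(default_factory=lambda: np.array([]))
    sift_counts: list[int] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for c in self.imfs:
            out += c
        return out


def _ptp(v: np.ndarray) -> float:
    return float(np.max(v) - np.min(v)) if v.size else 0.0


def envelope_mean_circular(signal: CircularSignal) -> np.ndarray:
    """Mean of the periodic upper and lower envelopes, sampled at 0..N-1.

    The upper envelope interpolates the maxima, the lower the minima, each as
    a periodic cubic spline with period N.
    """
    ext = find_circular_extrema(signal)
    if ext.maxima.size < 2 or ext.minima.size < 2:
        raise TooFewExtremaError(
            f"need >= 2 maxima and >= 2 minima, got {ext.maxima.size}/{ext.minima.size}"
        )
    n = signal.n
    grid = np.arange(n, dtype=float)
    v = signal.values
    upper = evaluate_spline(
        fit_periodic_spline(ext.maxima.astype(float), v[ext.maxima], float(n)), grid
    )
    lower = evaluate_spline(
        fit_periodic_spline(ext.minima.astype(float), v[ext.minima], float(n)), grid
    )
    return (upper + lower) / 2.0


def is_valid_imf(candidate: CircularSignal, config: SiftConfig) -> tuple[bool, dict]:
    """Check the two IMF conditions on the ring.

    (1) circular extrema count and circular zero-crossing count differ by at
    most one; (2) the mean envelope is small: max|m(t)| <= mean_env_tol *
    max|candidate|.  Signals on which an envelope cannot be built are reported
    invalid with a diagnostic rather than raising.
    """
    ext = find_circular_extrema(candidate)
    nzc = count_zero_crossings(candidate)
    diagnostics: dict = {
        "n_extrema": int(ext.n_extrema),
        "n_zero_crossings": int(nzc),
        "count_condition": bool(abs(ext.n_extrema - nzc) <= 1),
        "envelope_condition": False,
        "max_mean_envelope": np.nan,
    }
    if not diagnostics["count_condition"]:
        return False, diagnostics
    try:
        m = envelope_mean_circular(candidate)
    except TooFewExtremaError as exc:
        diagnostics["error"] = str(exc)
        return False, diagnostics
    scale = float(np.max(np.abs(candidate.values)))
    diagnostics["max_mean_envelope"] = float(np.max(np.abs(m)))
    diagnostics["envelope_condition"] = bool(
        diagnostics["max_mean_envelope"] <= config.mean_env_tol * scale
    )
    return diagnostics["envelope_condition"], diagnostics


def _sift_generic(x, envelope_fn, valid_fn, config):
    """Shared inner loop for both decomposition variants."""
    h = np.array(x, dtype=float, copy=True)
    iters = 0
    while True:
        if valid_fn(h):
            break
        try:
            m = envelope_fn(h)
        except TooFewExtremaError:
            break
        h_new = h - m
        iters += 1
        denom = float(np.sum(h * h))
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < config.sd_tol or iters >= config.max_sift_iters:
            break
    return h, iters


def sift(signal: CircularSignal, config: SiftConfig = SiftConfig()) -> tuple[np.ndarray, int]:
    """Extract one IMF candidate from a circular signal.

    Subtracts the circular mean envelope until the IMF conditions hold, the
    Cauchy criterion triggers, or the iteration cap is reached.  Returns the
    final iterate and the number of subtractions (0 if already valid).
    """
    ext = find_circular_extrema(signal)
    if ext.maxima.size < 2 or ext.minima.size < 2:
        raise TooFewExtremaError("signal has too few extrema to sift")
    return _sift_generic(
        signal.values,
        lambda h: envelope_mean_circular(CircularSignal(h)),
        lambda h: is_valid_imf(CircularSignal(h), config)[0],
        config,
    )


def circle_emd(signal: CircularSignal, config: SiftConfig = SiftConfig()) -> IMFSet:
    """Full circular decomposition of a ring signal into IMFs + residual.

    A non-constant ring signal cannot be monotonic, so the classic
    "monotonic or constant" terminal state becomes: the residual has fewer
    than two maxima or minima, or its amplitude is negligible relative to the
    input.
    """
    if signal.n < 4:
        raise InvalidInputError("circular decomposition needs N >= 4")
    x = signal.values
    residual = x.copy()
    input_ptp = _ptp(x)
    out = IMFSet(residual=residual)
    while out.n_imfs < config.max_imfs:
        if input_ptp == 0.0 or _ptp(residual) <= config.residual_amp_tol * input_ptp:
            break
        ext = find_circular_extrema(CircularSignal(residual))
        if ext.maxima.size < 2 or ext.minima.size < 2:
            break
        imf, iters = sift(CircularSignal(residual), config)
        residual = residual - imf
        out.imfs.append(imf)
        out.sift_counts.append(iters)
        out.residual = residual
    out.residual = residual
    return out


# --- classic (non-periodic) baseline -------------------------------------


def _linear_extrema(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior strict extrema of a non-circular sequence, plateau-resolved."""
    n = v.size
    is_run_start = np.empty(n, dtype=bool)
    is_run_start[0] = True
    is_run_start[1:] = v[1:] != v[:-1]
    starts = np.flatnonzero(is_run_start)
    run_vals = v[starts]
    nruns = starts.size
    maxima: list[int] = []
    minima: list[int] = []
    for i in range(1, nruns - 1):  # endpoints are never extrema
        start = starts[i]
        end = starts[i + 1] if i + 1 < nruns else n
        rep = start + (end - start - 1) // 2
        if run_vals[i] > run_vals[i - 1] and run_vals[i] > run_vals[i + 1]:
            maxima.append(rep)
        elif run_vals[i] < run_vals[i - 1] and run_vals[i] < run_vals[i + 1]:
            minima.append(rep)
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def _envelope_mean_classic(v: np.ndarray) -> np.ndarray:
    """Mean of natural-spline envelopes with no end extension.

    Beyond the outermost extrema the natural cubic is extrapolated; this is
    precisely the boundary pathology the circular construction avoids, and the
    baseline keeps it on purpose.
    """
    maxima, minima = _linear_extrema(v)
    if maxima.size < 2 or minima.size < 2:
        raise TooFewExtremaError(
            f"need >= 2 interior maxima and minima, got {maxima.size}/{minima.size}"
        )
    grid = np.arange(v.size, dtype=float)
    upper = CubicSpline(maxima, v[maxima], bc_type="natural")(grid)
    lower = CubicSpline(minima, v[minima], bc_type="natural")(grid)
    return (upper + lower) / 2.0


def _count_zero_crossings_linear(v: np.ndarray) -> int:
    nz = v[v != 0.0]
    if nz.size < 2:
        return 0
    signs = np.sign(nz)
    return int(np.count_nonzero(signs[1:] != signs[:-1]))


def _is_valid_imf_classic(v: np.ndarray, config: SiftConfig) -> bool:
    maxima, minima = _linear_extrema(v)
    n_ext = maxima.size + minima.size
    if abs(n_ext - _count_zero_crossings_linear(v)) > 1:
        return False
    try:
        m = _envelope_mean_classic(v)
    except TooFewExtremaError:
        return False
    scale = float(np.max(np.abs(v)))
    return bool(np.max(np.abs(m)) <= config.mean_env_tol * scale)


def classic_emd(signal: np.ndarray | CircularSignal, config: SiftConfig = SiftConfig()) -> IMFSet:
    """Conventional EMD with natural-spline envelopes (end-effect baseline)."""
    v = signal.values if isinstance(signal, CircularSignal) else np.asarray(signal, dtype=float)
    if v.ndim != 1 or v.size < 4:
        raise InvalidInputError("classic decomposition needs a 1-D signal of length >= 4")
    residual = v.copy()
    input_ptp = _ptp(v)
    out = IMFSet(residual=residual)
    while out.n_imfs < config.max_imfs:
        if input_ptp == 0.0 or _ptp(residual) <= config.residual_amp_tol * input_ptp:
            break
        d = np.diff(residual)
        if np.all(d >= 0) or np.all(d <= 0):  # monotonic or constant
            break
        maxima, minima = _linear_extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        imf, iters = _sift_generic(
            residual,
            _envelope_mean_classic,
            lambda h: _is_valid_imf_classic(h, config),
            config,
        )
        residual = residual - imf
        out.imfs.append(imf)
        out.sift_counts.append(iters)
    out.residual = residual
    return out


def combine_imfs(imf_set: IMFSet, which: list[int] | str) -> np.ndarray:
    """Sum selected IMFs (1-based indices); "all" sums every IMF, no residual."""
    n = imf_set.n_imfs
    if isinstance(which, str):
        if which != "all":
            raise InvalidSelectionError(f"unknown selection {which!r}; use indices or 'all'")
        indices = list(range(1, n + 1))
    else:
        indices = list(which)
        bad = [i for i in indices if not (1 <= i <= n)]
        if bad:
            raise InvalidSelectionError(f"IMF indices out of range 1..{n}: {bad}")
    if n == 0:
        raise InvalidSelectionError("decomposition has no IMFs to combine")
    out = np.zeros_like(imf_set.imfs[0])
    for i in indices:
        out += imf_set.imfs[i - 1]
    return out
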