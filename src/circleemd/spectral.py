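"""FFT characterisation of IMFs.

Each component of a decomposition occupies a distinct spatial-frequency band;
these helpers summarise a component by its half-spectrum magnitudes, its
dominant normalised frequency (radians per channel, in [0, pi]) and its total
energy, and report whether dominant frequencies decrease across the IMF order
(components are extracted from fast to slow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emd_core import IMFSet
from .errors import InvalidInputError

__all__ = ["SpectrumSummary", "SeparationReport", "imf_spectrum", "spectral_separation_report"]

# relative magnitude below which a bin is considered numerically empty
_EMPTY_BIN_RTOL = 1e-12


@dataclass(frozen=True)
class SpectrumSummary:
    frequencies: np.ndarray  # 2*pi*k/N, nonnegative half spectrum
    magnitudes: np.ndarray
    dominant_frequency: float
    total_energy: float  # = sum of squared signal values (Parseval)


@dataclass(frozen=True)
class SeparationReport:
    dominant_frequencies: list[float]
    band_energies: list[float]
    monotonic: bool  # dominant frequencies non-increasing in IMF order


def imf_spectrum(imf: np.ndarray) -> SpectrumSummary:
    """Half-spectrum magnitudes and dominant normalised spatial frequency.

    The zero bin is excluded from the dominant-frequency search whenever any
    oscillatory bin carries non-negligible magnitude, so a constant offset is
    never reported as the dominant oscillation.
    """
    v = np.asarray(imf, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise InvalidInputError("spectrum needs a 1-D signal of length >= 2")
    n = v.size
    spec = np.fft.rfft(v)
    mags = np.abs(spec)
    freqs = 2.0 * np.pi * np.arange(mags.size) / n

    # Parseval: energy from the half spectrum (double shared bins)
    weights = np.full(mags.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    total_energy = float(np.sum(weights * mags**2) / n)

    if mags.size > 1 and np.max(mags[1:]) > _EMPTY_BIN_RTOL * (np.max(mags) + 1e-300):
        k = 1 + int(np.argmax(mags[1:]))
    else:
        k = 0
    return SpectrumSummary(freqs, mags, float(freqs[k]), total_energy)


def spectral_separation_report(imf_set: IMFSet) -> SeparationReport:
    """Dominant frequency and energy of each IMF, in extraction order."""
    if imf_set.n_imfs < 1:
        raise InvalidInputError("need at least one IMF")
    doms: list[float] = []
    energies: list[float] = []
    for c in imf_set.imfs:
        s = imf_spectrum(c)
        doms.append(s.dominant_frequency)
        energies.append(s.total_energy)
    monotonic = all(doms[i + 1] <= doms[i] + 1e-12 for i in range(len(doms) - 1))
    return SeparationReport(doms, energies, monotonic)
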