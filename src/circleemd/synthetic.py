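"""Synthetic fixtures: circular multi-tone signals and an emulated study.

The emulated study mimics a rock/scissors/paper motor decoding session: 10
runs of 32 states (8 rest + 24 task, balanced over three classes), a channel
pool in which only a subset responds to the task, class-specific spatial
activation patterns with distinct spatial-frequency content, smooth per-run
drift, and additive Gaussian noise.  Everything is a pure function of the
spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circle_signal import CircularSignal
from .errors import InvalidInputError
from .preprocess import RawStudy

__all__ = ["ToneSpec", "EmulatedStudySpec", "make_circular_tones", "make_emulated_study", "ROI_NAMES"]

ROI_NAMES = ("M1_RHand", "SMA_RHand", "CB_RHand", "M1_LHand", "SMA_LHand", "CB_LHand")


@dataclass(frozen=True)
class ToneSpec:
    """Sum of exact circular harmonics plus offset and seeded noise.

    Cycle counts must be integers so every component is exactly periodic on
    the circle (no built-in boundary jump).
    """

    n: int
    components: tuple[tuple[int, float, float], ...]  # (cycles, amplitude, phase)
    offset: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise InvalidInputError("at least one tone component is required")
        for cycles, _, _ in self.components:
            if int(cycles) != cycles or cycles <= 0:
                raise InvalidInputError(f"cycle counts must be positive integers, got {cycles}")
        if self.n < 4 * max(c for c, _, _ in self.components):
            raise InvalidInputError("N must be >= 4 x the fastest component's cycle count")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be nonnegative")


def make_circular_tones(spec: ToneSpec) -> tuple[CircularSignal, list[np.ndarray]]:
    """Generate the tone signal; returns it with each clean component.

    The returned component list is ordered as in the spec (ground truth for
    recovery scoring); the signal is their sum plus offset plus noise.
    """
    i = np.arange(spec.n)
    comps = [
        amp * np.cos(2.0 * np.pi * cycles * i / spec.n + phase)
        for cycles, amp, phase in spec.components
    ]
    total = np.sum(comps, axis=0) + spec.offset
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        total = total + rng.normal(0.0, spec.noise_sd, size=spec.n)
    return CircularSignal(total), comps


@dataclass(frozen=True)
class EmulatedStudySpec:
    """Design of the emulated decoding study.

    Per run, the condition sequence interleaves one rest state before every
    three task states (8 blocks of 1+3 = 32 states), plus one trailing rest
    volume so the hemodynamic shift has a volume to discard.  Task volumes of
    class c add ``activation_offset`` plus a class-specific circular harmonic
    (``pattern_amplitude`` x cos with ``class_pattern_frequencies[c]`` cycles)
    across the first ``n_channels_signal`` channels, delayed by
    ``hemodynamic_delay_trs`` volumes.  Amplitudes are in raw scanner-like
    units on top of ``baseline_level``.
    """

    n_runs: int = 10
    states_per_run: int = 32
    rest_states_per_run: int = 8
    n_classes: int = 3
    n_channels_raw: int = 300
    n_channels_signal: int = 250
    class_pattern_frequencies: tuple[int, ...] = (3, 8, 19)
    pattern_amplitude: float = 1.0
    activation_offset: float = 2.0
    drift_amplitude: float = 1.0
    noise_sd: float = 0.5
    baseline_level: float = 100.0
    hemodynamic_delay_trs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        task = self.states_per_run - self.rest_states_per_run
        if task <= 0 or task % self.n_classes != 0:
            raise InvalidInputError(
                "task states per run must be positive and divisible by the class count"
            )
        if self.rest_states_per_run <= 0 or self.states_per_run % self.rest_states_per_run != 0:
            raise InvalidInputError("rest states must evenly divide the run into blocks")
        if len(self.class_pattern_frequencies) != self.n_classes:
            raise InvalidInputError("one spatial frequency per class is required")
        if not 0 < self.n_channels_signal <= self.n_channels_raw:
            raise InvalidInputError("signal channels must be a nonempty subset of raw channels")

    @property
    def task_states_per_run(self) -> int:
        return self.states_per_run - self.rest_states_per_run


def _condition_sequence(spec: EmulatedStudySpec, run: int) -> np.ndarray:
    """Rest-interleaved condition codes for one run, plus a trailing rest.

    Blocks of (1 rest + n_classes task states); the class order rotates with
    the block and run index so every class appears equally often at every
    within-block position across the session.
    """
    n_blocks = spec.rest_states_per_run
    per_block = spec.states_per_run // n_blocks - 1  # task states per block
    seq: list[int] = []
    for b in range(n_blocks):
        seq.append(1)
        for j in range(per_block):
            cls = (b + run + j) % spec.n_classes
            seq.append(2 + cls)
    seq.extend([1] * spec.hemodynamic_delay_trs)  # trailing rest, dropped by the shift
    return np.array(seq, dtype=int)


def _class_patterns(spec: EmulatedStudySpec) -> np.ndarray:
    """(n_classes x n_channels_raw) activation added during task volumes."""
    pats = np.zeros((spec.n_classes, spec.n_channels_raw))
    i = np.arange(spec.n_channels_signal)
    for c, cycles in enumerate(spec.class_pattern_frequencies):
        phase = 2.0 * np.pi * c / spec.n_classes
        pats[c, : spec.n_channels_signal] = spec.activation_offset + spec.pattern_amplitude * np.cos(
            2.0 * np.pi * cycles * i / spec.n_channels_signal + phase
        )
    return pats


def make_emulated_study(spec: EmulatedStudySpec) -> tuple[RawStudy, np.ndarray]:
    """Build the raw study; also returns the (n_classes x channels) patterns."""
    rng = np.random.default_rng(spec.seed)
    pats = _class_patterns(spec)
    n_chan = spec.n_channels_raw
    roi = np.array(
        [ROI_NAMES[min(i * len(ROI_NAMES) // n_chan, len(ROI_NAMES) - 1)] for i in range(n_chan)]
    )
    runs, conds = [], []
    for r in range(spec.n_runs):
        c = _condition_sequence(spec, r)
        t_len = c.size
        mat = np.full((t_len, n_chan), spec.baseline_level, dtype=float)
        # smooth per-run drift: random slope + slow half-sine, per channel
        slope = rng.uniform(-1.0, 1.0, size=n_chan)
        amp = rng.uniform(-1.0, 1.0, size=n_chan)
        tt = np.arange(t_len) / max(t_len - 1, 1)
        mat += spec.drift_amplitude * (np.outer(tt - 0.5, slope) + np.outer(np.sin(np.pi * tt), amp))
        # delayed task response
        for t in range(t_len):
            src = t - spec.hemodynamic_delay_trs
            if src >= 0 and c[src] >= 2:
                mat[t, :] += pats[c[src] - 2, :]
        mat += rng.normal(0.0, spec.noise_sd, size=mat.shape)
        runs.append(mat)
        conds.append(c)
    return RawStudy(runs=runs, channel_roi=roi, conditions=conds, tr=5.0), pats
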