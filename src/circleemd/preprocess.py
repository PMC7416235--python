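"""Preprocessing of raw multi-run channel series into a sample matrix.

The stages mirror a standard fMRI decoding preparation flow: shift signals
against condition labels to compensate the hemodynamic delay, restrict to the
regions of interest, keep the task-responsive channels by a two-sample t
statistic, clip outliers, detrend each run, convert to percent signal change
against the run baseline, z-score each volume across channels, and finally
keep only the task-condition volumes as labelled samples.

Condition-code convention: 1 = rest/baseline block, 2..4 = the three task
classes (rock / scissors / paper).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "CLASS_NAMES",
    "RawStudy",
    "StudyDataset",
    "PreprocConfig",
    "shift_data",
    "select_roi_channels",
    "select_channels_by_tvalue",
    "reduce_outliers",
    "detrend_runs",
    "normalize_by_baseline",
    "znorm_spatial",
    "select_task_conditions",
    "run_preprocessing",
]

CLASS_NAMES = ("rock", "scissors", "paper")


@dataclass
class RawStudy:
    """Raw multi-run recordings: one (volumes x channels) matrix per run."""

    runs: list[np.ndarray]
    channel_roi: np.ndarray  # ROI label per channel
    conditions: list[np.ndarray]  # condition code per volume, per run
    tr: float = 5.0

    def __post_init__(self) -> None:
        if not self.runs:
            raise InvalidInputError("a study needs at least one run")
        n_chan = self.runs[0].shape[1]
        if any(r.ndim != 2 or r.shape[1] != n_chan for r in self.runs):
            raise InvalidInputError("all runs must share the same channel count")
        if len(self.conditions) != len(self.runs):
            raise InvalidInputError("one condition vector per run is required")
        for r, c in zip(self.runs, self.conditions):
            if len(c) != r.shape[0]:
                raise InvalidInputError("condition codes must cover every volume")
        if len(self.channel_roi) != n_chan:
            raise InvalidInputError("one ROI label per channel is required")

    @property
    def n_channels(self) -> int:
        return self.runs[0].shape[1]

    @property
    def n_runs(self) -> int:
        return len(self.runs)


@dataclass
class StudyDataset:
    """Labelled samples-by-channels matrix produced by preprocessing."""

    samples: np.ndarray  # (n_samples, n_channels)
    labels: np.ndarray  # class index 0..n_classes-1
    run_id: np.ndarray
    condition: np.ndarray  # original condition code per sample

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class PreprocConfig:
    """Stage parameters for the full preprocessing flow.

    ``base_conds`` is the condition set defining the percent-signal-change
    baseline (all conditions by default, i.e. the run mean), while
    ``rest_conds`` is the rest block used as the contrast group of the
    channel-selection t statistic.
    """

    shift_trs: int = 1
    n_channels_keep: int = 200
    tval_min: float = 3.2
    outlier_std_thres: float = 4.0
    outlier_iters: int = 2
    base_conds: frozenset[int] = frozenset({1, 2, 3, 4})
    task_conds: frozenset[int] = frozenset({2, 3, 4})
    rest_conds: frozenset[int] = frozenset({1})

    def __post_init__(self) -> None:
        if self.n_channels_keep < 1 or self.outlier_iters < 1:
            raise InvalidConfigError("counts must be positive")
        if self.outlier_std_thres <= 0:
            raise InvalidConfigError("outlier threshold must be positive")


def shift_data(study: RawStudy, shift_trs: int) -> RawStudy:
    """Advance each run's signal by ``shift_trs`` volumes relative to labels.

    Compensates the hemodynamic delay: the BOLD response to the condition
    presented at volume t is read from volume t + shift.  Trailing volumes
    with no label to pair with are dropped, so each run shortens by the shift.
    """
    if shift_trs < 0:
        raise InvalidConfigError("shift must be nonnegative")
    if shift_trs == 0:
        return study
    shortest = min(r.shape[0] for r in study.runs)
    if shift_trs >= shortest:
        raise InvalidConfigError(f"shift {shift_trs} >= shortest run length {shortest}")
    runs = [r[shift_trs:, :].copy() for r in study.runs]
    conds = [np.asarray(c)[: len(c) - shift_trs].copy() for c in study.conditions]
    return replace(study, runs=runs, conditions=conds)


def select_roi_channels(study: RawStudy, rois: list[str]) -> RawStudy:
    """Keep only channels whose ROI label is in ``rois``, order preserved."""
    if not rois:
        raise InvalidConfigError("at least one ROI must be selected")
    available = set(study.channel_roi.tolist())
    unknown = [r for r in rois if r not in available]
    if unknown:
        raise InvalidConfigError(f"unknown ROI names: {unknown}")
    mask = np.isin(study.channel_roi, list(rois))
    runs = [r[:, mask].copy() for r in study.runs]
    return replace(study, runs=runs, channel_roi=study.channel_roi[mask])


def _stack_condition_volumes(study: RawStudy, conds: frozenset[int]) -> np.ndarray:
    blocks = [
        r[np.isin(c, list(conds)), :]
        for r, c in zip(study.runs, study.conditions)
    ]
    return np.vstack(blocks)


def select_channels_by_tvalue(
    study: RawStudy, config: PreprocConfig
) -> tuple[RawStudy, np.ndarray]:
    """Keep the most task-responsive channels.

    Computes a pooled two-sample t statistic (task volumes vs. rest volumes,
    pooled across runs) per channel, drops channels below ``tval_min``, then
    keeps the top ``n_channels_keep`` by statistic (fewer if fewer pass).
    Returns the filtered study and the per-channel statistic.
    """
    task = _stack_condition_volumes(study, config.task_conds)
    rest = _stack_condition_volumes(study, config.rest_conds)
    if rest.shape[0] < 2 or task.shape[0] < 2:
        raise InvalidInputError("need at least 2 task and 2 baseline volumes")
    na, nb = task.shape[0], rest.shape[0]
    va = task.var(axis=0, ddof=1)
    vb = rest.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(denom > 0, (task.mean(axis=0) - rest.mean(axis=0)) / denom, 0.0)
    passing = np.flatnonzero(tvals >= config.tval_min)
    if passing.size == 0:
        warnings.warn("no channel reaches the t-value threshold; keeping none")
        keep = passing
    else:
        order = passing[np.argsort(tvals[passing])[::-1]]
        keep = np.sort(order[: config.n_channels_keep])  # original channel order
    runs = [r[:, keep].copy() for r in study.runs]
    return replace(study, runs=runs, channel_roi=study.channel_roi[keep]), tvals


def reduce_outliers(study: RawStudy, std_thres: float, num_its: int) -> RawStudy:
    """Iteratively clip values beyond mean +/- std_thres*SD, per channel per run."""
    if std_thres <= 0 or num_its < 1:
        raise InvalidConfigError("thresholds must be positive")
    runs = []
    for r in study.runs:
        x = r.copy()
        for _ in range(num_its):
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
            lo, hi = mu - std_thres * sd, mu + std_thres * sd
            x = np.clip(x, lo, hi)
        runs.append(x)
    return replace(study, runs=runs)


def detrend_runs(study: RawStudy) -> RawStudy:
    """Remove the least-squares linear trend per channel per run, keep the mean.

    The run mean is re-added after removing the fitted line so that the
    subsequent baseline normalisation still sees physiological signal levels.
    """
    runs = []
    for r in study.runs:
        t = r.shape[0]
        if t < 3:
            raise InvalidInputError("detrending needs runs of length >= 3")
        x = np.arange(t, dtype=float)
        xc = x - x.mean()
        slope = (xc @ r) / np.sum(xc * xc)
        runs.append(r - np.outer(xc, slope))
    return replace(study, runs=runs)


def normalize_by_baseline(study: RawStudy, base_conds: frozenset[int]) -> RawStudy:
    """Convert to percent signal change against the run baseline mean."""
    runs = []
    for r, c in zip(study.runs, study.conditions):
        mask = np.isin(c, list(base_conds))
        if not mask.any():
            raise InvalidInputError("a run has no baseline-condition volumes")
        b = r[mask, :].mean(axis=0)
        if np.any(np.abs(b) < 1e-12):
            raise InvalidInputError("degenerate baseline: a channel's baseline mean is zero")
        runs.append(100.0 * (r - b) / b)
    return replace(study, runs=runs)


def _znorm_rows(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)  # population SD convention
    if np.any(sd < 1e-300):
        raise InvalidInputError("degenerate sample: zero variance across channels")
    return (mat - mu) / sd


def znorm_spatial(data: RawStudy | StudyDataset) -> RawStudy | StudyDataset:
    """Z-score each volume/sample across channels (mean 0, population SD 1)."""
    if isinstance(data, StudyDataset):
        if data.n_channels < 2:
            raise InvalidInputError("spatial z-norm needs >= 2 channels")
        return replace(data, samples=_znorm_rows(data.samples))
    if data.n_channels < 2:
        raise InvalidInputError("spatial z-norm needs >= 2 channels")
    return replace(data, runs=[_znorm_rows(r) for r in data.runs])


def select_task_conditions(study: RawStudy, task_conds: frozenset[int]) -> StudyDataset:
    """Keep only task-condition volumes as labelled samples.

    Class labels are assigned by the sorted order of the task condition codes
    (2 -> rock, 3 -> scissors, 4 -> paper under the default convention).
    """
    codes = sorted(task_conds)
    code_to_label = {code: i for i, code in enumerate(codes)}
    samples, labels, run_ids, conditions = [], [], [], []
    for run_idx, (r, c) in enumerate(zip(study.runs, study.conditions)):
        mask = np.isin(c, codes)
        samples.append(r[mask, :])
        kept = np.asarray(c)[mask]
        labels.append(np.array([code_to_label[int(k)] for k in kept], dtype=int))
        run_ids.append(np.full(mask.sum(), run_idx, dtype=int))
        conditions.append(kept.astype(int))
    out = StudyDataset(
        samples=np.vstack(samples),
        labels=np.concatenate(labels),
        run_id=np.concatenate(run_ids),
        condition=np.concatenate(conditions),
    )
    if out.n_samples == 0:
        raise InvalidConfigError("no task-condition volumes found")
    return out


def run_preprocessing(
    study: RawStudy,
    config: PreprocConfig = PreprocConfig(),
    rois: list[str] | None = None,
) -> tuple[StudyDataset, np.ndarray]:
    """Run the full flow in order; returns the dataset and per-channel t values.

    Order: shift -> ROI selection -> t-value channel selection -> outlier
    clipping -> detrend -> baseline percent change -> spatial z-norm -> task
    condition selection.
    """
    s = shift_data(study, config.shift_trs)
    if rois is not None:
        s = select_roi_channels(s, rois)
    s, tvals = select_channels_by_tvalue(s, config)
    if s.n_channels == 0:
        raise InvalidInputError("channel selection removed every channel")
    s = reduce_outliers(s, config.outlier_std_thres, config.outlier_iters)
    s = detrend_runs(s)
    s = normalize_by_baseline(s, config.base_conds)
    s = znorm_spatial(s)
    return select_task_conditions(s, config.task_conds), tvals
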