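"""Delimited-text I/O for studies, datasets and matrices.

All files are headered CSV with 0-based indices; floats are written with 17
significant digits so round trips are bit-exact.  A study directory contains
one ``run_XX.csv`` per run (volumes x channels), ``labels.csv`` with columns
(run, volume, condition) and ``channels.csv`` with columns (channel, roi).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .preprocess import RawStudy, StudyDataset

__all__ = [
    "write_study",
    "read_study",
    "write_dataset",
    "read_dataset",
    "write_matrix",
    "read_matrix",
]

_FLOAT_FMT = "%.17g"


def write_study(study: RawStudy, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cols = [f"ch{i:04d}" for i in range(study.n_channels)]
    rows = []
    for r, (mat, conds) in enumerate(zip(study.runs, study.conditions)):
        pd.DataFrame(mat, columns=cols).to_csv(
            d / f"run_{r:02d}.csv", index=False, float_format=_FLOAT_FMT
        )
        for v, c in enumerate(conds):
            rows.append((r, v, int(c)))
    pd.DataFrame(rows, columns=["run", "volume", "condition"]).to_csv(
        d / "labels.csv", index=False
    )
    pd.DataFrame(
        {"channel": np.arange(study.n_channels), "roi": study.channel_roi}
    ).to_csv(d / "channels.csv", index=False)
    return d


def read_study(directory: str | Path, tr: float = 5.0) -> RawStudy:
    d = Path(directory)
    labels = pd.read_csv(d / "labels.csv")
    channels = pd.read_csv(d / "channels.csv")
    run_files = sorted(d.glob("run_*.csv"))
    if not run_files:
        raise InvalidInputError(f"no run_*.csv files found in {d}")
    runs, conds = [], []
    for r, f in enumerate(run_files):
        mat = pd.read_csv(f).to_numpy(dtype=float)
        sub = labels[labels["run"] == r].sort_values("volume")
        if len(sub) != mat.shape[0]:
            raise InvalidInputError(
                f"{f.name}: {mat.shape[0]} volumes but {len(sub)} condition labels"
            )
        runs.append(mat)
        conds.append(sub["condition"].to_numpy(dtype=int))
    return RawStudy(
        runs=runs,
        channel_roi=channels.sort_values("channel")["roi"].to_numpy(dtype=str),
        conditions=conds,
        tr=tr,
    )


def write_dataset(dataset: StudyDataset, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        dataset.samples, columns=[f"ch{i:04d}" for i in range(dataset.n_channels)]
    )
    df.insert(0, "condition", dataset.condition)
    df.insert(0, "run", dataset.run_id)
    df.insert(0, "label", dataset.labels)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_dataset(path: str | Path) -> StudyDataset:
    df = pd.read_csv(path)
    meta = {"label", "run", "condition"}
    missing = meta - set(df.columns)
    if missing:
        raise InvalidInputError(f"dataset file lacks columns: {sorted(missing)}")
    chan_cols = [c for c in df.columns if c not in meta]
    return StudyDataset(
        samples=df[chan_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        run_id=df["run"].to_numpy(dtype=int),
        condition=df["condition"].to_numpy(dtype=int),
    )


def write_matrix(mat: np.ndarray, path: str | Path, prefix: str = "c") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        np.atleast_2d(mat), columns=[f"{prefix}{i:04d}" for i in range(np.atleast_2d(mat).shape[1])]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_matrix(path: str | Path) -> np.ndarray:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InvalidInputError(f"{path}: empty or unparsable matrix file") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise InvalidInputError(f"{path}: matrix file has no data rows")
    try:
        return df.to_numpy(dtype=float)
    except ValueError as exc:
        raise InvalidInputError(f"{path}: non-numeric matrix entries: {exc}") from exc
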