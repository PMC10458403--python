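"""Windowed ISI datasets with FuzzyEn targets.

A dataset is built by scanning the HR slow-current parameter r over an
even grid, generating one long ISI series per r, cutting it into
overlapping fixed-length windows (length NL, shift S), and attaching the
FuzzyEn of each window as the regression target.  The two standard sets
differ only in the external current:

* Base_1 : I_ex = 3.25
* Base_2 : I_ex = 3.35
* Base_1_2 : their row-wise concatenation.

Defaults follow the standard protocol: 100 r values in [5e-3, 1.5e-2],
one 500-interval series per r, 100 windows of length 50 at step 4
(offsets 0, 4, 8, ... -- the first 100 of the 113 that fit).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fuzzyen import DEFAULT_PARAMS, FuzzyEnParams, fuzzy_entropy
from .hr import HRParams, generate_isi_series

__all__ = [
    "WindowedDataset", "DatasetStats", "sliding_windows",
    "build_hr_dataset", "build_base", "dataset_stats",
    "normalize_dataset", "merge_datasets", "write_dataset", "read_dataset",
]


@dataclass(frozen=True)
class WindowedDataset:
    """Fixed-length windows with entropy targets and per-row provenance.

    windows : (n_rows, NL) float matrix.
    targets : (n_rows,) FuzzyEn values.
    r, i_ex : (n_rows,) generating HR parameters per row.
    offset : (n_rows,) start index of the window in its long series.
    normalization : constant already subtracted from every element
        (0.0 for a raw dataset); recorded so a trained sensor can apply
        the same shift at inference.
    """

    windows: np.ndarray
    targets: np.ndarray
    r: np.ndarray
    i_ex: np.ndarray
    offset: np.ndarray
    normalization: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.windows, dtype=float)
        t = np.asarray(self.targets, dtype=float)
        if w.ndim != 2:
            raise ValueError("windows must be a 2-D matrix")
        n = w.shape[0]
        cols = {"targets": t}
        for name in ("r", "i_ex", "offset"):
            cols[name] = np.asarray(getattr(self, name))
        for name, col in cols.items():
            if col.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(t))):
            raise ValueError("windows and targets must be finite")
        object.__setattr__(self, "windows", w)
        object.__setattr__(self, "targets", t)
        for name in ("r", "i_ex"):
            object.__setattr__(self, name, cols[name].astype(float))
        object.__setattr__(self, "offset", cols["offset"].astype(int))

    @property
    def nl(self) -> int:
        return self.windows.shape[1]

    @property
    def n_rows(self) -> int:
        return self.windows.shape[0]

    def __len__(self) -> int:
        return self.n_rows


@dataclass(frozen=True)
class DatasetStats:
    """Summary statistics of a windowed dataset.

    mean : grand mean of all elements (the normalization constant).
    mean50_min / mean50_max : extremes of the per-window means.
    min_x / max_x : extremes over all elements.
    """

    mean: float
    mean50_min: float
    mean50_max: float
    min_x: float
    max_x: float

    def __post_init__(self) -> None:
        if not (self.min_x <= self.mean50_min <= self.mean
                <= self.mean50_max <= self.max_x):
            raise ValueError("statistics violate min <= mean50_min <= mean "
                             "<= mean50_max <= max ordering")


def sliding_windows(
    long_series: Sequence[float], nl: int, s: int, n_windows: int
) -> np.ndarray:
    """First ``n_windows`` windows of length ``nl`` at step ``s``.

    Row k holds elements [k*s, k*s + nl) of the long series (0-based,
    half-open).  Consecutive rows share exactly nl - s elements.
    """
    x = np.asarray(long_series, dtype=float)
    if nl < 1 or s < 1 or n_windows < 1:
        raise ValueError("nl, s and n_windows must be >= 1")
    required = nl + s * (n_windows - 1)
    if x.size < required:
        raise ValueError(
            f"series of length {x.size} too short: "
            f"{n_windows} windows of {nl} at step {s} need {required}"
        )
    return np.lib.stride_tricks.sliding_window_view(x, nl)[::s][:n_windows].copy()


def build_hr_dataset(
    i_ex: float,
    r_min: float = 5e-3,
    r_max: float = 1.5e-2,
    n_r: int = 100,
    nl: int = 50,
    s: int = 4,
    windows_per_r: int = 100,
    long_len: int = 500,
    entropy_params: FuzzyEnParams = DEFAULT_PARAMS,
    **hr_kwargs,
) -> WindowedDataset:
    """Build a windowed HR dataset over an even r grid.

    For each of ``n_r`` evenly spaced r values (endpoints inclusive) one
    ``long_len``-interval ISI series is generated and windowed; every
    window gets a FuzzyEn target.  Deterministic for fixed parameters.
    """
    r_grid = np.linspace(r_min, r_max, n_r)
    blocks, targets, rs, offs = [], [], [], []
    for r in r_grid:
        try:
            series = generate_isi_series(
                HRParams(r=float(r), i_ex=i_ex, **hr_kwargs), long_len
            )
            win = sliding_windows(series.values, nl, s, windows_per_r)
            en = [fuzzy_entropy(w, entropy_params) for w in win]
        except Exception as exc:
            raise RuntimeError(f"dataset build failed at r={r}: {exc}") from exc
        blocks.append(win)
        targets.append(en)
        rs.append(np.full(windows_per_r, r))
        offs.append(np.arange(windows_per_r) * s)
    n = n_r * windows_per_r
    return WindowedDataset(
        windows=np.vstack(blocks),
        targets=np.concatenate(targets),
        r=np.concatenate(rs),
        i_ex=np.full(n, i_ex),
        offset=np.concatenate(offs),
    )


def build_base(which: int, **kwargs) -> WindowedDataset:
    """Convenience builder: base 1 (I_ex=3.25) or base 2 (I_ex=3.35)."""
    currents = {1: 3.25, 2: 3.35}
    if which not in currents:
        raise ValueError("which must be 1 or 2")
    return build_hr_dataset(i_ex=currents[which], **kwargs)


def dataset_stats(ds: WindowedDataset) -> DatasetStats:
    """Grand mean, per-window-mean extremes and element extremes."""
    if ds.n_rows == 0:
        raise ValueError("empty dataset")
    w = ds.windows
    row_means = w.mean(axis=1)
    return DatasetStats(
        mean=float(w.mean()),
        mean50_min=float(row_means.min()),
        mean50_max=float(row_means.max()),
        min_x=float(w.min()),
        max_x=float(w.max()),
    )


def normalize_dataset(ds: WindowedDataset, mean: float | None = None) -> WindowedDataset:
    """Subtract ``mean`` (default: the dataset's own grand mean) from all
    elements.  Targets and provenance are unchanged; the total constant
    subtracted so far is recorded in ``normalization``."""
    if mean is None:
        mean = float(ds.windows.mean())
    if not np.isfinite(mean):
        raise ValueError("mean must be finite")
    return replace(
        ds,
        windows=ds.windows - mean,
        normalization=ds.normalization + mean,
    )


def merge_datasets(a: WindowedDataset, b: WindowedDataset) -> WindowedDataset:
    """Row-wise concatenation (all of a, then all of b)."""
    if a.n_rows == 0:
        return b
    if b.n_rows == 0:
        return a
    if a.nl != b.nl:
        raise ValueError(f"window length mismatch: {a.nl} vs {b.nl}")
    if a.normalization != b.normalization:
        raise ValueError("cannot merge datasets with different normalization")
    return WindowedDataset(
        windows=np.vstack([a.windows, b.windows]),
        targets=np.concatenate([a.targets, b.targets]),
        r=np.concatenate([a.r, b.r]),
        i_ex=np.concatenate([a.i_ex, b.i_ex]),
        offset=np.concatenate([a.offset, b.offset]),
        normalization=a.normalization,
    )


def write_dataset(ds: WindowedDataset, path: str | Path) -> None:
    """CSV with columns r, i_ex, offset, x1..xNL, fuzzyen (full precision)."""
    cols = {"r": ds.r, "i_ex": ds.i_ex, "offset": ds.offset}
    for j in range(ds.nl):
        cols[f"x{j + 1}"] = ds.windows[:, j]
    cols["fuzzyen"] = ds.targets
    # %.17g guarantees exact float64 round-tripping
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> WindowedDataset:
    """Read a dataset written by :func:`write_dataset`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    xcols = [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]
    xcols.sort(key=lambda c: int(c[1:]))
    expected = {"r", "i_ex", "offset", "fuzzyen"}
    missing = expected - set(df.columns)
    if missing or not xcols:
        raise ValueError(f"{path}: missing columns {sorted(missing) or ['x1..xNL']}")
    if [int(c[1:]) for c in xcols] != list(range(1, len(xcols) + 1)):
        raise ValueError(f"{path}: window columns are not contiguous x1..xNL")
    return WindowedDataset(
        windows=df[xcols].to_numpy(dtype=float),
        targets=df["fuzzyen"].to_numpy(dtype=float),
        r=df["r"].to_numpy(dtype=float),
        i_ex=df["i_ex"].to_numpy(dtype=float),
        offset=df["offset"].to_numpy(dtype=int),
    )
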