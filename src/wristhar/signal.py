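"""Accelerometer stream containers, scaling, resampling and windowing.

The classifier consumes fixed-size windows: 12 s of triaxial acceleration
at 32 Hz, i.e. a 3x384 matrix, cut with a 50% stride (6 s).  Windows are
laid out on a grid that restarts at each cleaned label interval's start,
and a window is emitted only when it lies entirely inside one interval
with all 384 expected samples present — a window touching a sensor gap is
dropped rather than imputed.  A gapless interval of T seconds therefore
yields floor((T - 12) / 6) + 1 windows for T >= 12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .timeline import Timeline

RATE_HZ = 32
WINDOW_S = 12.0
STRIDE_S = 6.0
WINDOW_LEN = int(round(WINDOW_S * RATE_HZ))  # 384


@dataclass
class SensorStream:
    """Timestamped triaxial acceleration in g at a nominal sampling rate."""

    subject_id: str
    timestamps: np.ndarray  # (N,) seconds, strictly increasing
    values: np.ndarray  # (N, 3) in g
    nominal_rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError(f"values must be (N, 3), got {self.values.shape}")
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values lengths differ")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class WindowSample:
    subject_id: str
    start_time: float
    matrix: np.ndarray  # (3, 384)
    label: str


@dataclass
class WindowDataset:
    """A stack of labeled 3x384 windows plus a tabular index.

    ``X`` is (N, 3, 384); ``index`` has one row per window with columns
    ``window_id, subject, activity, start_s``.
    """

    X: np.ndarray
    index: pd.DataFrame
    vocabulary: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float32)
        if self.X.ndim != 3 or self.X.shape[1:] != (3, WINDOW_LEN):
            raise ValueError(f"X must be (N, 3, {WINDOW_LEN}), got {self.X.shape}")
        if len(self.index) != len(self.X):
            raise ValueError("index length != number of windows")
        if not self.vocabulary:
            self.vocabulary = tuple(sorted(self.index["activity"].unique()))

    def __len__(self) -> int:
        return len(self.X)

    @property
    def labels(self) -> np.ndarray:
        return self.index["activity"].to_numpy()

    def counts(self) -> pd.DataFrame:
        """Per-subject, per-activity window counts."""
        return self.index.pivot_table(
            index="subject", columns="activity", values="window_id", aggfunc="count", fill_value=0
        )

    def subset(self, window_ids) -> "WindowDataset":
        ids = np.asarray(sorted(window_ids))
        pos = self.index.index[self.index["window_id"].isin(ids)]
        sub = self.index.loc[pos].reset_index(drop=True)
        return WindowDataset(self.X[pos.to_numpy()], sub, self.vocabulary)

    def restrict_vocabulary(self, vocabulary) -> "WindowDataset":
        vocab = tuple(vocabulary)
        keep = self.index["activity"].isin(vocab).to_numpy()
        sub = self.index.loc[keep].reset_index(drop=True)
        return WindowDataset(self.X[keep], sub, vocab)

    @staticmethod
    def concat(datasets: list["WindowDataset"]) -> "WindowDataset":
        if not datasets:
            raise ValueError("nothing to concatenate")
        X = np.concatenate([d.X for d in datasets])
        idx = pd.concat([d.index for d in datasets], ignore_index=True)
        idx["window_id"] = np.arange(len(idx))
        vocab = tuple(sorted({a for d in datasets for a in d.vocabulary}))
        return WindowDataset(X, idx, vocab)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for subject, grp in self.index.groupby("subject"):
            np.save(directory / f"{subject}.npy", self.X[grp.index.to_numpy()])
        idx = self.index.copy()
        idx["file"] = idx["subject"].astype(str) + ".npy"
        idx["offset"] = idx.groupby("subject").cumcount()
        idx.to_csv(directory / "index.csv", index=False)

    @staticmethod
    def load(directory) -> "WindowDataset":
        directory = Path(directory)
        idx = pd.read_csv(directory / "index.csv")
        X = np.empty((len(idx), 3, WINDOW_LEN), dtype=np.float32)
        for fname, grp in idx.groupby("file"):
            arr = np.load(directory / str(fname))
            X[grp.index.to_numpy()] = arr[grp["offset"].to_numpy()]
        return WindowDataset(X, idx.drop(columns=["file", "offset"]))


def rescale(stream: SensorStream, device_range: tuple[float, float]) -> tuple[SensorStream, int]:
    """Affinely map raw device units onto [-2, 2] g, clipping outliers.

    ``device_range = (lo, hi)`` gives the raw values that correspond to
    -2 g and +2 g.  Returns the scaled stream and the number of clipped
    samples.
    """
    lo, hi = device_range
    if hi <= lo:
        raise ValueError(f"device_range must have hi > lo, got {device_range}")
    scaled = -2.0 + 4.0 * (stream.values - lo) / (hi - lo)
    n_clipped = int(np.count_nonzero((scaled < -2.0) | (scaled > 2.0)))
    scaled = np.clip(scaled, -2.0, 2.0)
    out = SensorStream(stream.subject_id, stream.timestamps.copy(), scaled, stream.nominal_rate)
    return out, n_clipped


def downsample(stream: SensorStream, target_rate: float) -> SensorStream:
    """Mean-aggregate a stream into bins of width 1/target_rate.

    The time axis is partitioned into contiguous bins anchored at the first
    timestamp; each output sample is the mean of the input samples in its
    bin, timestamped at the bin start.  Bins with no input samples are
    simply absent, so sensor gaps propagate.
    """
    if target_rate >= stream.nominal_rate:
        raise ValueError(
            f"target rate {target_rate} must be below the source rate {stream.nominal_rate}; "
            "upsampling is not supported"
        )
    if len(stream) == 0:
        return SensorStream(stream.subject_id, stream.timestamps, stream.values, target_rate)
    t0 = stream.timestamps[0]
    # small epsilon guards against a sample landing a float ulp below its bin edge
    bins = np.floor((stream.timestamps - t0) * target_rate + 1e-9).astype(np.int64)
    uniq, start_idx, counts = np.unique(bins, return_index=True, return_counts=True)
    sums = np.add.reduceat(stream.values, start_idx, axis=0)
    means = sums / counts[:, None]
    ts = t0 + uniq / target_rate
    return SensorStream(stream.subject_id, ts, means, target_rate)


def expected_window_count(duration_s: float, window_s: float = WINDOW_S, stride_s: float = STRIDE_S) -> int:
    """Closed-form window count for a gapless interval of the given length."""
    if duration_s < window_s:
        return 0
    return int(np.floor((duration_s - window_s) / stride_s + 1e-9)) + 1


def segment_windows(
    stream: SensorStream,
    timeline: "Timeline",
    window_s: float = WINDOW_S,
    stride_s: float = STRIDE_S,
) -> WindowDataset:
    """Cut a cleaned timeline's intervals into labeled 3x384 windows.

    The window grid restarts at each interval start and advances by
    ``stride_s``; only windows fully inside the interval whose 384 expected
    samples are all present are kept.  Presence is checked with a tolerance
    of a quarter sample period so exact-grid timestamps are robust to float
    jitter.
    """
    if abs(stream.nominal_rate - RATE_HZ) > 1e-6:
        raise ValueError(
            f"stream is at {stream.nominal_rate} Hz; downsample to {RATE_HZ} Hz before windowing"
        )
    n_expected = int(round(window_s * stream.nominal_rate))
    tol = 1.0 / (4.0 * stream.nominal_rate)
    ts = stream.timestamps
    mats, rows = [], []
    for iv in sorted(timeline.intervals, key=lambda iv: iv.start):
        start = iv.start
        while start + window_s <= iv.end + 1e-9:
            lo = int(np.searchsorted(ts, start - tol))
            hi = int(np.searchsorted(ts, start + window_s - tol))
            # a half-open 12-s span holds exactly 384 grid samples at any
            # phase, so count + span suffice to reject windows touching gaps
            ok = (
                hi - lo == n_expected
                and lo < len(ts)
                and abs((ts[hi - 1] - ts[lo]) - (n_expected - 1) / stream.nominal_rate) <= tol
            )
            if ok:
                mats.append(stream.values[lo:hi].T)
                rows.append((stream.subject_id, iv.activity, start))
            start += stride_s
    if mats:
        X = np.stack(mats).astype(np.float32)
    else:
        X = np.empty((0, 3, n_expected), dtype=np.float32)
    index = pd.DataFrame(rows, columns=["subject", "activity", "start_s"])
    index.insert(0, "window_id", np.arange(len(index)))
    return WindowDataset(X, index, timeline.activity_vocabulary)
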