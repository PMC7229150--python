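"""Uniformly sampled multichannel time series: the currency of the pipeline.

Every stage consumes and produces :class:`UniformTimeSeries`.  The canonical
on-disk form is a plain CSV with a ``time`` column in seconds from record
start, one column per channel, and an optional ``# start=<ISO-8601>`` comment
line carrying the wall-clock origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["UniformTimeSeries", "read_sensor_csv", "write_sensor_csv"]

#: relative tolerance for declaring timestamps uniformly spaced
_UNIFORMITY_RTOL = 1e-6

_DEFAULT_START = "1970-01-01T00:00:00"


@dataclass
class UniformTimeSeries:
    """Gap-free, uniformly sampled record of one or more sensor channels.

    Parameters
    ----------
    values : ndarray of shape (n, c)
        One row per sample, one column per channel.
    step : float
        Sampling interval in seconds (> 0).
    channels : sequence of str
        Unique channel names, one per column.
    start_time : str
        ISO-8601 timestamp of the first sample.
    """

    values: np.ndarray
    step: float
    channels: list[str]
    start_time: str = _DEFAULT_START

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n, c) array")
        self.channels = list(self.channels)
        n, c = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if len(self.channels) != c:
            raise ValueError(
                f"{len(self.channels)} channel names for {c} value columns"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"channel names not unique: {self.channels}")
        if not self.step > 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            raise ValueError(f"non-finite value at (row, col) {tuple(bad[0])}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Record span in seconds (first to last sample)."""
        return (self.n - 1) * self.step

    def time(self) -> np.ndarray:
        """Sample times in seconds from record start."""
        return np.arange(self.n) * self.step

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-D array (a view)."""
        try:
            j = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; have {self.channels}"
            ) from None
        return self.values[:, j]

    def select(self, names: Sequence[str]) -> "UniformTimeSeries":
        """Sub-record restricted to ``names`` (in the given order)."""
        cols = [self.channels.index(nm) if nm in self.channels else -1 for nm in names]
        missing = [nm for nm, j in zip(names, cols) if j < 0]
        if missing:
            raise KeyError(f"unknown channels {missing}; have {self.channels}")
        return replace(self, values=self.values[:, cols].copy(), channels=list(names))

    def single(self, name: str) -> "UniformTimeSeries":
        return self.select([name])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channels)
        df.insert(0, "time", self.time())
        return df

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> Path:
        return write_sensor_csv(self, path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "UniformTimeSeries":
        return read_sensor_csv(path)


def write_sensor_csv(ts: UniformTimeSeries, path: str | Path) -> Path:
    """Write the canonical sensor CSV (``# start=`` comment + time column)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# start={ts.start_time}\n")
        ts.to_frame().to_csv(fh, index=False, lineterminator="\n")
    return path


def read_sensor_csv(path: str | Path) -> UniformTimeSeries:
    """Read a sensor CSV, validating uniform spacing; gaps are rejected.

    Unknown extra columns are preserved as additional channels.  A missing
    or duplicated timestamp is an error naming the offending interval —
    imputation is out of scope by design.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    start_time = _DEFAULT_START
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        if "start=" in first:
            start_time = first.split("start=", 1)[1].strip()
    df = pd.read_csv(path, skiprows=skip)
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing required 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 rows, got {len(t)}")
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0:
        raise ValueError(f"{path}: non-increasing timestamps (median step {step})")
    bad = np.where(np.abs(dt - step) > _UNIFORMITY_RTOL * max(step, 1.0))[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"{path}: non-uniform sampling between t={t[i]} and t={t[i + 1]} "
            f"(rows {i + 2 + skip}-{i + 3 + skip}; interval {dt[i]:g} s, "
            f"expected {step:g} s)"
        )
    channels = [c for c in df.columns if c != "time"]
    return UniformTimeSeries(
        values=df[channels].to_numpy(dtype=float),
        step=step,
        channels=channels,
        start_time=start_time,
    )
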