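"""Per-cell fluorescence time series.

A :class:`Trajectory` is one cell's signal on a uniform time grid, in
baseline-0 normalized fluorescence units.  Calcium (GCaMP) records are
typically sampled every 6 s, Crz1 nuclear-localization records every 30 s.
Values may be negative: calcium bursts overshoot below the resting baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CHANNELS = ("calcium", "crz1")


@dataclass
class Trajectory:
    """Uniformly sampled, baseline-0 fluorescence trace for one cell/channel.

    Parameters
    ----------
    cell_id : str
        Cell identifier; shared between the calcium and crz1 channels of
        the same cell.
    channel : str
        Either ``"calcium"`` or ``"crz1"``.
    times : ndarray
        Sample times in seconds, strictly increasing with constant spacing.
    values : ndarray
        Fluorescence values (baseline-0; may be negative).
    """

    cell_id: str
    channel: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly spaced")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        if self.times.size < 2:
            raise ValueError("trajectory too short to define dt")
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size

    def with_values(self, values: np.ndarray) -> "Trajectory":
        """Copy of this trajectory with new values on the same grid."""
        return replace(self, values=np.asarray(values, dtype=float))

    def resample(self, new_times: np.ndarray) -> "Trajectory":
        """Linear interpolation onto a new uniform grid."""
        new_times = np.asarray(new_times, dtype=float)
        vals = np.interp(new_times, self.times, self.values)
        return Trajectory(self.cell_id, self.channel, new_times, vals)


def to_frame(trajs: Iterable[Trajectory]) -> pd.DataFrame:
    """Long-format DataFrame (cell_id, time_sec, channel, value)."""
    parts = []
    for t in trajs:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": t.cell_id,
                    "time_sec": t.times,
                    "channel": t.channel,
                    "value": t.values,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=["cell_id", "time_sec", "channel", "value"])
    return pd.concat(parts, ignore_index=True)


def from_frame(df: pd.DataFrame) -> list[Trajectory]:
    """Parse a long-format trajectory table into Trajectory objects."""
    required = {"cell_id", "time_sec", "channel", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    out: list[Trajectory] = []
    for (cell, channel), grp in df.groupby(["cell_id", "channel"], sort=True):
        grp = grp.sort_values("time_sec")
        out.append(
            Trajectory(
                cell_id=str(cell),
                channel=str(channel),
                times=grp["time_sec"].to_numpy(dtype=float),
                values=grp["value"].to_numpy(dtype=float),
            )
        )
    return out


def write_csv(trajs: Iterable[Trajectory], path) -> None:
    to_frame(trajs).to_csv(path, index=False)


def read_csv(path) -> list[Trajectory]:
    return from_frame(pd.read_csv(path))
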