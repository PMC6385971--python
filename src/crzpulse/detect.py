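"""Burst and pulse detection on baseline-0 trajectories.

Trajectories are Savitzky-Golay smoothed (suppressing fluctuations shorter
than ~4 time points), detection thresholds are derived from negative-control
records (cells with no added calcium): calcium bursts use the top 0.5% of
control peak heights (default 0.09) and Crz1 pulses the top 5% of both peak
height (default 0.30) and topographic prominence (default 0.15).  Local
maxima are kept greedily highest-first subject to a 60 s minimum separation.
Each calcium burst is annotated with the depth of its post-burst overshoot
(the dip below baseline that follows channel-driven bursts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .trajectory import Trajectory

__all__ = [
    "ThresholdSpec",
    "Pulse",
    "Burst",
    "smooth",
    "compute_thresholds",
    "detect",
    "overshoot_regression",
    "pulse_triggered_average",
    "cross_correlation",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Detection thresholds and smoothing settings.

    Height defaults are the published control-derived values; the quantiles
    re-derive them from any control set.
    """

    ca_height: float = 0.09
    crz1_height: float = 0.30
    crz1_prominence: float = 0.15
    min_distance_sec: float = 60.0
    ca_quantile: float = 0.995
    crz1_quantile: float = 0.95
    sg_window: int = 5
    sg_order: int = 2
    overshoot_window_sec: float = 300.0

    def __post_init__(self) -> None:
        if self.ca_height <= 0 or self.crz1_height <= 0 or self.crz1_prominence <= 0:
            raise ValueError("thresholds must be > 0")
        if self.min_distance_sec <= 0:
            raise ValueError("min_distance_sec must be > 0")
        for q in (self.ca_quantile, self.crz1_quantile):
            if not 0.0 < q < 1.0:
                raise ValueError("quantiles must be in (0, 1)")


@dataclass(frozen=True)
class Pulse:
    """A detected Crz1 nuclear-localization pulse (or generic peak)."""

    cell_id: str
    channel: str
    time_sec: float
    height: float       # smoothed value at the maximum
    prominence: float


@dataclass(frozen=True)
class Burst:
    """A detected calcium burst with its overshoot annotation."""

    cell_id: str
    time_sec: float
    height: float
    prominence: float
    overshoot_depth: float          # >= 0; magnitude of the post-burst minimum below 0
    following_interval_sec: float   # to the next burst, or to record end


def smooth(traj: Trajectory, window: int | None = None, order: int | None = None) -> Trajectory:
    """Savitzky-Golay polynomial smoothing of one trajectory."""
    window = 5 if window is None else window
    order = 2 if order is None else order
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and > order")
    if len(traj) < window:
        raise ValueError("record shorter than smoothing window")
    vals = signal.savgol_filter(traj.values, window, order, mode="interp")
    return traj.with_values(vals)


def _find_local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local maxima (plateau midpoint kept)."""
    peaks, _ = signal.find_peaks(values)
    return peaks


def _greedy_select(times: np.ndarray, heights: np.ndarray, min_distance_sec: float) -> np.ndarray:
    """Greedy highest-first peak selection with earlier-peak tie-break.

    Returns indices (into the candidate arrays) of kept peaks, time-ordered.
    Peaks separated by >= min_distance_sec may coexist.
    """
    order = sorted(range(times.size), key=lambda i: (-heights[i], times[i]))
    kept: list[int] = []
    for i in order:
        if all(abs(times[i] - times[j]) >= min_distance_sec for j in kept):
            kept.append(i)
    return np.array(sorted(kept, key=lambda i: times[i]), dtype=int)


def compute_thresholds(
    control_trajs: Sequence[Trajectory], spec: ThresholdSpec | None = None
) -> ThresholdSpec:
    """Derive detection thresholds from negative-control records.

    Every local maximum (min separation 60 s) across all control cells is
    pooled per channel; the calcium height threshold is the
    ``ca_quantile`` (99.5th) percentile of control calcium peak heights,
    and the Crz1 height/prominence thresholds are the ``crz1_quantile``
    (95th) percentiles of control Crz1 peak heights and prominences.
    Percentiles interpolate linearly between order statistics.  With no
    control peaks the published defaults are kept, with a warning.
    """
    spec = spec or ThresholdSpec()
    if len(control_trajs) < 1:
        raise ValueError("need at least one control trajectory")
    ca_heights: list[float] = []
    crz_heights: list[float] = []
    crz_proms: list[float] = []
    for traj in control_trajs:
        sm = smooth(traj, spec.sg_window, spec.sg_order)
        peaks = _find_local_maxima(sm.values)
        if peaks.size == 0:
            continue
        keep = _greedy_select(sm.times[peaks], sm.values[peaks], spec.min_distance_sec)
        idx = peaks[keep]
        heights = sm.values[idx]
        if traj.channel == "calcium":
            ca_heights.extend(heights)
        else:
            proms = signal.peak_prominences(sm.values, idx)[0]
            crz_heights.extend(heights)
            crz_proms.extend(proms)
    updates = {}
    if ca_heights:
        updates["ca_height"] = float(np.percentile(ca_heights, 100 * spec.ca_quantile))
    if crz_heights:
        updates["crz1_height"] = float(np.percentile(crz_heights, 100 * spec.crz1_quantile))
        updates["crz1_prominence"] = float(np.percentile(crz_proms, 100 * spec.crz1_quantile))
    if not updates:
        warnings.warn("no peaks found in control records; keeping default thresholds", stacklevel=2)
        return spec
    if not ca_heights and any(t.channel == "calcium" for t in control_trajs):
        warnings.warn("no calcium peaks in controls; keeping default calcium threshold", stacklevel=2)
    return replace(spec, **updates)


def detect(
    traj: Trajectory,
    thresholds: ThresholdSpec | None = None,
    presmoothed: bool = False,
) -> list[Pulse] | list[Burst]:
    """Detect calcium bursts or Crz1 pulses on one trajectory.

    The trace is smoothed (unless ``presmoothed``), local maxima above the
    channel's height threshold (and, for Crz1, the prominence threshold)
    are kept greedily highest-first subject to the minimum separation, and
    calcium events are annotated with overshoot depth: the magnitude of the
    most negative smoothed value between the burst apex and the next burst
    (capped at ``overshoot_window_sec``), clipped at 0.
    """
    th = thresholds or ThresholdSpec()
    sm = traj if presmoothed else smooth(traj, th.sg_window, th.sg_order)
    values = sm.values
    times = sm.times

    cand = _find_local_maxima(values)
    if cand.size == 0:
        return []
    proms = signal.peak_prominences(values, cand)[0]
    heights = values[cand]
    if traj.channel == "calcium":
        ok = heights >= th.ca_height
    else:
        ok = (heights >= th.crz1_height) & (proms >= th.crz1_prominence)
    cand, proms, heights = cand[ok], proms[ok], heights[ok]
    if cand.size == 0:
        return []
    keep = _greedy_select(times[cand], heights, th.min_distance_sec)
    cand, proms, heights = cand[keep], proms[keep], heights[keep]

    if traj.channel != "calcium":
        return [
            Pulse(traj.cell_id, traj.channel, float(times[i]), float(h), float(p))
            for i, h, p in zip(cand, heights, proms)
        ]

    bursts: list[Burst] = []
    for n, (i, h, p) in enumerate(zip(cand, heights, proms)):
        t0 = times[i]
        if n + 1 < cand.size:
            t_next = times[cand[n + 1]]
            interval = t_next - t0
        else:
            t_next = times[-1] + sm.dt
            interval = times[-1] - t0
        t_cap = min(t_next, t0 + th.overshoot_window_sec)
        win = (times > t0) & (times <= t_cap)
        depth = max(0.0, -float(np.min(values[win]))) if np.any(win) else 0.0
        bursts.append(
            Burst(traj.cell_id, float(t0), float(h), float(p), depth, float(interval))
        )
    return bursts


def overshoot_regression(bursts: Sequence[Burst]):
    """OLS of overshoot depth on ln(burst height): (slope, intercept, r_squared)."""
    hb = [b for b in bursts if b.height > 0]
    if len(hb) < 3:
        raise ValueError("need >= 3 bursts with positive height")
    x = np.log([b.height for b in hb])
    y = np.array([b.overshoot_depth for b in hb])
    if np.ptp(x) == 0:
        raise ValueError("degenerate: burst heights have no variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def pulse_triggered_average(
    trajs: Sequence[Trajectory],
    events: Sequence,
    window_sec: float,
):
    """Event-aligned mean trace with per-timepoint normal-theory 95% CI.

    Events (anything with ``cell_id`` and ``time_sec``) are aligned at
    time 0; windows extending past a record's edges are excluded and the
    number of snippets used is reported.

    Returns ``(rel_times, mean, ci_half_width, n_used)``.
    """
    if len(events) < 2:
        raise ValueError("need >= 2 events for a triggered average")
    by_cell = {t.cell_id: t for t in trajs}
    snippets = []
    rel = None
    for ev in events:
        traj = by_cell.get(ev.cell_id)
        if traj is None:
            continue
        dt = traj.dt
        half = int(round(window_sec / dt))
        i0 = int(round((ev.time_sec - traj.times[0]) / dt))
        if i0 - half < 0 or i0 + half >= len(traj):
            continue  # partial window at a record edge: excluded
        snippets.append(traj.values[i0 - half : i0 + half + 1])
        if rel is None:
            rel = dt * np.arange(-half, half + 1)
    if not snippets:
        raise ValueError("window exceeds all records")
    arr = np.vstack(snippets)
    mean = arr.mean(axis=0)
    n = arr.shape[0]
    sd = arr.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    ci = 1.96 * sd / np.sqrt(n)
    return rel, mean, ci, n


def cross_correlation(ca: Trajectory, crz: Trajectory, max_lag_sec: float):
    """Pearson correlation of mean-centered traces as a function of lag.

    Crz1 is linearly resampled onto the calcium grid; positive lag means
    Crz1 follows calcium.  Returns ``(lags_sec, correlations)``.
    """
    t0 = max(ca.times[0], crz.times[0])
    t1 = min(ca.times[-1], crz.times[-1])
    if t1 <= t0:
        raise ValueError("trajectories do not overlap")
    dt = ca.dt
    grid = ca.times[(ca.times >= t0) & (ca.times <= t1)]
    x = np.interp(grid, ca.times, ca.values)
    y = np.interp(grid, crz.times, crz.values)
    x = x - x.mean()
    y = y - y.mean()
    if np.allclose(x, 0) or np.allclose(y, 0):
        raise ValueError("zero-variance input")
    max_lag = int(round(max_lag_sec / dt))
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = x[: x.size - lag], y[lag:]
        else:
            a, b = x[-lag:], y[: y.size + lag]
        if a.size < 3 or a.std() == 0 or b.std() == 0:
            corr[i] = np.nan
        else:
            corr[i] = float(np.corrcoef(a, b)[0, 1])
    return lags * dt, corr
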