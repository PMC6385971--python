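"""Synthetic single-cell fixtures with known ground truth.

Generates the inputs the analysis pipeline consumes:

* calcium trajectories with stochastic bursts whose post-burst overshoot
  depth scales linearly with the natural log of burst height,
* Crz1 nuclear-localization pulse trains whose pulse count per burst
  follows a Poisson law with a log-link on ln(burst height),
* per-cell pixel sets (bright Gaussian nuclear pool over a uniform
  cytoplasmic background),
* bi-exponential photobleaching applied to any trajectory.

Every stochastic draw is governed by the spec's seed; identical specs give
bitwise-identical outputs, and every generated event is recorded in a
ground-truth structure so downstream detection and regression stages can be
scored against truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "SynthCalciumSpec",
    "SynthCrzSpec",
    "SynthPixelSpec",
    "TrueBurst",
    "TruePulse",
    "PixelSample",
    "gen_calcium",
    "gen_crz_train",
    "gen_pixels",
    "apply_photobleach",
    "burst_waveform",
    "logistic_pulse_waveform",
]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass(frozen=True)
class SynthCalciumSpec:
    """Conditions for the calcium-burst generator.

    Bursts are a Poisson process in time; heights are log-normal; the
    waveform is a double-exponential rise/decay followed by an additive
    negative-exponential undershoot peaking ``overshoot_tau`` seconds after
    the burst apex.  True overshoot depth is
    ``overshoot_gain * (ln height + N(0, depth_jitter))`` clipped at 0.
    """

    duration_sec: float = 3600.0
    dt_sec: float = 6.0
    burst_rate: float = 1.0 / 600.0      # events per second (~6 per hour)
    height_mu_log: float = 0.5           # ln-scale mean of burst height
    height_sigma_log: float = 0.5
    rise_tau: float = 8.0                # s; bursts live on the 10-100 s scale
    decay_tau: float = 30.0              # s
    overshoot_gain: float = 0.10         # depth per unit ln(height)
    overshoot_tau: float = 100.0         # s; dip minimum ~100 s after apex
    depth_jitter: float = 0.3            # sd of ln-height jitter in the depth law
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "duration_sec", "dt_sec", "burst_rate", "height_mu_log",
            "height_sigma_log", "rise_tau", "decay_tau", "overshoot_gain",
            "overshoot_tau", "depth_jitter", "noise_sd",
        ):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"SynthCalciumSpec.{name} must be finite, got {v}")
        if self.dt_sec <= 0:
            raise ValueError("dt_sec must be > 0")
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("must have decay_tau > rise_tau > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.burst_rate < 0:
            raise ValueError("burst_rate must be >= 0")


@dataclass(frozen=True)
class SynthCrzSpec:
    """Conditions for the Crz1 pulse-train generator.

    The number of pulses after burst *i* is Poisson with mean
    ``exp(count_intercept + count_slope * ln h_i)``; pulses are logistic
    product bumps placed ``first_delay_sec`` after the burst and separated
    by at least ``inter_pulse_sec``.
    """

    dt_sec: float = 30.0
    pulse_width_sec: float = 60.0
    pulse_height_mean: float = 0.6
    pulse_height_sd: float = 0.08
    pulse_height_min: float = 0.35       # keep synthetic pulses above threshold
    narrowness: float = 0.10             # logistic steepness r, 1/s
    count_intercept: float = np.log(2.0)  # Poisson log-link intercept
    count_slope: float = 0.3              # per unit ln(burst height)
    first_delay_sec: float = 90.0
    delay_jitter_sd: float = 20.0
    inter_pulse_sec: float = 150.0
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.pulse_width_sec <= 0:
            raise ValueError("pulse_width_sec must be > 0")
        if not np.isfinite(self.count_slope):
            raise ValueError("count_slope must be finite")
        if self.dt_sec <= 0:
            raise ValueError("dt_sec must be > 0")
        if self.inter_pulse_sec <= 0:
            raise ValueError("inter_pulse_sec must be > 0")


@dataclass(frozen=True)
class SynthPixelSpec:
    """Pixel-intensity fixture: Gaussian nuclear pool over uniform background."""

    n_pixels: int = 5000
    nuclear_fraction: float = 0.3
    nuc_mean: float = 15.0
    nuc_sd: float = 1.0
    cyto_lo: float = 0.0
    cyto_hi: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_pixels < 10:
            raise ValueError("n_pixels must be >= 10 (mixture fit under-determined)")
        if not 0.0 <= self.nuclear_fraction <= 1.0:
            raise ValueError("nuclear_fraction must be in [0, 1]")
        if not self.cyto_lo < self.cyto_hi:
            raise ValueError("must have cyto_lo < cyto_hi")
        if self.nuc_sd <= 0:
            raise ValueError("nuc_sd must be > 0")


@dataclass(frozen=True)
class TrueBurst:
    """Ground truth for one generated calcium burst."""

    time_sec: float          # apex time
    height: float
    overshoot_depth: float   # >= 0; depth realized in the noiseless trace


@dataclass(frozen=True)
class TruePulse:
    """Ground truth for one generated Crz1 pulse."""

    time_sec: float          # apex time
    height: float
    burst_index: int         # index into the burst list that spawned it
    ordinal: int             # 1-based position within its burst's train
    truncated: bool = False  # True if later siblings were dropped at the boundary


@dataclass(frozen=True)
class PixelSample:
    """Generated pixel intensities with ground-truth component labels."""

    intensities: np.ndarray
    is_nuclear: np.ndarray   # boolean, same length
    spec: SynthPixelSpec


def burst_waveform(u: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak double-exponential burst, apex at u = 0.

    ``u`` is time relative to the apex; the underlying difference of
    exponentials starts ``t_peak`` before the apex.
    """
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    t = u + t_peak
    raw = np.where(t >= 0, np.exp(-t / decay_tau) - np.exp(-t / rise_tau), 0.0)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return raw / peak


def _undershoot_waveform(u: np.ndarray, tau: float) -> np.ndarray:
    """Unit-depth alpha-function dip, minimum at u = tau (u relative to apex)."""
    x = np.where(u > 0, u / tau, 0.0)
    return np.where(u > 0, -x * np.exp(1.0 - x), 0.0)


def gen_calcium(spec: SynthCalciumSpec) -> tuple[Trajectory, list[TrueBurst]]:
    """Generate one cell's calcium trace plus its ground-truth burst list."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.duration_sec + 0.5 * spec.dt_sec, spec.dt_sec)
    values = np.zeros_like(times)

    n_bursts = rng.poisson(spec.burst_rate * spec.duration_sec)
    burst_times = np.sort(rng.uniform(0.0, spec.duration_sec, size=n_bursts))
    heights = rng.lognormal(spec.height_mu_log, spec.height_sigma_log, size=n_bursts)
    depth_noise = rng.normal(0.0, spec.depth_jitter, size=n_bursts)

    bursts: list[TrueBurst] = []
    for t0, h, eps in zip(burst_times, heights, depth_noise):
        depth = max(0.0, spec.overshoot_gain * (np.log(h) + eps))
        u = times - t0
        values += h * burst_waveform(u, spec.rise_tau, spec.decay_tau)
        if depth > 0:
            # The burst's decay tail is still positive where the dip bottoms
            # out; inflate the undershoot so the net noiseless minimum is
            # -depth, keeping the recorded ground truth honest.
            tail = float(
                h * burst_waveform(np.array([spec.overshoot_tau]), spec.rise_tau, spec.decay_tau)[0]
            )
            values += (depth + tail) * _undershoot_waveform(u, spec.overshoot_tau)
        bursts.append(TrueBurst(time_sec=float(t0), height=float(h), overshoot_depth=float(depth)))

    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=times.size)

    traj = Trajectory(cell_id="synthetic", channel="calcium", times=times, values=values)
    return traj, bursts


def logistic_pulse_waveform(t: np.ndarray, h: float, r: float, a: float, b: float) -> np.ndarray:
    """Single logistic-product pulse h*sigma(r(t-a))*sigma(-r(t-b))."""
    return h * _logistic(r * (t - a)) * _logistic(-r * (t - b))


def gen_crz_train(
    bursts: Sequence[TrueBurst],
    spec: SynthCrzSpec,
    duration_sec: float,
    cell_id: str = "synthetic",
) -> tuple[Trajectory, list[TruePulse]]:
    """Generate a Crz1 trace whose pulse trains follow the given bursts.

    Pulse count after burst *i* is Poisson(exp(intercept + slope*ln h_i));
    pulses that would collide with the next burst or run off the record are
    dropped with a warning and the surviving siblings flagged truncated.
    """
    spec.validate()
    for b in bursts:
        if not (0.0 <= b.time_sec <= duration_sec):
            raise ValueError(f"burst at t={b.time_sec} outside record [0, {duration_sec}]")
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, duration_sec + 0.5 * spec.dt_sec, spec.dt_sec)
    values = np.zeros_like(times)
    pulses: list[TruePulse] = []
    truncated_any = False

    ordered = sorted(range(len(bursts)), key=lambda i: bursts[i].time_sec)
    for rank, i in enumerate(ordered):
        b = bursts[i]
        next_t = bursts[ordered[rank + 1]].time_sec if rank + 1 < len(ordered) else duration_sec
        mean = np.exp(spec.count_intercept + spec.count_slope * np.log(b.height))
        n = int(rng.poisson(mean))
        t_prev = None
        kept = []
        for j in range(n):
            if j == 0:
                t_j = b.time_sec + spec.first_delay_sec + abs(rng.normal(0.0, spec.delay_jitter_sd))
            else:
                t_j = t_prev + spec.inter_pulse_sec + abs(rng.normal(0.0, spec.delay_jitter_sd))
            if t_j + spec.pulse_width_sec / 2 > min(next_t, duration_sec):
                truncated_any = True
                kept = [
                    TruePulse(p.time_sec, p.height, p.burst_index, p.ordinal, truncated=True)
                    for p in kept
                ]
                break
            h = max(spec.pulse_height_min, rng.normal(spec.pulse_height_mean, spec.pulse_height_sd))
            kept.append(TruePulse(time_sec=float(t_j), height=float(h), burst_index=i, ordinal=j + 1))
            t_prev = t_j
        for p in kept:
            a = p.time_sec - spec.pulse_width_sec / 2
            bb = p.time_sec + spec.pulse_width_sec / 2
            values += logistic_pulse_waveform(times, p.height, spec.narrowness, a, bb)
        pulses.extend(kept)

    if truncated_any:
        warnings.warn("some Crz1 pulses were truncated at a burst/record boundary", stacklevel=2)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=times.size)
    traj = Trajectory(cell_id=cell_id, channel="crz1", times=times, values=values)
    return traj, pulses


def gen_pixels(spec: SynthPixelSpec) -> PixelSample:
    """Draw one cell-frame's pixel intensities with ground-truth labels."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_nuc = int(round(spec.nuclear_fraction * spec.n_pixels))
    nuc = rng.normal(spec.nuc_mean, spec.nuc_sd, size=n_nuc)
    cyto = rng.uniform(spec.cyto_lo, spec.cyto_hi, size=spec.n_pixels - n_nuc)
    intensities = np.concatenate([nuc, cyto])
    labels = np.concatenate([np.ones(n_nuc, bool), np.zeros(spec.n_pixels - n_nuc, bool)])
    order = rng.permutation(spec.n_pixels)
    return PixelSample(intensities=intensities[order], is_nuclear=labels[order], spec=spec)


def write_pixel_tiff(samples: Sequence[PixelSample], image_path, mask_path) -> None:
    """Write pixel samples as a 16-bit intensity TIFF plus integer-label mask.

    Each sample's pixels are packed into one row-block of a shared image;
    the mask labels block k with value k+1 (0 is background).  Intensities
    are clipped to the uint16 range.
    """
    import tifffile

    if not samples:
        raise ValueError("no pixel samples to write")
    width = max(int(np.ceil(np.sqrt(s.intensities.size))) for s in samples)
    blocks, masks = [], []
    for k, s in enumerate(samples):
        n = s.intensities.size
        rows = int(np.ceil(n / width))
        img = np.zeros((rows, width), dtype=np.uint16)
        msk = np.zeros((rows, width), dtype=np.uint16)
        flat = np.clip(np.round(s.intensities), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        img.ravel()[:n] = flat
        msk.ravel()[:n] = k + 1
        blocks.append(img)
        masks.append(msk)
    tifffile.imwrite(image_path, np.vstack(blocks))
    tifffile.imwrite(mask_path, np.vstack(masks))


def apply_photobleach(traj: Trajectory, a1: float, k1: float, a2: float, k2: float) -> Trajectory:
    """Multiply a trajectory by a bi-exponential bleach factor, normalized to 1 at t=0.

    factor(t) = (a1*exp(-k1*t) + a2*exp(-k2*t)) / (a1 + a2), with t measured
    from the start of the record.
    """
    if a1 < 0 or a2 < 0 or k1 < 0 or k2 < 0:
        raise ValueError("amplitudes and rates must be >= 0")
    if a1 + a2 == 0:
        raise ValueError("a1 + a2 must be > 0")
    t = traj.times - traj.times[0]
    factor = (a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)) / (a1 + a2)
    return traj.with_values(traj.values * factor)
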