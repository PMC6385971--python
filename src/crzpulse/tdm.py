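"""Stochastic time-delay model (TDM) of Crz1 nuclear-localization pulsing.

The model converts a measured cytosolic calcium trace into pulses of
nuclear Crz1 without any feedback loop.  Calcineurin activity Cn(t) follows
a discrete-time relaxation driven by calcium,

    Cn(t+1) - Cn(t) = (Cn_base - Cn(t)) * D + max(0, Ca(t)) * A,

(negative Ca values — overshoots of the baseline-0 calcium signal — do not
activate).  Each of ~500 Crz1 molecules is an independent Markov chain:
a phosphorylated cytoplasmic molecule enters a multistage nuclear-import
chain with per-step probability Cn(t) * q_dephos (q_dephos is the
calcineurin docking-affinity knob), advances through k_in stages each with
probability p_in, resides in the nucleus until phosphorylated (probability
p_phos_nuc per step), then traverses a k_out-stage export chain with
probability p_out.  The multistage transits give Gamma-like (negative
binomial in discrete time) delay distributions; the coherent first wave of
import decoheres over successive round trips, producing a damped pulse
train whose pulse count grows with ln(burst height) — a noisy
analog-to-digital converter.

The conformational-switch model (CSM) is the comparator: nuclear Crz1 is a
steep Hill readout of Cn(t) crossing a threshold, driven by a damped
calcium oscillation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .detect import ThresholdSpec, detect
from .stats import GlmFit, poisson_glm
from .synthetic import burst_waveform
from .trajectory import Trajectory

logger = logging.getLogger(__name__)


def stable_cell_hash(cell_id: str) -> int:
    """Process-independent small hash of a cell id (for seed derivation)."""
    import zlib

    return zlib.crc32(str(cell_id).encode()) % 99991

__all__ = [
    "CnParams",
    "TDMParams",
    "CSMParams",
    "TDMResult",
    "update_calcineurin",
    "cn_fixed_point",
    "simulate_cn",
    "sample_transit_delay",
    "transit_delay_pmf",
    "single_molecule_transition_matrix",
    "stationary_nuclear_fraction",
    "simulate_tdm",
    "predict_from_calcium",
    "affinity_sweep",
    "two_pulse_shape_fits",
    "simulate_csm",
]


@dataclass(frozen=True)
class CnParams:
    """Calcineurin activity dynamics (per 1 s model step).

    Defaults are calibrated so that activity relaxes back to near-baseline
    about 5 minutes after a calcium burst (decay time constant 1/D = 125 s,
    <10% residual activity at 300 s).
    """

    Cn_base: float = 0.002  # basal activity, dimensionless
    D: float = 0.008        # decay rate per step
    A: float = 0.03         # activation per unit calcium per step

    def __post_init__(self) -> None:
        if self.Cn_base < 0:
            raise ValueError("Cn_base must be >= 0")
        if not 0 < self.D <= 1:
            raise ValueError("D must be in (0, 1]")
        if self.A < 0:
            raise ValueError("A must be >= 0")


@dataclass(frozen=True)
class TDMParams:
    """Time-delay model parameters.

    The (k, p) pairs set the import/export transit-delay distributions
    (mean k/p steps, variance k(1-p)/p^2); defaults give 75 s transits and
    a 50 s mean nuclear residence, i.e. a ~3 min round trip matching
    observed inter-pulse spacing.  ``q_dephos`` scales the import
    probability Cn(t)*q_dephos and models the calcineurin docking affinity;
    ``signal_gain`` maps nuclear fraction to the fluorescence units the
    detection thresholds are defined in.  All parameter values are
    fitted-by-us to those timescale anchors.
    """

    cn: CnParams = field(default_factory=CnParams)
    n_molecules: int = 500
    k_in: int = 60
    p_in: float = 0.8
    k_out: int = 60
    p_out: float = 0.8
    q_dephos: float = 0.25
    p_phos_nuc: float = 0.02
    signal_gain: float = 2.0  # fluorescence units per unit nuclear fraction
    dt_model: float = 1.0   # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_in < 1 or self.k_out < 1:
            raise ValueError("k_in and k_out must be >= 1")
        for name in ("p_in", "p_out", "p_phos_nuc"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.q_dephos <= 1:
            raise ValueError("q_dephos must be in [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.dt_model <= 0:
            raise ValueError("dt_model must be > 0")
        if self.signal_gain <= 0:
            raise ValueError("signal_gain must be > 0")


@dataclass(frozen=True)
class CSMParams:
    """Conformational-switch comparator: Hill readout of Cn over a threshold.

    The calcium input is a damped oscillation
    Ca(t) = amplitude * exp(-t/decay_tau) * max(0, cos(2*pi*t/period)).
    Calcineurin tracks the oscillation closely here (fast decay D), since
    this comparator assumes nuclear localization sensitively reads out the
    instantaneous activity; the high default cooperativity makes the
    readout switch-like (fully nuclear or fully cytoplasmic), so each
    pulse's duration is the time the activity spends above threshold.
    """

    cn: CnParams = field(default_factory=lambda: CnParams(Cn_base=0.002, D=0.05, A=0.03))
    hill_n: float = 50.0
    K: float = 0.3
    amplitude: float = 1.2
    period_sec: float = 300.0
    decay_tau: float = 500.0
    start_sec: float = 120.0   # oscillation onset within the record
    dt_model: float = 1.0

    def __post_init__(self) -> None:
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.K <= 0:
            raise ValueError("K must be > 0")


@dataclass
class TDMResult:
    """Simulated nuclear-fraction trajectory plus model internals."""

    trajectory: Trajectory           # nuclear fraction minus pre-stimulus baseline
    cn_trace: np.ndarray             # Cn at every model step
    nuclear_fraction: np.ndarray     # raw nuclear fraction at every model step
    model_times: np.ndarray          # model-step times (s)
    baseline: float                  # pre-stimulus nuclear fraction subtracted
    state_counts: np.ndarray | None = None  # optional (steps, 4) coarse occupancy


def update_calcineurin(Cn: float, Ca: float, p: CnParams) -> float:
    """One discrete-time step of calcineurin activity."""
    return Cn + (p.Cn_base - Cn) * p.D + max(0.0, Ca) * p.A


def cn_fixed_point(p: CnParams, Ca_const: float) -> float:
    """Stationary calcineurin activity under constant calcium: Cn_base + Ca*A/D."""
    if Ca_const < 0:
        raise ValueError("Ca_const must be >= 0")
    if p.D == 0:
        raise ValueError("D must be > 0")
    return p.Cn_base + Ca_const * p.A / p.D


def simulate_cn(ca: np.ndarray, p: CnParams, Cn0: float | None = None) -> np.ndarray:
    """Iterate the Cn update over a per-step calcium array."""
    cn = np.empty(len(ca) + 1)
    cn[0] = p.Cn_base if Cn0 is None else Cn0
    for i, c in enumerate(ca):
        cn[i + 1] = update_calcineurin(cn[i], c, p)
    return cn


def sample_transit_delay(k: int, p: float, n_samples: int, seed: int = 0) -> np.ndarray:
    """Sample multistage transit delays (steps to complete k stage-advances).

    Each stage advances with per-step probability p, so the delay is a sum
    of k geometric waits — the discrete-time analogue of a Gamma delay,
    with mean k/p and variance k(1-p)/p^2.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    rng = np.random.default_rng(seed)
    return rng.geometric(p, size=(n_samples, k)).sum(axis=1)


def transit_delay_pmf(k: int, p: float, delays: np.ndarray) -> np.ndarray:
    """Closed-form pmf of the k-stage transit delay (shifted negative binomial)."""
    from scipy import stats as sps

    delays = np.asarray(delays)
    return sps.nbinom.pmf(delays - k, k, p)


def single_molecule_transition_matrix(params: TDMParams, Cn: float) -> np.ndarray:
    """Transition matrix of one molecule's chain at fixed calcineurin activity.

    States are ordered CYTO_P, IMPORT_1..k_in, NUCLEAR, EXPORT_1..k_out.
    """
    k_in, k_out = params.k_in, params.k_out
    n = k_in + k_out + 2
    P = np.zeros((n, n))
    p_imp = min(1.0, Cn * params.q_dephos)
    nuc = k_in + 1
    P[0, 0] = 1 - p_imp
    P[0, 1] = p_imp
    for i in range(1, k_in + 1):
        nxt = i + 1  # stage k_in advances into NUCLEAR
        P[i, i] = 1 - params.p_in
        P[i, nxt] = params.p_in
    P[nuc, nuc] = 1 - params.p_phos_nuc
    P[nuc, nuc + 1] = params.p_phos_nuc
    for j in range(nuc + 1, nuc + k_out + 1):
        nxt = j + 1 if j < nuc + k_out else 0
        P[j, j] = 1 - params.p_out
        P[j, nxt] = params.p_out
    return P


def stationary_nuclear_fraction(params: TDMParams, Cn: float) -> float:
    """Stationary probability of the NUCLEAR state at fixed Cn (eigen-solve)."""
    pi = _stationary_distribution(params, Cn)
    return float(pi[params.k_in + 1])


def _stationary_distribution(params: TDMParams, Cn: float) -> np.ndarray:
    P = single_molecule_transition_matrix(params, Cn)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = pi * np.sign(pi[np.argmax(np.abs(pi))])  # eigenvector sign is arbitrary
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def simulate_tdm(
    ca: Trajectory,
    params: TDMParams | None = None,
    out_dt_sec: float = 30.0,
    burnin_sec: float = 600.0,
    record_states: bool = False,
) -> TDMResult:
    """Simulate the time-delay model driven by a measured calcium trace.

    Calcium is held piecewise-constant within each of its frames and the
    model advances in ``dt_model`` (1 s) steps.  Molecules start from the
    stationary distribution of the basal (Ca=0) chain and a burn-in period
    establishes the pre-stimulus baseline nuclear fraction, which is
    subtracted from the output.  The output trajectory is sampled on the
    Crz1 grid (``out_dt_sec``).
    """
    params = params or TDMParams()
    dt_ca = ca.dt
    reps = dt_ca / params.dt_model
    if abs(reps - round(reps)) > 1e-9:
        raise ValueError("dt_model must divide the calcium sampling interval")
    reps = int(round(reps))

    ca_steps = np.repeat(ca.values, reps)
    n_burn = int(round(burnin_sec / params.dt_model))
    drive = np.concatenate([np.zeros(n_burn), ca_steps])
    n_steps = drive.size

    rng = np.random.default_rng(params.seed)
    k_in, k_out = params.k_in, params.k_out
    nuc_state = k_in + 1
    n_states = k_in + k_out + 2

    pi0 = _stationary_distribution(params, params.cn.Cn_base)
    states = rng.choice(n_states, size=params.n_molecules, p=pi0)

    cn = params.cn.Cn_base
    cn_trace = np.empty(n_steps)
    nuc_frac = np.empty(n_steps)
    counts = np.empty((n_steps, 4), dtype=np.int32) if record_states else None
    clamp_warned = False

    in_import = None
    for t in range(n_steps):
        cn = update_calcineurin(cn, drive[t], params.cn)
        p_imp = cn * params.q_dephos
        if p_imp > 1.0:
            p_imp = 1.0
            if not clamp_warned:
                logger.warning("import probability Cn*q_dephos exceeded 1; clamped (mis-scaled parameters?)")
                clamp_warned = True
        u = rng.random(params.n_molecules)
        is_cyto = states == 0
        is_imp = (states >= 1) & (states <= k_in)
        is_nuc = states == nuc_state
        is_exp = states > nuc_state

        adv = np.zeros(params.n_molecules, dtype=bool)
        adv |= is_cyto & (u < p_imp)
        adv |= is_imp & (u < params.p_in)
        adv |= is_nuc & (u < params.p_phos_nuc)
        adv |= is_exp & (u < params.p_out)
        states = np.where(adv, states + 1, states)
        states[states >= n_states] = 0  # last export stage returns to cytoplasm

        cn_trace[t] = cn
        nuc_frac[t] = np.count_nonzero(states == nuc_state) / params.n_molecules
        if record_states:
            counts[t] = (
                np.count_nonzero(states == 0),
                np.count_nonzero((states >= 1) & (states <= k_in)),
                np.count_nonzero(states == nuc_state),
                np.count_nonzero(states > nuc_state),
            )

    baseline = float(nuc_frac[:n_burn].mean()) if n_burn > 0 else float(
        stationary_nuclear_fraction(params, params.cn.Cn_base)
    )

    model_times = ca.times[0] + params.dt_model * (np.arange(n_steps) - n_burn + 1)
    post = slice(n_burn, None)
    out_reps = out_dt_sec / params.dt_model
    if abs(out_reps - round(out_reps)) > 1e-9:
        raise ValueError("dt_model must divide out_dt_sec")
    out_times = np.arange(ca.times[0], ca.times[0] + ca_steps.size * params.dt_model, out_dt_sec)
    out_vals = params.signal_gain * np.interp(
        out_times, model_times[post], nuc_frac[post] - baseline
    )
    traj = Trajectory(cell_id=ca.cell_id, channel="crz1", times=out_times, values=out_vals)
    return TDMResult(
        trajectory=traj,
        cn_trace=cn_trace,
        nuclear_fraction=nuc_frac,
        model_times=model_times,
        baseline=baseline,
        state_counts=counts,
    )


def predict_from_calcium(
    ca_trajs: Sequence[Trajectory],
    params: TDMParams | None = None,
    thresholds: ThresholdSpec | None = None,
    n_replicates: int = 1,
    min_interval_sec: float = 600.0,
) -> tuple[list[dict], GlmFit]:
    """Predict per-burst Crz1 pulse counts from measured calcium traces.

    For each calcium trajectory the model is simulated ``n_replicates``
    times with distinct seeds; pulses are detected on the simulated Crz1
    output and counted per detected calcium burst (until the next burst,
    with the 10-min following-interval filter).  Returns the per-burst
    records and the Poisson GLM of count on ln(burst height).
    """
    params = params or TDMParams()
    th = thresholds or ThresholdSpec()
    records: list[dict] = []
    for traj in ca_trajs:
        bursts = detect(traj, th)
        if not bursts:
            continue
        for rep in range(n_replicates):
            p = replace(
                params,
                seed=int((params.seed + 1) * 100003 + stable_cell_hash(traj.cell_id) + rep)
                % (2**31),
            )
            sim = simulate_tdm(traj, p)
            pulses = detect(sim.trajectory, th)
            ptimes = np.array([pl.time_sec for pl in pulses])
            for i, b in enumerate(bursts):
                next_t = bursts[i + 1].time_sec if i + 1 < len(bursts) else traj.times[-1]
                interval = next_t - b.time_sec
                if interval < min_interval_sec:
                    continue
                n = int(np.count_nonzero((ptimes > b.time_sec) & (ptimes <= next_t)))
                records.append(
                    {
                        "cell_id": traj.cell_id,
                        "replicate": rep,
                        "burst_time": b.time_sec,
                        "burst_height": b.height,
                        "ln_height": float(np.log(b.height)),
                        "n_pulses": n,
                    }
                )
    if len(records) < 3:
        raise RuntimeError("too few burst records for a GLM (need >= 3)")
    fit = poisson_glm([r["ln_height"] for r in records], [r["n_pulses"] for r in records])
    return records, fit


def _single_burst_trajectory(
    height: float,
    duration_sec: float = 1800.0,
    burst_time: float = 300.0,
    dt_sec: float = 6.0,
) -> Trajectory:
    """Noiseless calcium record containing one burst of the given height."""
    times = np.arange(0.0, duration_sec + 0.5 * dt_sec, dt_sec)
    vals = height * burst_waveform(times - burst_time, rise_tau=8.0, decay_tau=30.0)
    return Trajectory("burst", "calcium", times, vals)


def affinity_sweep(
    params: TDMParams,
    q_values: Sequence[float],
    burst_height: float = 1.0,
    n_seeds: int = 100,
    thresholds: ThresholdSpec | None = None,
) -> dict:
    """Mean detected pulses per burst as a function of docking affinity.

    Higher ``q_dephos`` (affinity) lets Crz1 be re-imported at lower
    residual calcineurin activity, so the molecule population oscillates
    longer after a burst and more pulses are detected.
    """
    qs = list(q_values)
    if any(b <= a for a, b in zip(qs, qs[1:])):
        raise ValueError("q_values must be increasing")
    th = thresholds or ThresholdSpec()
    ca = _single_burst_trajectory(burst_height)
    means, counts_all = [], []
    for q in qs:
        counts = []
        for s in range(n_seeds):
            p = replace(params, q_dephos=q, seed=(params.seed * 7919 + s) % (2**31))
            sim = simulate_tdm(ca, p)
            counts.append(len(detect(sim.trajectory, th)))
        counts_all.append(counts)
        means.append(float(np.mean(counts)))
    return {"q_values": qs, "mean_pulses": means, "counts": counts_all}


def two_pulse_shape_fits(
    model: str = "tdm",
    n_cells: int = 200,
    seed: int = 0,
    burst_height: float = 1.5,
    noise_sd: float = 0.02,
    out_dt_sec: float = 10.0,
    min_height: float = 0.3,
    min_distance_sec: float = 60.0,
    tdm_params: TDMParams | None = None,
    csm_params: CSMParams | None = None,
) -> list:
    """Logistic-pulse fits of the first two simulated pulses, per cell.

    Simulates ``n_cells`` single-burst responses of the chosen model at the
    model's native resolution (no smoothing; pulse-shape differences
    between successive pulses are narrower than the microscope's 30 s grid
    resolves), locates the first two pulses, and fits the two-pulse
    logistic model.  For the CSM — which is deterministic — cell-to-cell
    variability enters through the calcium-oscillation amplitude and
    observation noise.  Cells with fewer than two detectable pulses are
    skipped.
    """
    from scipy.signal import find_peaks

    from .shape import fit_logistic_pulses

    rng = np.random.default_rng(seed)
    fits = []
    dist = max(1, int(round(min_distance_sec / out_dt_sec)))
    for i in range(n_cells):
        if model == "tdm":
            ca = _single_burst_trajectory(burst_height, duration_sec=1500.0)
            p = replace(tdm_params or TDMParams(), seed=int(rng.integers(2**31)))
            tr = simulate_tdm(ca, p, out_dt_sec=out_dt_sec).trajectory
        elif model == "csm":
            # Amplitudes span the regime where the second excursion ranges
            # from comfortably supra-threshold down to grazing.
            base = csm_params or CSMParams()
            p = replace(base, amplitude=base.amplitude * float(rng.uniform(0.75, 1.08)))
            tr = simulate_csm(p, duration_sec=1800.0, out_dt_sec=out_dt_sec)
        else:
            raise ValueError("model must be 'tdm' or 'csm'")
        if noise_sd > 0:
            tr = tr.with_values(tr.values + rng.normal(0, noise_sd, tr.values.size))
        peaks, _ = find_peaks(tr.values, height=min_height, distance=dist)
        if peaks.size < 2:
            continue
        t1, t2 = tr.times[peaks[0]], tr.times[peaks[1]]
        mask = (tr.times >= t1 - 150) & (tr.times <= t2 + 180)
        try:
            fit = fit_logistic_pulses(
                times=tr.times[mask], values=tr.values[mask], n_pulses=2, seed=i
            )
        except (RuntimeError, ValueError):
            continue
        fits.append(fit)
    return fits


def simulate_csm(params: CSMParams, duration_sec: float = 1800.0, out_dt_sec: float = 30.0) -> Trajectory:
    """Deterministic conformational-switch simulation.

    A damped calcium oscillation drives Cn via the same update rule; the
    nuclear signal is the Hill readout Cn^n / (K^n + Cn^n), with the basal
    readout subtracted so the output is baseline-0.
    """
    n_steps = int(round(duration_sec / params.dt_model))
    t = params.dt_model * np.arange(n_steps)
    tt = t - params.start_sec
    ca = np.where(
        tt >= 0,
        params.amplitude
        * np.exp(-np.maximum(tt, 0) / params.decay_tau)
        * np.maximum(0.0, np.cos(2 * np.pi * tt / params.period_sec)),
        0.0,
    )
    cn = simulate_cn(ca, params.cn)[1:]
    hill = cn**params.hill_n / (params.K**params.hill_n + cn**params.hill_n)
    base = params.cn.Cn_base ** params.hill_n / (
        params.K**params.hill_n + params.cn.Cn_base ** params.hill_n
    )
    sig = hill - base
    out_times = np.arange(0.0, duration_sec, out_dt_sec)
    out_vals = np.interp(out_times, t, sig)
    return Trajectory("csm", "crz1", out_times, out_vals)
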