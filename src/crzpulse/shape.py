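"""Pulse shape and trajectory periodicity.

Two quantifications of Crz1 dynamics:

* **Logistic pulse fitting** — each pulse is a product of a logistic rise
  and a logistic fall sharing one steepness r (the *narrowness*; smaller r
  means a wider pulse):

      y(t) = baseline + sum_i h_i * s(r_i (t - a_i)) * s(-r_i (t - b_i)),

  with s the standard logistic function.  By default the rise and fall
  midpoints are tied, b_i - a_i = 2 / r_i, so each pulse is a self-similar
  bump whose duration is proportional to 1/r_i: r is the narrowness, an
  inverse pulse width.  (With a free b - a, r degenerates into an
  edge-steepness parameter and no longer tracks pulse duration; the free
  variant remains available via ``tie_width=False``.)  Fitted by
  multi-start nonlinear least squares; yields per-pulse height h_i and
  narrowness r_i, used to compare first and second pulses after a burst.

* **Gaussian-process periodicity** — the log-likelihood ratio (LLR, nats)
  between the maximized GP marginal likelihoods under a periodic kernel
  (exp-sine-squared + white noise) and an aperiodic kernel (squared
  exponential + white noise).  Positive LLR favours periodic dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, signal, stats

from .trajectory import Trajectory

__all__ = [
    "LogisticPulseFit",
    "PulseShape",
    "PeriodicityResult",
    "fit_logistic_pulses",
    "compare_first_second",
    "gp_llr",
    "gp_log_marginal_likelihood",
    "llr_vs_burst_height",
    "post_burst_segment",
]

JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass(frozen=True)
class PulseShape:
    """One fitted pulse: height, narrowness, rise/fall midpoints (a < b)."""

    h: float
    r: float
    a: float
    b: float


@dataclass
class LogisticPulseFit:
    """Least-squares logistic-pulse fit of a trajectory segment."""

    pulses: list[PulseShape]   # time-ordered
    baseline: float
    r_squared: float           # nan when the segment has no variance
    converged: bool
    at_bound: bool             # some fitted r hit its optimizer bound

    @property
    def heights(self) -> np.ndarray:
        return np.array([p.h for p in self.pulses])

    @property
    def narrowness(self) -> np.ndarray:
        return np.array([p.r for p in self.pulses])


@dataclass
class PeriodicityResult:
    """Periodic-vs-aperiodic GP comparison for one segment.

    ``llr`` is the difference of maximized log marginal likelihoods minus a
    one-nat complexity charge for the periodic model's extra hyperparameter
    (the period); ``loglik_periodic``/``loglik_aperiodic`` are raw.
    """

    llr: float                       # nats; >0 favours the periodic model
    periodic_params: dict            # period, length_scale, signal_var, noise_var
    aperiodic_params: dict           # length_scale, signal_var, noise_var
    loglik_periodic: float
    loglik_aperiodic: float
    n_points: int


def _pulse_model(
    t: np.ndarray, params: np.ndarray, n_pulses: int, tie_width: bool
) -> np.ndarray:
    """Tied: params = [baseline, (h, r, a)*n]; free: [baseline, (h, r, a, w)*n]."""
    y = np.full_like(t, params[0], dtype=float)
    k = 3 if tie_width else 4
    for i in range(n_pulses):
        p = params[1 + k * i : 1 + k * (i + 1)]
        if tie_width:
            h, r, a = p
            w = 2.0 / r
        else:
            h, r, a, w = p
        y += h * _sigmoid(r * (t - a)) * _sigmoid(-r * (t - a - w))
    return y


R_BOUNDS = (1e-4, 10.0)
TIED_WIDTH_FACTOR = 2.0  # b - a = TIED_WIDTH_FACTOR / r in the tied fit


def fit_logistic_pulses(
    traj: Trajectory | None = None,
    n_pulses: int = 1,
    n_starts: int = 4,
    times: np.ndarray | None = None,
    values: np.ndarray | None = None,
    seed: int = 0,
    tie_width: bool = True,
) -> LogisticPulseFit:
    """Fit ``n_pulses`` logistic-product pulses plus a shared baseline.

    With ``tie_width`` (default) each pulse has b - a = 2/r, so r is an
    inverse pulse duration (the narrowness); with ``tie_width=False`` the
    rise-fall separation is free and r measures edge steepness only.
    Starts are seeded from the segment's highest local maxima (peak
    positions and heights), with randomized perturbations for the
    remaining starts.  The best-objective fit over all starts is returned;
    a fitted narrowness at the optimizer bound is flagged.
    """
    if traj is not None:
        times, values = traj.times, traj.values
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if n_pulses not in (1, 2):
        raise ValueError("n_pulses must be 1 or 2")
    if t.size < 8 * n_pulses:
        raise ValueError("need >= 8 samples per pulse")
    rng = np.random.default_rng(seed)
    dt = float(np.median(np.diff(t)))
    span = t[-1] - t[0]

    # Peak-seeded initial pulse locations; enforce separation so that noise
    # spikes on one plateau cannot seed both pulses onto the same bump.
    peaks, _ = signal.find_peaks(y)
    order = peaks[np.argsort(y[peaks])[::-1]] if peaks.size else np.array([], int)
    min_sep = span / (2 * n_pulses)
    guesses: list[float] = []
    for i in order:
        if all(abs(t[i] - g) >= min_sep for g in guesses):
            guesses.append(float(t[i]))
        if len(guesses) == n_pulses:
            break
    while len(guesses) < n_pulses:
        guesses.append(t[0] + span * (len(guesses) + 1) / (n_pulses + 1))
    guesses = sorted(guesses)

    scale = float(np.ptp(y)) or 1.0
    base0 = float(np.percentile(y, 10))
    w0 = max(4 * dt, span / (3 * n_pulses))
    k = 3 if tie_width else 4
    # Pulses narrower than the sampling or wider than the whole segment are
    # unresolvable; bound r (and h) accordingly to keep the fit identified.
    r_lo = max(R_BOUNDS[0], TIED_WIDTH_FACTOR / (2 * span))
    r_hi = min(R_BOUNDS[1], 2 * TIED_WIDTH_FACTOR / dt)
    h_hi = 4 * scale

    def make_start(jitter: bool):
        p = [base0]
        for g in guesses:
            a = g - w0 / 2
            h = max(float(np.interp(g, t, y)) - base0, 0.1 * scale)
            r = (TIED_WIDTH_FACTOR if tie_width else 4.0) / w0
            if jitter:
                a += rng.normal(0, w0 / 4)
                h *= rng.uniform(0.5, 1.5)
                r *= rng.uniform(0.3, 3.0)
            p.extend([min(h, h_hi), np.clip(r, r_lo, r_hi), a])
            if not tie_width:
                p.append(w0 * rng.uniform(0.5, 1.5) if jitter else w0)
        return np.array(p)

    lo = [-np.inf] + ([0.0, r_lo, t[0] - w0] + ([] if tie_width else [2 * dt])) * n_pulses
    hi = [np.inf] + ([h_hi, r_hi, t[-1]] + ([] if tie_width else [2 * span])) * n_pulses

    best = None
    for s in range(n_starts):
        x0 = make_start(jitter=s > 0)
        try:
            res = optimize.least_squares(
                lambda p: _pulse_model(t, p, n_pulses, tie_width) - y,
                x0=np.clip(x0, lo, hi),
                bounds=(lo, hi),
                xtol=1e-10, ftol=1e-10, max_nfev=600,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("logistic pulse fit failed to converge from any start")

    p = best.x
    pulses = []
    at_bound = False
    for i in range(n_pulses):
        pi = p[1 + k * i : 1 + k * (i + 1)]
        if tie_width:
            h, r, a = pi
            w = TIED_WIDTH_FACTOR / r
        else:
            h, r, a, w = pi
        if r <= r_lo * 1.001 or r >= r_hi * 0.999:
            at_bound = True
        pulses.append(PulseShape(h=float(h), r=float(r), a=float(a), b=float(a + w)))
    pulses.sort(key=lambda s: (s.a + s.b) / 2)

    ss_res = float(np.sum((_pulse_model(t, p, n_pulses, tie_width) - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return LogisticPulseFit(
        pulses=pulses, baseline=float(p[0]), r_squared=r2,
        converged=bool(best.success), at_bound=at_bound,
    )


def compare_first_second(fits: list[LogisticPulseFit]) -> dict:
    """Paired t-tests on (h1 - h2) and (r1 - r2) over two-pulse fits."""
    two = [f for f in fits if len(f.pulses) == 2]
    if len(two) < 3:
        raise ValueError("need >= 3 two-pulse fits")
    h1 = np.array([f.pulses[0].h for f in two])
    h2 = np.array([f.pulses[1].h for f in two])
    r1 = np.array([f.pulses[0].r for f in two])
    r2 = np.array([f.pulses[1].r for f in two])
    th, ph = stats.ttest_rel(h1, h2)
    tr, pr = stats.ttest_rel(r1, r2)
    return {
        "n": len(two),
        "mean_h1": float(h1.mean()), "mean_h2": float(h2.mean()),
        "mean_r1": float(r1.mean()), "mean_r2": float(r2.mean()),
        "height_t": float(th), "height_p": float(ph),
        "narrowness_t": float(tr), "narrowness_p": float(pr),
        "second_shorter": bool(h2.mean() < h1.mean()),
        "second_less_narrow": bool(r2.mean() < r1.mean()),
    }


def _kernel_periodic(t: np.ndarray, period: float, ls: float, sig_var: float) -> np.ndarray:
    d = t[:, None] - t[None, :]
    return sig_var * np.exp(-2.0 * np.sin(np.pi * d / period) ** 2 / ls**2)


def _kernel_rbf(t: np.ndarray, ls: float, sig_var: float) -> np.ndarray:
    d = t[:, None] - t[None, :]
    return sig_var * np.exp(-(d**2) / (2.0 * ls**2))


def gp_log_marginal_likelihood(y: np.ndarray, K: np.ndarray, noise_var: float) -> float:
    """Standard GP log marginal likelihood with a jitter ladder for stability."""
    n = y.size
    for jit in JITTERS:
        try:
            L = linalg.cholesky(K + (noise_var + jit) * np.eye(n), lower=True)
        except linalg.LinAlgError:
            continue
        alpha = linalg.cho_solve((L, True), y)
        return float(
            -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * np.log(2 * np.pi)
        )
    raise linalg.LinAlgError("covariance not positive definite at maximum jitter")


def _fit_gp(y, t, kernel, theta0_list, bounds):
    """Maximize the marginal likelihood over log-hyperparameters, multi-start."""

    def nll(log_theta):
        theta = np.exp(log_theta)
        try:
            K = kernel(t, *theta[:-1])
            return -gp_log_marginal_likelihood(y, K, theta[-1])
        except (linalg.LinAlgError, FloatingPointError):
            return 1e10

    best = None
    log_bounds = [(np.log(a), np.log(b)) for a, b in bounds]
    for theta0 in theta0_list:
        res = optimize.minimize(
            nll, np.log(theta0), method="L-BFGS-B", bounds=log_bounds,
            options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(-best.fun), np.exp(best.x)


def gp_llr(
    traj: Trajectory | None = None,
    n_starts: int = 8,
    period_bounds: tuple[float, float] | None = None,
    times: np.ndarray | None = None,
    values: np.ndarray | None = None,
) -> PeriodicityResult:
    """Periodic-vs-aperiodic GP log-likelihood ratio for one segment.

    Both models share a white-noise term; hyperparameters are maximized by
    bounded quasi-Newton from multiple starts (periods log-spaced in
    ``period_bounds``, default [60 s, half the segment span]).
    """
    if traj is not None:
        times, values = traj.times, traj.values
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if t.size < 16:
        raise ValueError("need >= 16 samples")
    y = y - y.mean()
    var = float(y.var())
    if var == 0:
        raise ValueError("zero-variance segment")
    span = float(t[-1] - t[0])
    dt = float(np.median(np.diff(t)))
    if period_bounds is None:
        period_bounds = (60.0, span / 2)

    var_b = (1e-4 * var, 100 * var)
    noise_b = (1e-6 * var, 10 * var)

    # Aperiodic: squared-exponential + noise.
    ls_b = (dt / 2, 10 * span)
    starts_a = [
        (ls, 0.5 * var, 0.5 * var)
        for ls in np.geomspace(2 * dt, span, 4)
    ]
    ll_a, theta_a = _fit_gp(
        y, t, _kernel_rbf, starts_a, [ls_b, var_b, noise_b]
    )

    # Periodic: exp-sine-squared + noise.  The length-scale is bounded below
    # at 4 so the periodic model stays in the smooth, sinusoid-like regime;
    # with a free length-scale the kernel can chase chance structure in
    # pure noise, inflating null LLRs.
    pls_b = (4.0, 20.0)
    starts_p = [
        (P, 5.0, 0.5 * var, 0.5 * var)
        for P in np.geomspace(period_bounds[0], period_bounds[1], n_starts)
    ]
    ll_p, theta_p = _fit_gp(
        y, t, _kernel_periodic, starts_p, [period_bounds, pls_b, var_b, noise_b]
    )

    # AIC-style complexity correction: the periodic model carries one more
    # free hyperparameter (the period) than the aperiodic model, so one nat
    # is charged to put the two maximized likelihoods on equal footing.
    return PeriodicityResult(
        llr=float(ll_p - ll_a - 1.0),
        periodic_params={
            "period": float(theta_p[0]), "length_scale": float(theta_p[1]),
            "signal_var": float(theta_p[2]), "noise_var": float(theta_p[3]),
        },
        aperiodic_params={
            "length_scale": float(theta_a[0]),
            "signal_var": float(theta_a[1]), "noise_var": float(theta_a[2]),
        },
        loglik_periodic=ll_p,
        loglik_aperiodic=ll_a,
        n_points=int(t.size),
    )


def llr_vs_burst_height(
    llrs,
    heights,
    split_height: float | None = None,
) -> dict:
    """OLS of LLR on burst height, plus a high-vs-low two-group comparison."""
    llrs = np.asarray(llrs, float)
    heights = np.asarray(heights, float)
    if llrs.size < 4:
        raise ValueError("need >= 4 (llr, height) pairs")
    if np.ptp(heights) == 0:
        raise ValueError("degenerate: heights have no variance")
    res = stats.linregress(heights, llrs)
    out = {
        "slope": float(res.slope),
        "slope_se": float(res.stderr),
        "p_value": float(res.pvalue),
        "r_squared": float(res.rvalue**2),
        "n": int(llrs.size),
    }
    split = float(np.median(heights)) if split_height is None else split_height
    hi = llrs[heights > split]
    lo = llrs[heights <= split]
    if hi.size >= 2 and lo.size >= 2:
        tt, tp = stats.ttest_ind(hi, lo, equal_var=False)
        out["split_height"] = split
        out["high_minus_low"] = float(hi.mean() - lo.mean())
        out["split_t"] = float(tt)
        out["split_p"] = float(tp)
    return out


def post_burst_segment(
    traj: Trajectory,
    bursts,
    edge_margin_sec: float = 300.0,
    side: str = "post",
) -> Trajectory | None:
    """Segment of a Crz1 record after (or before) the cell's largest burst.

    Cells whose largest calcium burst falls within ``edge_margin_sec`` of
    either record edge are excluded (returns None): too little trajectory
    remains on one side to evaluate periodicity.
    """
    if not bursts:
        return None
    biggest = max(bursts, key=lambda b: b.height)
    t0, t1 = traj.times[0], traj.times[-1]
    if biggest.time_sec < t0 + edge_margin_sec or biggest.time_sec > t1 - edge_margin_sec:
        return None
    if side == "post":
        mask = traj.times >= biggest.time_sec
    elif side == "pre":
        mask = traj.times <= biggest.time_sec
    else:
        raise ValueError("side must be 'post' or 'pre'")
    if np.count_nonzero(mask) < 16:
        return None
    return Trajectory(traj.cell_id, traj.channel, traj.times[mask], traj.values[mask])
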