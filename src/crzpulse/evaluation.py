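"""Property evaluations of the full pipeline on its synthetic study conditions.

Each function sets up the study conditions the package's synthetic
generators define, runs the relevant pipeline stage(s) end-to-end, and
measures a quantitative property of the result: calcineurin relaxation
accuracy, transit-delay law agreement, mixture-fit recovery, detection
operating characteristics, the analog-to-digital slope, model direction
contrasts, periodicity calibration, the docking-affinity effect, and the
calibration of the matched-vs-control tests.  They are used by the
acceptance script and the acceptance test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import replace

import numpy as np
from scipy import optimize, stats as sps

from .detect import ThresholdSpec, detect
from .quantify import PixelSet, fit_mixture_em
from .shape import compare_first_second, gp_llr, llr_vs_burst_height
from .stats import BONFERRONI_ALPHA, compare_offsets, poisson_glm
from .synthetic import SynthCalciumSpec, SynthPixelSpec, gen_calcium, gen_pixels
from .tdm import (
    CnParams,
    TDMParams,
    affinity_sweep,
    cn_fixed_point,
    sample_transit_delay,
    simulate_cn,
    simulate_tdm,
    transit_delay_pmf,
    two_pulse_shape_fits,
    _single_burst_trajectory,
)

__all__ = [
    "cn_convergence_error",
    "transit_delay_calibration",
    "em_recovery",
    "detection_performance",
    "tdm_adc_glm",
    "shape_direction_contrast",
    "periodicity_calibration",
    "periodicity_height_slope",
    "affinity_doubling",
    "test_calibration_rates",
    "glm_oracle_deviation",
]


def cn_convergence_error(n_steps: int = 10_000) -> float:
    """|simulated Cn - closed-form fixed point| after n_steps at constant Ca."""
    p = CnParams(Cn_base=0.1, D=0.5, A=0.2)
    err = 0.0
    for ca_const, cn0 in ((0.0, 1.0), (1.0, 0.0), (2.5, 5.0)):
        cn = simulate_cn(np.full(n_steps, ca_const), p, Cn0=cn0)
        err = max(err, abs(cn[-1] - cn_fixed_point(p, ca_const)))
    return float(err)


def transit_delay_calibration(
    k: int = 5, p: float = 0.5, n_samples: int = 100_000, seed: int = 0
) -> dict:
    """Empirical moments and pmf distance of the multistage transit delay."""
    d = sample_transit_delay(k, p, n_samples, seed=seed)
    mean_rel = abs(d.mean() - k / p) / (k / p)
    var_rel = abs(d.var() - k * (1 - p) / p**2) / (k * (1 - p) / p**2)
    support = np.arange(k, d.max() + 1)
    emp = np.bincount(d, minlength=support[-1] + 1)[k:] / n_samples
    theo = transit_delay_pmf(k, p, support)
    tv = 0.5 * float(np.sum(np.abs(emp - theo))) + 0.5 * float(1 - theo.sum())
    return {"mean_rel_err": float(mean_rel), "var_rel_err": float(var_rel), "tv_distance": tv}


def em_recovery(n_seeds: int = 20, seed: int = 0, rel_tol: float = 0.05) -> dict:
    """Mixture-fit recovery on generated pixel sets; scale-relative 5% bands."""
    truth = SynthPixelSpec()
    span = truth.cyto_hi - truth.cyto_lo
    n_ok = 0
    monotone = True
    for i in range(n_seeds):
        px = gen_pixels(replace(truth, seed=seed + i))
        fit = fit_mixture_em(PixelSet(px.intensities))
        if fit.loglik_path is not None and np.any(np.diff(fit.loglik_path) < -1e-9):
            monotone = False
        ok = (
            abs(fit.w_gauss - truth.nuclear_fraction) <= rel_tol * truth.nuclear_fraction
            and abs(fit.mu - truth.nuc_mean) <= rel_tol * truth.nuc_mean
            and abs(fit.sigma - truth.nuc_sd) <= rel_tol * max(truth.nuc_sd, 1.0)
            and abs(fit.u_lo - truth.cyto_lo) <= rel_tol * span
            and abs(fit.u_hi - truth.cyto_hi) <= rel_tol * span
        )
        n_ok += ok
    return {"n_recovered": int(n_ok), "n_seeds": int(n_seeds), "loglik_monotone": monotone}


def detection_performance(n_traj: int = 100, seed: int = 0) -> dict:
    """Sensitivity / FDR of burst detection on seeded synthetic records.

    Sensitivity is scored over ground-truth bursts at >= 2x the height
    threshold and >= 2x the minimum separation from their neighbours; false
    discoveries are detections with no true burst within half the minimum
    separation.
    """
    th = ThresholdSpec()
    tp = fn = fp = n_det = 0
    for i in range(n_traj):
        spec = SynthCalciumSpec(duration_sec=2400.0, burst_rate=1 / 500.0, seed=seed + i)
        traj, truth = gen_calcium(spec)
        truth_t = np.array([b.time_sec for b in truth])
        detected = detect(traj, th)
        det_t = np.array([d.time_sec for d in detected])
        n_det += det_t.size
        for b in truth:
            others = truth_t[truth_t != b.time_sec]
            sep = np.min(np.abs(others - b.time_sec)) if others.size else np.inf
            if b.height < 2 * th.ca_height or sep < 2 * th.min_distance_sec:
                continue
            if det_t.size and np.min(np.abs(det_t - b.time_sec)) <= th.min_distance_sec * 0.75:
                tp += 1
            else:
                fn += 1
        for t in det_t:
            if truth_t.size == 0 or np.min(np.abs(truth_t - t)) > th.min_distance_sec * 0.75:
                fp += 1
    sens = tp / max(tp + fn, 1)
    fdr = fp / max(n_det, 1)
    return {"sensitivity": float(sens), "fdr": float(fdr), "n_true_scored": tp + fn}


def tdm_adc_glm(n_cells: int = 200, seed: int = 0) -> dict:
    """Poisson GLM of TDM-predicted pulse count on ln burst height.

    Single-burst calcium records with heights spanning two decades
    (0.08-8 fluorescence units) are fed through the time-delay model and
    the standard pulse detector; the noisy analog-to-digital property is
    the positive regression slope.
    """
    rng = np.random.default_rng(seed)
    th = ThresholdSpec()
    xs, ys = [], []
    for i in range(n_cells):
        h = float(np.exp(rng.uniform(np.log(0.08), np.log(8.0))))
        ca = _single_burst_trajectory(h, duration_sec=1800.0)
        sim = simulate_tdm(ca, TDMParams(seed=int(rng.integers(2**31))))
        n = len(detect(sim.trajectory, th))
        xs.append(np.log(h))
        ys.append(n)
    fit = poisson_glm(xs, ys)
    ci_lo = fit.slope - 1.96 * fit.slope_se
    return {
        "slope": fit.slope, "slope_se": fit.slope_se, "p_value": fit.p_value,
        "ci_lower": float(ci_lo), "n": fit.n,
    }


def shape_direction_contrast(n_cells: int = 200, seed: int = 0) -> dict:
    """First-vs-second pulse height/narrowness contrast, TDM vs CSM."""
    out = {}
    for model in ("tdm", "csm"):
        fits = two_pulse_shape_fits(model=model, n_cells=n_cells, seed=seed)
        out[model] = compare_first_second(fits)
    return out


def periodicity_calibration(n_seeds: int = 100, seed: int = 0) -> dict:
    """GP LLR on periodic vs aperiodic synthetic segments (30 s grid)."""
    t = np.arange(60) * 30.0
    pos = small = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(seed + i)
        y = np.sin(2 * np.pi * t / 300.0) + rng.normal(0, 0.22, t.size)  # SNR ~10
        pos += gp_llr(times=t, values=y).llr > 0
        y = rng.normal(0, 1.0, t.size)
        small += gp_llr(times=t, values=y).llr <= 1.0
    return {
        "frac_periodic_positive": pos / n_seeds,
        "frac_null_small": small / n_seeds,
        "n_seeds": n_seeds,
    }


def periodicity_height_slope(n_cells: int = 40, seed: int = 0) -> dict:
    """LLR of TDM post-burst dynamics regressed on burst height."""
    rng = np.random.default_rng(seed)
    llrs, heights = [], []
    for i in range(n_cells):
        h = float(np.exp(rng.uniform(np.log(0.15), np.log(8.0))))
        ca = _single_burst_trajectory(h, duration_sec=2100.0, burst_time=300.0)
        sim = simulate_tdm(ca, TDMParams(seed=int(rng.integers(2**31))))
        tr = sim.trajectory
        mask = tr.times >= 300.0
        vals = tr.values[mask] + rng.normal(0, 0.02, int(mask.sum()))
        llrs.append(gp_llr(times=tr.times[mask], values=vals).llr)
        heights.append(h)
    return llr_vs_burst_height(llrs, heights)


def affinity_doubling(n_seeds: int = 500, seed: int = 0) -> dict:
    """Pulse-count gain from doubling the docking affinity q_dephos."""
    base = TDMParams(seed=seed)
    res = affinity_sweep(base, [base.q_dephos, 2 * base.q_dephos], n_seeds=n_seeds)
    lo = np.array(res["counts"][0], float)
    hi = np.array(res["counts"][1], float)
    t, p_two = sps.ttest_ind(hi, lo, equal_var=False)
    p_one = p_two / 2 if t > 0 else 1 - p_two / 2
    return {
        "mean_pulses_base": float(lo.mean()),
        "mean_pulses_doubled": float(hi.mean()),
        "one_sided_p": float(p_one),
        "n_seeds": n_seeds,
    }


def test_calibration_rates(n_sims: int = 10_000, n_per_group: int = 100, seed: int = 0) -> dict:
    """Type-I rates of the matched-vs-control t and F tests at alpha=0.0031."""
    rng = np.random.default_rng(seed)
    t_hits = f_hits = 0
    for _ in range(n_sims):
        a = rng.normal(0.0, 1.0, n_per_group)
        b = rng.normal(0.0, 1.0, n_per_group)
        res = compare_offsets(a, b)
        t_hits += res.t_p < BONFERRONI_ALPHA
        f_hits += res.f_p < BONFERRONI_ALPHA
    return {
        "t_type1_rate": t_hits / n_sims,
        "f_type1_rate": f_hits / n_sims,
        "alpha": BONFERRONI_ALPHA,
        "n_sims": n_sims,
    }


GLM_ORACLE_INSTANCES = (
    ((0.0, 0.5, 1.0, 1.5), (1, 2, 2, 4)),
    ((-1.0, 0.0, 1.0, 2.0), (0, 1, 3, 5)),
    ((0.2, 0.4, 0.9, 1.4, 2.0), (1, 1, 2, 2, 3)),
    ((0.0, 0.7, 1.3, 2.2, 3.0, 4.1), (1, 0, 2, 3, 5, 6)),
    ((-0.5, 0.1, 0.9, 1.6), (2, 1, 3, 2)),
    ((0.0, 1.0, 2.0, 3.0, 4.0, 5.0), (1, 1, 2, 4, 5, 9)),
)


def glm_oracle_deviation() -> float:
    """Max |IRLS - brute-force| over the small-instance fixture set.

    The oracle maximizes the Poisson log-likelihood directly (coarse grid
    of simplex starts), independent of the IRLS path.
    """
    worst = 0.0
    for x, y in GLM_ORACLE_INSTANCES:
        x_arr = np.array(x, float)
        y_arr = np.array(y, float)

        def nll(params):
            eta = params[0] + params[1] * x_arr
            return -np.sum(y_arr * eta - np.exp(eta))

        best = None
        for b0 in np.linspace(-3, 3, 7):
            for b1 in np.linspace(-3, 3, 7):
                r = optimize.minimize(
                    nll, [b0, b1], method="Nelder-Mead",
                    options={"xatol": 1e-11, "fatol": 1e-13, "maxiter": 3000},
                )
                if best is None or r.fun < best.fun:
                    best = r
        fit = poisson_glm(x_arr, y_arr)
        worst = max(
            worst, abs(fit.intercept - best.x[0]), abs(fit.slope - best.x[1])
        )
    return float(worst)
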