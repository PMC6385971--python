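"""Reporter intensity quantification.

Turns per-cell pixel data into calcium and Crz1 signals:

* GCaMP calcium signal: mean pixel intensity over the cell.
* Crz1 nuclear/cytoplasmic signals: a two-component mixture of a Gaussian
  (the compact bright nuclear pixel population) and a uniform distribution
  (the spread-out cytoplasmic background), fitted per cell-frame by
  expectation-maximization.
* Photobleaching correction by bi-exponential regression against a
  reference trace, followed by baseline-0 normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .trajectory import Trajectory

__all__ = [
    "PixelSet",
    "MixtureFit",
    "BleachFit",
    "gcamp_signal",
    "fit_mixture_em",
    "correct_photobleach",
    "read_pixel_tiff",
]

# Relative floor on sigma, as a fraction of the data range, preventing the
# Gaussian component from collapsing onto a single pixel value.
SIGMA_FLOOR_FRAC = 1e-6


@dataclass
class PixelSet:
    """All pixel intensities for one cell at one frame."""

    intensities: np.ndarray
    cell_id: str = "cell"
    time_sec: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("intensities must be 1-D")
        if self.intensities.size == 0:
            raise ValueError("empty pixel set")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("pixel intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("pixel intensities must be >= 0")


@dataclass
class MixtureFit:
    """Gaussian + uniform mixture parameters for one pixel set.

    ``nuclear_signal`` is the weighted expected intensity of the Gaussian
    (bright nuclear) component, ``w_gauss * mu``; ``cytoplasmic_signal`` is
    the expected intensity of the uniform component, ``(u_lo + u_hi) / 2``.
    The roles can be swapped via ``fit_mixture_em(nuclear_component=...)``.
    """

    w_gauss: float
    mu: float
    sigma: float
    u_lo: float
    u_hi: float
    loglik: float
    n_iter: int
    converged: bool
    nuclear_signal: float
    cytoplasmic_signal: float
    loglik_path: np.ndarray | None = None


@dataclass
class BleachFit:
    """Bi-exponential bleach model b(t) = a1*exp(-k1 t) + a2*exp(-k2 t), k1 >= k2."""

    a1: float
    k1: float
    a2: float
    k2: float
    r_squared: float


def gcamp_signal(pixels: PixelSet) -> float:
    """Mean pixel intensity over the cell — the GCaMP calcium readout."""
    return float(np.mean(pixels.intensities))


def mixture_loglik(
    x: np.ndarray, w: float, mu: float, sigma: float, u_lo: float, u_hi: float
) -> float:
    """Log-likelihood of the Gaussian+uniform mixture on data x."""
    gauss = w * stats.norm.pdf(x, mu, sigma)
    unif = (1.0 - w) * np.where((x >= u_lo) & (x <= u_hi), 1.0 / (u_hi - u_lo), 0.0)
    dens = gauss + unif
    if np.any(dens <= 0):
        return -np.inf
    return float(np.sum(np.log(dens)))


def _em_once(
    x: np.ndarray,
    w: float,
    mu: float,
    sigma: float,
    u_lo: float,
    u_hi: float,
    tol: float,
    max_iter: int,
    sigma_floor: float,
):
    """One EM run from a single start; uniform support held fixed."""
    u_dens = 1.0 / (u_hi - u_lo)
    in_support = (x >= u_lo) & (x <= u_hi)
    path = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = w * stats.norm.pdf(x, mu, sigma)
        u = (1.0 - w) * np.where(in_support, u_dens, 0.0)
        dens = g + u
        dens = np.maximum(dens, 1e-300)
        gamma = g / dens
        ll = float(np.sum(np.log(dens)))
        path.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = ll
        # M-step
        s = gamma.sum()
        if s <= 0:
            break
        w = float(np.clip(s / x.size, 1e-12, 1.0 - 1e-12))
        mu = float(np.sum(gamma * x) / s)
        var = float(np.sum(gamma * (x - mu) ** 2) / s)
        sigma = max(np.sqrt(max(var, 0.0)), sigma_floor)
    return (w, mu, sigma), path[-1] if path else -np.inf, np.array(path), it, converged


def fit_mixture_em(
    pixels: PixelSet,
    n_starts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 500,
    nuclear_component: str = "gaussian",
    seed: int = 0,
) -> MixtureFit:
    """EM fit of a Gaussian + uniform mixture to one cell-frame's pixels.

    The closed-form M-step for the uniform support is degenerate (the MLE
    pins it to the data min/max), so EM updates only (w, mu, sigma) with
    the support held fixed: initially at the robust 0.5th/99.5th
    percentiles of all pixels, then refined to the same percentiles of the
    uniform-component responsibility-weighted distribution (two rounds),
    which stops the bright nuclear tail from inflating the background
    support.  The first start is quantile-based (Gaussian centred at the
    90th-percentile intensity); remaining starts are randomized.  The
    best-log-likelihood start wins; the reported log-likelihood path is
    the final EM run's and is non-decreasing.
    """
    x = pixels.intensities
    if x.size < 10:
        raise ValueError("need >= 10 pixels for a mixture fit")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    data_range = float(np.ptp(x))
    sigma_floor = max(SIGMA_FLOOR_FRAC * data_range, 1e-300)

    if data_range == 0.0:
        # Degenerate: all pixels identical; flag not-converged.
        v = float(x[0])
        return MixtureFit(
            w_gauss=1.0, mu=v, sigma=1e-6, u_lo=v - 0.5, u_hi=v + 0.5,
            loglik=np.nan, n_iter=0, converged=False,
            nuclear_signal=v, cytoplasmic_signal=v,
        )

    # The uniform background must cover the dimmest pixels: truncating the
    # low edge orphans them into the Gaussian and inflates sigma.  Only the
    # upper support edge (against the bright nuclear cluster) is searched.
    lo0 = float(np.min(x))

    starts = [(0.3, float(np.percentile(x, 90)), max(np.std(x) / 4, sigma_floor))]
    for _ in range(n_starts - 1):
        starts.append(
            (
                float(rng.uniform(0.05, 0.95)),
                float(rng.uniform(np.percentile(x, 50), np.max(x))),
                float(max(rng.uniform(0.05, 0.5) * np.std(x), sigma_floor)),
            )
        )

    def refine_support(w, mu, sigma, u_lo, u_hi):
        """Re-estimate the support from uniform-responsibility quantiles.

        The responsibility band is extended 5% past the current edge so
        background pixels just outside an underestimated support still
        count toward the refreshed edge estimate.
        """
        u_ext = u_hi + 0.05 * (u_hi - u_lo)
        g = w * stats.norm.pdf(x, mu, sigma)
        u = (1.0 - w) * np.where((x >= u_lo) & (x <= u_ext), 1.0 / (u_hi - u_lo), 0.0)
        resp_u = u / np.maximum(g + u, 1e-300)
        if resp_u.sum() < 1.0:
            return u_lo, u_hi
        order = np.argsort(x)
        cw = np.cumsum(resp_u[order])
        cw = cw / cw[-1]
        q995 = float(np.interp(0.995, cw, x[order]))
        # For a uniform component the 99.5% point sits at
        # lo + 0.995*(hi - lo); invert to estimate the true edge so the
        # brightest background pixels are not orphaned into the Gaussian.
        new_hi = u_lo + (q995 - u_lo) / 0.995
        if new_hi - u_lo <= sigma_floor:
            return u_lo, u_hi
        return u_lo, new_hi

    # The initial uniform support is itself multi-started: if the support
    # spans the bright Gaussian cluster, EM can slide into a broad
    # background-absorbing basin, so candidate upper truncations at several
    # data quantiles are tried and the best final log-likelihood wins (the
    # support is a model parameter; likelihoods are comparable).
    best = None
    for q_hi in (99.5, 95.0, 90.0, 85.0, 80.0, 75.0, 70.0, 65.0, 60.0, 55.0, 50.0):
        hi0 = float(np.percentile(x, q_hi))
        if hi0 <= lo0:
            continue
        for w0, mu0, s0 in starts:
            (w, mu, sigma), ll, path, it, conv = _em_once(
                x, w0, mu0, s0, lo0, hi0, tol, max_iter, sigma_floor
            )
            u_lo, u_hi = lo0, hi0
            for _ in range(3):
                new_lo, new_hi = refine_support(w, mu, sigma, u_lo, u_hi)
                if abs(new_lo - u_lo) < 1e-9 and abs(new_hi - u_hi) < 1e-9:
                    break
                u_lo, u_hi = new_lo, new_hi
                (w, mu, sigma), ll, path, it, conv = _em_once(
                    x, w, mu, sigma, u_lo, u_hi, tol, max_iter, sigma_floor
                )
            if best is None or ll > best[1]:
                best = ((w, mu, sigma, u_lo, u_hi), ll, path, it, conv)
    (w, mu, sigma, u_lo, u_hi), ll, path, it, conv = best

    if nuclear_component == "gaussian":
        nuc = w * mu
        cyto = (u_lo + u_hi) / 2.0
    elif nuclear_component == "uniform":
        nuc = (1.0 - w) * (u_lo + u_hi) / 2.0
        cyto = mu
    else:
        raise ValueError("nuclear_component must be 'gaussian' or 'uniform'")

    return MixtureFit(
        w_gauss=float(w), mu=float(mu), sigma=float(sigma),
        u_lo=float(u_lo), u_hi=float(u_hi), loglik=float(ll),
        n_iter=int(it), converged=bool(conv),
        nuclear_signal=float(nuc), cytoplasmic_signal=float(cyto),
        loglik_path=path,
    )


def _biexp(t: np.ndarray, a1: float, k1: float, a2: float, k2: float) -> np.ndarray:
    return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def _fit_biexp(t: np.ndarray, y: np.ndarray) -> tuple[BleachFit, float]:
    """Least-squares bleach fit with nested mono-exponential model selection.

    Returns the fit and its SSE.  When a bi-exponential gains nothing over a
    mono-exponential (the k1=k2 ridge is unidentifiable), the mono model is
    returned with a2 = 0.
    """
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    scale = float(np.mean(np.abs(y))) or 1.0

    def sse(params, model):
        return float(np.sum((model(t, *params) - y) ** 2))

    # Mono-exponential fit (a, k) over multi-start k.
    def mono(tt, a, k):
        return a * np.exp(-k * tt)

    best_mono = None
    for k0 in (0.0, 0.3 / span, 1.0 / span, 3.0 / span, 10.0 / span):
        try:
            res = optimize.least_squares(
                lambda p: mono(t, *p) - y, x0=[scale, k0],
                bounds=([0.0, 0.0], [np.inf, np.inf]), xtol=1e-14, ftol=1e-14,
            )
        except Exception:
            continue
        if best_mono is None or res.cost < best_mono.cost:
            best_mono = res
    if best_mono is None:
        raise RuntimeError("photobleach fit failed: mono-exponential stage did not converge")

    best_bi = None
    a_m, k_m = best_mono.x
    k_starts = [
        (max(k_m * 3, 1.0 / span), max(k_m / 3, 0.1 / span)),
        (10.0 / span, 1.0 / span),
        (3.0 / span, 0.3 / span),
        (max(k_m, 1e-12), max(k_m / 10, 0.0)),
    ]
    for k1_0, k2_0 in k_starts:
        try:
            res = optimize.least_squares(
                lambda p: _biexp(t, *p) - y,
                x0=[0.7 * scale, k1_0, 0.3 * scale, k2_0],
                bounds=([0.0, 0.0, 0.0, 0.0], [np.inf] * 4),
                xtol=1e-14, ftol=1e-14,
            )
        except Exception:
            continue
        if best_bi is None or res.cost < best_bi.cost:
            best_bi = res

    sse_mono = 2 * best_mono.cost
    use_bi = best_bi is not None and 2 * best_bi.cost < sse_mono * (1 - 1e-9) - 1e-12
    if use_bi:
        a1, k1, a2, k2 = best_bi.x
        if k2 > k1:
            a1, k1, a2, k2 = a2, k2, a1, k1
        sse_val = 2 * best_bi.cost
    else:
        a1, k1, a2, k2 = a_m, k_m, 0.0, 0.0
        sse_val = sse_mono

    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - sse_val / ss_tot if ss_tot > 0 else 1.0
    return BleachFit(float(a1), float(k1), float(a2), float(k2), float(r2)), sse_val


def correct_photobleach(
    traj: Trajectory,
    reference: Trajectory,
    baseline_quantile: float = 0.10,
) -> tuple[Trajectory, BleachFit]:
    """Divide out a bi-exponential bleach trend and renormalize the baseline.

    A bi-exponential is least-squares fitted to the reference trace (the
    GCaMP baseline intensity, or the Crz1 expected cytoplasmic signal), the
    trajectory is divided by the fitted factor normalized to 1 at t=0, and
    the result is shifted so that its ``baseline_quantile`` (default 10th
    percentile, robust to pulses occupying a minority of frames) is 0.
    """
    if reference.times.shape != traj.times.shape or not np.allclose(
        reference.times, traj.times
    ):
        raise ValueError("reference must share the trajectory's time grid")
    if np.any(reference.values <= 0):
        raise ValueError("reference values must be > 0 for bleach regression")

    t = traj.times - traj.times[0]
    fit, _ = _fit_biexp(t, reference.values)
    b0 = _biexp(np.array([0.0]), fit.a1, fit.k1, fit.a2, fit.k2)[0]
    if b0 <= 0:
        raise RuntimeError("photobleach fit degenerate: factor(0) <= 0")
    factor = _biexp(t, fit.a1, fit.k1, fit.a2, fit.k2) / b0
    corrected = traj.values / factor
    corrected = corrected - np.quantile(corrected, baseline_quantile)
    return traj.with_values(corrected), fit


def read_pixel_tiff(image_path, mask_path) -> list[PixelSet]:
    """Extract per-cell PixelSets from a single-frame TIFF + integer-label mask.

    Label 0 is background; each positive label is one cell.
    """
    import tifffile

    img = tifffile.imread(image_path).astype(float)
    mask = tifffile.imread(mask_path)
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    out = []
    for label in np.unique(mask):
        if label == 0:
            continue
        vals = img[mask == label]
        out.append(PixelSet(intensities=vals, cell_id=str(int(label))))
    return out
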