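"""Event statistics linking calcium bursts to Crz1 pulse trains.

Implements the burst/pulse pairing rules (pulses after a burst are counted
until the next burst or the record end; pulses before until the previous
burst or the record start), randomized-cell controls, Welch t / F
comparisons of offset distributions with Bonferroni correction, the
10-minute following-interval filter, the Poisson GLM of pulse count on
ln(burst height), the residual-on-interval control analysis, burst-height
group tables, and a population-synchrony decay metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .detect import Burst, Pulse
from .trajectory import Trajectory

__all__ = [
    "EventPairing",
    "CountRecord",
    "GlmFit",
    "OffsetComparison",
    "BONFERRONI_ALPHA",
    "pair_events",
    "randomized_control",
    "compare_offsets",
    "count_and_filter",
    "poisson_glm",
    "residual_control",
    "height_groups",
    "synchrony_decay",
]

# Bonferroni family of 16 comparisons: 0.05 / 16 = 0.003125.
BONFERRONI_ALPHA = 0.05 / 16


@dataclass
class EventPairing:
    """One calcium burst with its ordinal-labelled flanking Crz1 pulses.

    ``offsets_after`` are positive times (s) from the burst to each following
    pulse up to the next burst or record end, ordinals 1, 2, ...;
    ``offsets_before`` are negative times to each preceding pulse back to
    the previous burst or record start, nearest first.
    """

    cell_id: str
    burst_time: float
    burst_height: float
    offsets_after: list[float]
    offsets_before: list[float]
    following_interval_sec: float
    preceding_interval_sec: float

    @property
    def n_after(self) -> int:
        return len(self.offsets_after)

    @property
    def n_before(self) -> int:
        return len(self.offsets_before)


@dataclass(frozen=True)
class CountRecord:
    """Per-burst pulse counts used in the count-vs-height regressions."""

    burst_height: float
    ln_height: float
    n_pulses_after: int
    n_pulses_before: int
    following_interval_sec: float
    preceding_interval_sec: float


@dataclass(frozen=True)
class GlmFit:
    """Poisson GLM slope estimate with Wald inference."""

    slope: float
    slope_se: float
    intercept: float
    p_value: float
    n: int

    def summary(self) -> str:
        return (
            f"Poisson GLM (log link), n={self.n}: slope={self.slope:.4f} "
            f"+- {self.slope_se:.4f} (Wald p={self.p_value:.3g}), "
            f"intercept={self.intercept:.4f}"
        )


@dataclass(frozen=True)
class OffsetComparison:
    """Welch t-test on means and F-test on variances, matched vs control."""

    mean_matched: float
    mean_control: float
    sd_matched: float
    sd_control: float
    t_stat: float
    t_p: float
    f_stat: float
    f_p: float
    n_matched: int
    n_control: int
    alpha: float = BONFERRONI_ALPHA

    @property
    def mean_significant(self) -> bool:
        return self.t_p < self.alpha

    @property
    def sd_significant(self) -> bool:
        return self.f_p < self.alpha


def _pair_one_cell(
    bursts: Sequence[Burst],
    pulses: Sequence[Pulse],
    record_start: float,
    record_end: float,
) -> list[EventPairing]:
    bt = sorted(bursts, key=lambda b: b.time_sec)
    pt = np.array(sorted(p.time_sec for p in pulses))
    out = []
    for i, b in enumerate(bt):
        prev_t = bt[i - 1].time_sec if i > 0 else record_start
        next_t = bt[i + 1].time_sec if i + 1 < len(bt) else record_end
        after = pt[(pt > b.time_sec) & (pt <= next_t)]
        before = pt[(pt < b.time_sec) & (pt >= prev_t)]
        out.append(
            EventPairing(
                cell_id=b.cell_id,
                burst_time=b.time_sec,
                burst_height=b.height,
                offsets_after=[float(t - b.time_sec) for t in after],
                offsets_before=[float(t - b.time_sec) for t in before[::-1]],
                following_interval_sec=float(next_t - b.time_sec),
                preceding_interval_sec=float(b.time_sec - prev_t),
            )
        )
    return out


def pair_events(
    bursts: Sequence[Burst],
    pulses: Sequence[Pulse],
    record_spans: Mapping[str, tuple[float, float]],
) -> list[EventPairing]:
    """Pair each burst with its flanking Crz1 pulses, per cell.

    ``record_spans`` maps cell_id to (record start, record end) in seconds.
    Every pulse contributes to at most one burst's after-list and one
    burst's before-list (pairing stops at the flanking burst).
    """
    cells_b = {b.cell_id for b in bursts}
    cells_p = {p.cell_id for p in pulses}
    unknown = (cells_b | cells_p) - set(record_spans)
    if unknown:
        raise ValueError(f"events reference cells without record spans: {sorted(unknown)}")
    out: list[EventPairing] = []
    for cell in sorted(cells_b):
        cb = [b for b in bursts if b.cell_id == cell]
        cp = [p for p in pulses if p.cell_id == cell]
        start, end = record_spans[cell]
        out.extend(_pair_one_cell(cb, cp, start, end))
    return out


def randomized_control(
    bursts: Sequence[Burst],
    pulses: Sequence[Pulse],
    record_spans: Mapping[str, tuple[float, float]],
    seed: int = 0,
) -> list[EventPairing]:
    """Pair each burst's time against a randomly chosen *different* cell.

    The burst time is applied to another cell's Crz1 pulse sequence (which
    may or may not contain calcium bursts of its own) under the same
    stop-at-flanking-burst rule, using that cell's bursts and record span.
    Cells are assigned by a seeded permutation (without replacement,
    cycling when there are more bursts than other cells).
    """
    cells = sorted(record_spans)
    if len(cells) < 2:
        raise ValueError("randomized control needs >= 2 cells")
    rng = np.random.default_rng(seed)
    bursts_by_cell = {c: sorted((b for b in bursts if b.cell_id == c), key=lambda b: b.time_sec) for c in cells}
    pulses_by_cell = {c: [p for p in pulses if p.cell_id == c] for c in cells}

    out: list[EventPairing] = []
    perm: list[str] = []
    for b in sorted(bursts, key=lambda x: (x.cell_id, x.time_sec)):
        if not perm:
            perm = [cells[i] for i in rng.permutation(len(cells))]
        target = perm.pop()
        if target == b.cell_id:
            # swap with another assignment to avoid self-pairing
            if perm:
                perm.append(target)
                target = perm.pop(0)
            else:
                target = cells[(cells.index(b.cell_id) + 1) % len(cells)]
        start, end = record_spans[target]
        t = float(np.clip(b.time_sec, start, end))
        tb = bursts_by_cell[target]
        prev_t = max([x.time_sec for x in tb if x.time_sec < t], default=start)
        next_t = min([x.time_sec for x in tb if x.time_sec > t], default=end)
        pt = np.array(sorted(p.time_sec for p in pulses_by_cell[target]))
        after = pt[(pt > t) & (pt <= next_t)]
        before = pt[(pt < t) & (pt >= prev_t)]
        out.append(
            EventPairing(
                cell_id=target,
                burst_time=t,
                burst_height=b.height,
                offsets_after=[float(x - t) for x in after],
                offsets_before=[float(x - t) for x in before[::-1]],
                following_interval_sec=float(next_t - t),
                preceding_interval_sec=float(t - prev_t),
            )
        )
    return out


def compare_offsets(
    matched: Sequence[float],
    control: Sequence[float],
    alpha: float = BONFERRONI_ALPHA,
) -> OffsetComparison:
    """Welch t-test on means and two-tailed F-test on variances."""
    m = np.asarray(matched, float)
    c = np.asarray(control, float)
    if m.size < 3 or c.size < 3:
        raise ValueError("need >= 3 offsets per group")
    if m.std(ddof=1) == 0 or c.std(ddof=1) == 0:
        raise ValueError("zero variance in an offset group")
    t_stat, t_p = sps.ttest_ind(m, c, equal_var=False)
    f = float(m.var(ddof=1) / c.var(ddof=1))
    df1, df2 = m.size - 1, c.size - 1
    cdf = sps.f.cdf(f, df1, df2)
    f_p = float(2 * min(cdf, 1 - cdf))
    return OffsetComparison(
        mean_matched=float(m.mean()), mean_control=float(c.mean()),
        sd_matched=float(m.std(ddof=1)), sd_control=float(c.std(ddof=1)),
        t_stat=float(t_stat), t_p=float(t_p), f_stat=f, f_p=f_p,
        n_matched=int(m.size), n_control=int(c.size), alpha=alpha,
    )


def count_and_filter(
    pairings: Sequence[EventPairing], min_interval_sec: float = 600.0
) -> list[CountRecord]:
    """Pulse-count records for bursts whose following interval is >= 10 min.

    Short following intervals can hide pulses behind the next burst, so
    those bursts are excluded from the count-vs-height analysis.
    """
    out = []
    for p in pairings:
        if p.following_interval_sec < min_interval_sec:
            continue
        if p.burst_height <= 0:
            continue
        out.append(
            CountRecord(
                burst_height=p.burst_height,
                ln_height=float(np.log(p.burst_height)),
                n_pulses_after=p.n_after,
                n_pulses_before=p.n_before,
                following_interval_sec=p.following_interval_sec,
                preceding_interval_sec=p.preceding_interval_sec,
            )
        )
    return out


def poisson_glm(x: Sequence[float], counts: Sequence[int]) -> GlmFit:
    """Poisson regression (log link) of counts on a single regressor.

    Fitted by iteratively reweighted least squares; the slope p-value is a
    Wald test against 0.
    """
    import statsmodels.api as sm

    x = np.asarray(x, float)
    y = np.asarray(counts, float)
    if x.size < 3:
        raise ValueError("need >= 3 records")
    if np.ptp(x) == 0:
        raise ValueError("regressor has zero variance")
    if np.all(y == 0):
        raise ValueError("all counts are zero; Poisson GLM is not identified")
    X = sm.add_constant(x)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        res = model.fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # pragma: no cover - propagated as spec'd error
        raise RuntimeError(f"Poisson GLM did not converge: {exc}") from exc
    if not res.converged:
        raise RuntimeError("Poisson GLM did not converge in 100 IRLS iterations")
    return GlmFit(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        p_value=float(res.pvalues[1]),
        n=int(x.size),
    )


def glm_count_on_height(records: Sequence[CountRecord], side: str = "after") -> GlmFit:
    """Poisson GLM of pulse count (after or before bursts) on ln height."""
    x = [r.ln_height for r in records]
    y = [r.n_pulses_after if side == "after" else r.n_pulses_before for r in records]
    return poisson_glm(x, y)


def residual_control(records: Sequence[CountRecord]) -> dict:
    """Interval-controlled height effect on pulse counts.

    Counts are first regressed (OLS) on the flanking interval length; the
    residuals are then regressed on burst height.  A genuine causal effect
    of burst size shows up in the after-burst residual slope but not the
    before-burst one.
    """
    if len(records) < 4:
        raise ValueError("need >= 4 records")
    h = np.array([r.burst_height for r in records])
    if np.ptp(h) == 0:
        raise ValueError("degenerate: heights have no variance")
    out = {}
    for side in ("after", "before"):
        y = np.array(
            [r.n_pulses_after if side == "after" else r.n_pulses_before for r in records],
            float,
        )
        iv = np.array(
            [
                r.following_interval_sec if side == "after" else r.preceding_interval_sec
                for r in records
            ],
            float,
        )
        if np.ptp(iv) == 0:
            resid = y - y.mean()
        else:
            fit = sps.linregress(iv, y)
            resid = y - (fit.intercept + fit.slope * iv)
        res = sps.linregress(h, resid)
        out[side] = {"slope": float(res.slope), "p_value": float(res.pvalue)}
    return out


def height_groups(records: Sequence[CountRecord], edges: Sequence[float]) -> list[dict]:
    """Per-height-group pulse-count distributions with Poisson-theory CIs.

    ``edges`` are increasing interior bin edges on burst height; groups are
    (-inf, e1], (e1, e2], ..., (ek, inf).  Each group reports the empirical
    count probabilities, the mean count, and mean +- 1.96*sqrt(N)/m where N
    is the total count over the group's m records.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be increasing")
    bounds = [-np.inf] + edges + [np.inf]
    groups = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sub = [r for r in records if lo < r.burst_height <= hi]
        counts = np.array([r.n_pulses_after for r in sub], int)
        if sub:
            m = counts.size
            total = int(counts.sum())
            mean = total / m
            half = 1.96 * np.sqrt(total) / m
            probs = {int(k): float(np.mean(counts == k)) for k in np.unique(counts)}
            mean_height = float(np.mean([r.burst_height for r in sub]))
        else:
            mean = half = np.nan
            probs = {}
            mean_height = np.nan
        groups.append(
            {
                "height_range": (float(lo), float(hi)),
                "n": len(sub),
                "mean_height": mean_height,
                "mean_count": float(mean) if sub else np.nan,
                "ci_half_width": float(half) if sub else np.nan,
                "count_probs": probs,
            }
        )
    return groups


def synchrony_decay(
    trajs: Sequence[Trajectory],
    event_time: float,
    window_sec: float = 240.0,
):
    """Amplitude envelope of the population-mean trace after a shared event.

    Cells synchronized by a common calcium burst pulse together at first;
    as their periods drift apart the population-mean oscillation flattens.
    The envelope is the rolling peak-to-trough amplitude of the mean trace
    over windows of ``window_sec``.

    Returns ``(window_center_times, envelope)``.
    """
    if len(trajs) < 5:
        raise ValueError("need >= 5 cells")
    ref = trajs[0]
    post = ref.times[ref.times >= event_time]
    if post.size < 3:
        raise ValueError("no post-event support")
    stack = np.vstack([np.interp(post, t.times, t.values) for t in trajs])
    mean = stack.mean(axis=0)
    dt = float(post[1] - post[0])
    w = max(2, int(round(window_sec / dt)))
    centers, env = [], []
    for i in range(0, mean.size - w + 1):
        seg = mean[i : i + w]
        centers.append(post[i] + dt * (w - 1) / 2)
        env.append(float(seg.max() - seg.min()))
    return np.array(centers), np.array(env)
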