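"""Burst/pulse pairing, randomized controls, counting, GLM and synchrony."""

import numpy as np
import pytest
from scipy import stats as sps

from crzpulse.detect import Burst, Pulse
from crzpulse.stats import (
    BONFERRONI_ALPHA,
    CountRecord,
    compare_offsets,
    count_and_filter,
    glm_count_on_height,
    height_groups,
    pair_events,
    poisson_glm,
    randomized_control,
    residual_control,
    synchrony_decay,
)
from crzpulse.trajectory import Trajectory


def _burst(cell, t, h=1.0):
    return Burst(cell, t, h, h, 0.0, 0.0)


def _pulse(cell, t):
    return Pulse(cell, "crz1", t, 0.5, 0.5)


class TestPairEvents:
    def test_offsets_and_ordinals_after_single_burst(self):
        spans = {"c": (0.0, 900.0)}
        pairs = pair_events([_burst("c", 100.0)], [_pulse("c", 160.0), _pulse("c", 400.0)], spans)
        assert len(pairs) == 1
        assert pairs[0].offsets_after == [60.0, 300.0]
        assert pairs[0].following_interval_sec == 800.0

    def test_pulse_before_burst_gets_negative_offset(self):
        spans = {"c": (0.0, 900.0)}
        pairs = pair_events([_burst("c", 100.0)], [_pulse("c", 50.0)], spans)
        assert pairs[0].offsets_before == [-50.0]
        assert pairs[0].offsets_after == []

    def test_pulse_after_next_burst_belongs_to_that_burst_only(self):
        spans = {"c": (0.0, 900.0)}
        pairs = pair_events(
            [_burst("c", 100.0), _burst("c", 300.0)], [_pulse("c", 350.0)], spans
        )
        assert pairs[0].offsets_after == []  # stop at the flanking burst
        assert pairs[1].offsets_after == [50.0]

    def test_counting_conservation(self):
        # every pulse lands in at most one after-list and one before-list
        rng = np.random.default_rng(0)
        bursts = [_burst("c", float(t)) for t in sorted(rng.uniform(0, 3600, 12))]
        pulses = [_pulse("c", float(t)) for t in sorted(rng.uniform(0, 3600, 40))]
        pairs = pair_events(bursts, pulses, {"c": (0.0, 3600.0)})
        n_after = sum(p.n_after for p in pairs)
        n_before = sum(p.n_before for p in pairs)
        assert n_after <= 40 and n_before <= 40
        all_after = sorted(t for p in pairs for t in np.array(p.offsets_after) + p.burst_time)
        assert len(all_after) == len(set(all_after))

    def test_unknown_cell_rejected(self):
        with pytest.raises(ValueError):
            pair_events([_burst("a", 1.0)], [], {"b": (0.0, 10.0)})


class TestRandomizedControl:
    def _identical_cells(self, n=6):
        bursts, pulses, spans = [], [], {}
        for i in range(n):
            c = f"c{i}"
            bursts.append(_burst(c, 500.0))
            pulses.extend([_pulse(c, 600.0), _pulse(c, 800.0)])
            spans[c] = (0.0, 2000.0)
        return bursts, pulses, spans

    def test_identical_cells_give_identical_offset_distribution(self):
        bursts, pulses, spans = self._identical_cells()
        matched = pair_events(bursts, pulses, spans)
        control = randomized_control(bursts, pulses, spans, seed=1)
        m = sorted(o for p in matched for o in p.offsets_after)
        c = sorted(o for p in control for o in p.offsets_after)
        assert m == c

    def test_seed_determinism(self):
        bursts, pulses, spans = self._identical_cells()
        a = randomized_control(bursts, pulses, spans, seed=9)
        b = randomized_control(bursts, pulses, spans, seed=9)
        assert [p.cell_id for p in a] == [p.cell_id for p in b]

    def test_never_pairs_with_own_cell(self):
        bursts, pulses, spans = self._identical_cells()
        for seed in range(20):
            ctrl = randomized_control(bursts, pulses, spans, seed=seed)
            for orig, c in zip(sorted(bursts, key=lambda b: (b.cell_id, b.time_sec)), ctrl):
                assert c.cell_id != orig.cell_id

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            randomized_control([_burst("a", 1.0)], [], {"a": (0.0, 10.0)}, seed=0)

    def test_coupling_shrinks_matched_offset_spread(self, coupled_cells):
        # With true burst->pulse coupling, matched first-pulse offsets are
        # tighter than randomized-cell offsets in most replicates.
        bursts, pulses, spans = [], [], {}
        for c in coupled_cells:
            cell = c["ca"].cell_id
            spans[cell] = (0.0, float(c["ca"].times[-1]))
            for b in c["bursts"]:
                bursts.append(_burst(cell, b.time_sec, b.height))
            for p in c["pulses"]:
                pulses.append(_pulse(cell, p.time_sec))
        matched = pair_events(bursts, pulses, spans)
        m = [p.offsets_after[0] for p in matched if p.offsets_after]
        wins = 0
        reps = 30
        for seed in range(reps):
            ctrl = randomized_control(bursts, pulses, spans, seed=seed)
            c = [p.offsets_after[0] for p in ctrl if p.offsets_after]
            if np.std(m) < np.std(c):
                wins += 1
        assert wins / reps >= 0.9


class TestCompareOffsets:
    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = compare_offsets(x, x)
        assert res.t_stat == pytest.approx(0.0)
        assert res.f_stat == pytest.approx(1.0)
        assert not res.mean_significant

    def test_variance_difference_detected_with_power(self):
        rng = np.random.default_rng(0)
        hits = 0
        sims = 300
        for _ in range(sims):
            a = rng.normal(0, 1, 200)
            b = rng.normal(0, 2, 200)
            res = compare_offsets(a, b)
            hits += res.f_p < BONFERRONI_ALPHA
        assert hits / sims >= 0.90

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_offsets([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCountAndFilter:
    def _pairing(self, interval, n_after):
        from crzpulse.stats import EventPairing

        return EventPairing(
            cell_id="c", burst_time=0.0, burst_height=1.0,
            offsets_after=[60.0 * (i + 1) for i in range(n_after)],
            offsets_before=[], following_interval_sec=interval,
            preceding_interval_sec=100.0,
        )

    def test_short_interval_excluded(self):
        assert count_and_filter([self._pairing(500.0, 2)]) == []

    def test_long_interval_kept_with_count(self):
        recs = count_and_filter([self._pairing(700.0, 3)])
        assert len(recs) == 1
        assert recs[0].n_pulses_after == 3

    def test_all_short_gives_empty(self):
        assert count_and_filter([self._pairing(100.0, 1)] * 5) == []


class TestPoissonGlm:
    def test_equal_counts_give_zero_slope(self):
        fit = poisson_glm([0.0, 1.0, 2.0, 3.0], [2, 2, 2, 2])
        assert abs(fit.slope) < 1e-8

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            poisson_glm([0.0, 1.0, 2.0], [0, 0, 0])

    def test_matches_brute_force_likelihood_maximum(self):
        # Independent oracle: direct maximization of the Poisson
        # log-likelihood over (intercept, slope) by grid + simplex refine.
        instances = [
            ([0.0, 0.5, 1.0, 1.5], [1, 2, 2, 4]),
            ([-1.0, 0.0, 1.0, 2.0], [0, 1, 3, 5]),
            ([0.2, 0.4, 0.9, 1.4, 2.0], [1, 1, 2, 2, 3]),
            ([0.0, 1.0, 2.0, 3.0, 4.0, 5.0], [1, 1, 2, 4, 5, 9]),
        ]
        from scipy.optimize import minimize

        for x, y in instances:
            x_arr, y_arr = np.array(x), np.array(y, float)

            def nll(params):
                eta = params[0] + params[1] * x_arr
                return -np.sum(y_arr * eta - np.exp(eta))

            best = None
            for b0 in np.linspace(-3, 3, 13):
                for b1 in np.linspace(-3, 3, 13):
                    res = minimize(nll, [b0, b1], method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12})
                    if best is None or res.fun < best.fun:
                        best = res
            fit = poisson_glm(x, y)
            assert fit.intercept == pytest.approx(best.x[0], abs=1e-6)
            assert fit.slope == pytest.approx(best.x[1], abs=1e-6)

    def test_slope_recovery_from_generator(self, coupled_cells):
        # Generator law: pulses ~ Poisson(exp(ln2 + 0.3 ln h)); the GLM on
        # ground-truth counts must recover the slope within 2 SE.
        xs, ys = [], []
        for c in coupled_cells:
            bursts = sorted(c["bursts"], key=lambda b: b.time_sec)
            for i, b in enumerate(bursts):
                nxt = bursts[i + 1].time_sec if i + 1 < len(bursts) else c["ca"].times[-1]
                if nxt - b.time_sec < 600.0:
                    continue
                n = sum(1 for p in c["pulses"] if p.burst_index == i and not p.truncated)
                if any(p.burst_index == i and p.truncated for p in c["pulses"]):
                    continue
                xs.append(np.log(b.height))
                ys.append(n)
        fit = poisson_glm(xs, ys)
        assert abs(fit.slope - 0.3) < 2 * fit.slope_se


class TestResidualControl:
    def _records(self, rng, n, height_effect_after=0.0):
        recs = []
        for _ in range(n):
            h = float(np.exp(rng.uniform(-1, 2)))
            f_iv = float(rng.uniform(600, 3000))
            p_iv = float(rng.uniform(600, 3000))
            lam_a = 0.002 * f_iv + height_effect_after * np.log(h) + 0.5
            n_a = int(rng.poisson(max(lam_a, 0.01)))
            n_b = int(rng.poisson(0.002 * p_iv + 0.5))
            recs.append(CountRecord(h, float(np.log(h)), n_a, n_b, f_iv, p_iv))
        return recs

    def test_interval_only_counts_give_null_after_slope(self):
        rng = np.random.default_rng(0)
        ps = []
        for rep in range(50):
            recs = self._records(rng, 120, height_effect_after=0.0)
            ps.append(residual_control(recs)["after"]["p_value"])
        # null p-values should not pile up at the low end
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_after_effect_detected_before_effect_absent(self):
        rng = np.random.default_rng(1)
        hits_after, cover_before = 0, 0
        reps = 40
        for _ in range(reps):
            recs = self._records(rng, 150, height_effect_after=0.8)
            out = residual_control(recs)
            hits_after += out["after"]["slope"] > 0 and out["after"]["p_value"] < 0.05
            cover_before += out["before"]["p_value"] > 0.05
        assert hits_after / reps >= 0.9
        assert cover_before / reps >= 0.8

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(300):
            recs = self._records(rng, 60, height_effect_after=0.0)
            ps.append(residual_control(recs)["after"]["p_value"])
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestHeightGroups:
    def _recs(self, heights, counts):
        return [
            CountRecord(h, float(np.log(h)), c, 0, 700.0, 700.0)
            for h, c in zip(heights, counts)
        ]

    def test_single_occupied_group(self):
        groups = height_groups(self._recs([0.5, 0.6], [1, 2]), edges=[1.0, 2.0])
        assert groups[0]["n"] == 2
        assert groups[1]["n"] == 0 and groups[2]["n"] == 0

    def test_poisson_ci_formula(self):
        recs = self._recs([0.5, 0.5, 0.5, 0.5], [2, 3, 1, 2])
        g = height_groups(recs, edges=[1.0])[0]
        total, m = 8, 4
        assert g["mean_count"] == pytest.approx(total / m)
        assert g["ci_half_width"] == pytest.approx(1.96 * np.sqrt(total) / m)

    def test_group_means_increase_with_generator_slope(self):
        rng = np.random.default_rng(3)
        wins, reps = 0, 50
        for _ in range(reps):
            hs = np.exp(rng.uniform(-1.5, 1.5, 150))
            cs = rng.poisson(np.exp(np.log(2) + 0.5 * np.log(hs)))
            groups = height_groups(self._recs(hs, cs), edges=[0.5, 1.5])
            means = [g["mean_count"] for g in groups if g["n"] > 0]
            if all(b > a for a, b in zip(means, means[1:])):
                wins += 1
        assert wins / reps >= 0.8

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            height_groups([], edges=[2.0, 1.0])


class TestSynchronyDecay:
    def _cells(self, periods, n=400, dt=30.0):
        out = []
        for i, T in enumerate(periods):
            t = np.arange(n) * dt
            v = np.cos(2 * np.pi * t / T)
            out.append(Trajectory(f"c{i}", "crz1", t, v))
        return out

    def test_identical_periodic_traces_keep_constant_envelope(self):
        trajs = self._cells([300.0] * 6)
        _, env = synchrony_decay(trajs, event_time=0.0, window_sec=300.0)
        assert np.ptp(env) < 0.05 * env[0]

    def test_period_jitter_decays_the_envelope(self):
        rng = np.random.default_rng(0)
        trajs = self._cells(rng.normal(300.0, 25.0, 12))
        t, env = synchrony_decay(trajs, event_time=0.0, window_sec=300.0)
        # envelope keeps shrinking over the dephasing epoch (fixed-period
        # cells eventually re-cohere by beating, so only the initial decay
        # is asserted)
        i2 = np.searchsorted(t, 600.0)
        i4 = np.searchsorted(t, 1200.0)
        i6 = np.searchsorted(t, 1800.0)
        assert env[i4] < env[i2]
        assert env[i6] < env[i4]

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            synchrony_decay(self._cells([300.0] * 3), 0.0)
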