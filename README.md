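# crzpulse

Single-cell analysis of how stochastic cytosolic calcium bursts drive
pulses of nuclear localization of the transcription factor Crz1 in
budding yeast — and a stochastic time-delay model of the conversion.

Under constant calcium stress, cytosolic calcium shows stochastic bursts
on the 10–100 s scale, each followed by an overshoot below the resting
level whose depth grows with ln(burst height).  One burst can trigger
several discrete Crz1 nuclear-localization pulses, and the number of
pulses rises with the burst's height: the pathway behaves like a noisy
analog-to-digital converter.  This package implements the full analysis
chain for dual-reporter time-lapse data and the mechanistic model that
explains it:

- **quantify** — GCaMP calcium signal (mean pixel intensity) and Crz1
  nuclear/cytoplasmic signals from an expectation-maximization fit of a
  Gaussian + uniform pixel-intensity mixture; bi-exponential
  photobleaching correction and baseline-0 normalization.
- **detect** — Savitzky–Golay smoothing, control-derived thresholds
  (calcium height 0.09 = top 0.5% of control peaks; Crz1 height 0.30 and
  prominence 0.15 = top 5%), greedy peak selection with 60 s minimum
  separation, overshoot-depth annotation, pulse-triggered averaging and
  cross-correlation.
- **stats** — burst/pulse pairing with randomized-cell controls (Welch t
  and F tests, Bonferroni α = 0.0031), the 10-min interval filter,
  Poisson GLM of pulse count on ln height, residual-on-interval controls,
  height-group tables, and a population-synchrony decay metric.
- **tdm** — the discrete-time stochastic time-delay model (TDM): 500 Crz1
  molecules with multistage (Gamma-like) nuclear import/export delays
  driven by calcineurin activity
  `ΔCn = (Cn_base − Cn)·D + max(0, Ca)·A`, plus the conformational-switch
  comparator (CSM), a steep Hill readout of threshold crossings.
- **shape / periodicity** — logistic-pulse fits (height h, narrowness r
  per pulse) and a Gaussian-process periodic-vs-aperiodic log-likelihood
  ratio (LLR).
- **synthetic** — seeded generators for every input (calcium bursts with
  overshoots, Crz1 pulse trains, pixel sets, photobleaching) with full
  ground truth, so the whole pipeline is testable without any download.

## Worked example

```python
import numpy as np
from crzpulse import (
    SynthCalciumSpec, gen_calcium, detect_events, ThresholdSpec,
    overshoot_regression, TDMParams, simulate_tdm, poisson_glm,
)

# A cell with stochastic calcium bursts (ground truth retained)
traj, truth = gen_calcium(SynthCalciumSpec(duration_sec=3600, seed=2))
bursts = detect_events(traj, ThresholdSpec())
print(len(truth), len(bursts))                 # 6 6
slope, intercept, r2 = overshoot_regression(bursts)
print(round(slope, 3))                         # 0.202

# Drive the time-delay model with synthetic single-burst records and
# regress predicted pulse count on ln(burst height)
rng, xs, ys = np.random.default_rng(0), [], []
from crzpulse.tdm import _single_burst_trajectory
for i in range(60):
    h = float(np.exp(rng.uniform(np.log(0.08), np.log(8.0))))
    sim = simulate_tdm(_single_burst_trajectory(h), TDMParams(seed=i))
    xs.append(np.log(h)); ys.append(len(detect_events(sim.trajectory)))
print(poisson_glm(xs, ys).summary())
# Poisson GLM (log link), n=60: slope=0.2191 +- 0.0660 (Wald p=0.000892),
# intercept=0.8106
```

The detected overshoot-depth slope (0.202 against a generator law of
0.10, from only 6 noisy detected bursts) recovers the depth–ln(height)
relationship's direction, and the positive GLM slope is the noisy
analog-to-digital property: each e-fold of burst height buys, on
average, a fixed increment in expected Crz1 pulse count.

A command-line interface drives the same stages on CSV artifacts:

```bash
crzpulse generate --out run1 --seed 7 --n-cells 20
crzpulse detect --traj run1/trajectories.csv --out run1/events.csv
crzpulse analyze --out run1
crzpulse run-all --config examples/demo.yaml
```

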