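# Methods

`crzpulse` analyses the coupling between stochastic cytosolic calcium
bursts and pulses of nuclear localization of the transcription factor Crz1
in budding yeast under constant calcium stress, and simulates the
stochastic time-delay model that explains how a burst's analog height is
converted into a noisy digital number of Crz1 pulses.  This note records
the models, the parameter choices, the numerical decisions, and what the
synthetic study conditions do and do not establish.

## Signals and quantification

Two fluorescence channels are analysed per cell: a cytosolic calcium
indicator (GCaMP-type, sampled every 6 s) and a Crz1 fusion reporter
(sampled every 30 s).  The calcium signal is the mean pixel intensity over
the cell.  The Crz1 nuclear signal comes from a two-component mixture
fitted to each cell-frame's pixel intensities: a Gaussian for the compact
bright nuclear pixel population and a uniform distribution for the spread
cytoplasmic background.  The nuclear signal is `w·mu` (weighted expected
intensity of the Gaussian) and the cytoplasmic signal `(u_lo+u_hi)/2`;
the role assignment is configurable (`nuclear_component="uniform"` swaps
it) because with a dim nucleus the geometry could invert.

The mixture is fitted by expectation-maximization over `(w, mu, sigma)`
with the uniform support held fixed within each EM run: the closed-form
M-step for the support is degenerate (the MLE pins it to the data
extremes).  The lower support edge is the data minimum — the background
must cover the dimmest pixels, otherwise they are orphaned into the
Gaussian and inflate `sigma`.  The upper edge is searched: candidate
truncations at eleven data quantiles (99.5% down to 50%) are each run
through EM (quantile-based start plus four randomized restarts, tolerance
1e-8 relative log-likelihood, at most 500 iterations, `sigma` floored at
1e-6 of the data range), the edge is then refined twice from the uniform
component's responsibility-weighted 99.5% quantile with an inverse-0.995
extrapolation to the full support, and the overall best final
log-likelihood wins.  The support is a model parameter, so likelihoods
across candidates are directly comparable.  Within each EM run the
log-likelihood is non-decreasing and the final run's path is reported.

Photobleaching is corrected by dividing out a bi-exponential
`a1·exp(-k1 t) + a2·exp(-k2 t)` least-squares fitted to a reference trace
(the calcium baseline, or the Crz1 expected cytoplasmic signal),
normalized to 1 at t = 0.  The fit is multi-started over decay-rate
scales, and an explicit nested-model comparison collapses to a
mono-exponential when the second component buys nothing — on
mono-exponential references the `k1 = k2` ridge is unidentifiable and the
collapse makes `a2 = 0` well-defined.  After correction the trace is
shifted so its 10th percentile is 0; the 10th percentile is robust to
pulses occupying a minority of frames, which a mean or median is not.

## Detection

Trajectories are Savitzky-Golay smoothed (window 5 frames, order 2 — the
smallest odd window that suppresses fluctuations shorter than about four
time points).  Detection thresholds derive from negative-control records
(cells without added calcium): every local maximum with 60 s minimum
separation is pooled, and the calcium height threshold is the 99.5th
percentile of control calcium peak heights (published value 0.09), while
Crz1 uses the 95th percentiles of control peak heights (0.30) and
topographic prominences (0.15).  Percentiles interpolate linearly between
order statistics.  Candidate maxima above threshold are kept greedily
highest-first subject to the 60 s separation, with ties broken toward the
earlier peak.

Each calcium burst is annotated with its overshoot depth — the magnitude
of the most negative smoothed value between the apex and the next burst,
capped at 300 s (the dip bottoms out around 100 s after the apex) and
clipped at zero.  Depth regressed on ln(height) by OLS quantifies the
channel-driven undershoot.

## Event statistics

Per cell, Crz1 pulses after a burst are assigned to it up to the next
burst or the record end; pulses before a burst symmetrically.  The
matched distribution of burst-to-first-pulse offsets is compared against
a randomized-cell control: each burst's time is applied to a different
cell's pulse sequence (seeded permutation without replacement, cycling
when bursts outnumber cells), under the same stop-at-flanking-burst rule
evaluated with the target cell's own bursts — so identical cells give
identical matched and control distributions exactly.  Means are compared
by Welch's t-test (group variances demonstrably differ) and spreads by a
two-tailed F-test, with Bonferroni correction for a family of 16
comparisons (alpha = 0.05/16 = 0.003125).

For the count-vs-height analysis, bursts whose following interval is
shorter than 10 minutes are discarded (short intervals censor the pulse
train), and the remaining counts are regressed on ln(burst height) by a
Poisson GLM with log link (IRLS, via statsmodels).  ln rather than raw
height is used because burst heights span decades and all height analyses
in this pipeline live on the natural-log scale.  A residual control
regresses counts on interval length first and the residuals on height,
separating the height effect from interval censoring; the same machinery
applied to pre-burst counts is the negative control.  Burst-height groups
report empirical count distributions with Poisson-theory confidence
intervals (mean ± 1.96·√N/m for total count N over m bursts).

Population synchrony after a shared event is summarized by the rolling
peak-to-trough amplitude of the across-cell mean Crz1 trace (window one
oscillation period); dephasing cells flatten the mean and shrink the
envelope.

## The time-delay model (TDM)

Calcineurin activity follows the discrete-time relaxation

    Cn(t+1) − Cn(t) = (Cn_base − Cn(t))·D + max(0, Ca(t))·A,

with the baseline-0 calcium trace as input (negative overshoot values do
not activate).  Each of 500 Crz1 molecules is an independent Markov
chain: phosphorylated cytoplasmic → k_in-stage import chain → nuclear →
(phosphorylation, probability `p_phos_nuc` per step) → k_out-stage export
chain → cytoplasmic.  Entry into the import chain occurs with probability
`Cn(t)·q_dephos` per step, `q_dephos` modelling the calcineurin docking
affinity; values above 1 clamp with a logged warning since they signal
mis-scaled parameters.  Stage advances are Bernoulli, so transit delays
are sums of geometrics — negative binomial, the discrete-time analogue of
a Gamma delay, with mean k/p and variance k(1−p)/p².

The model runs at 1 s steps with calcium held constant within each 6 s
frame.  Molecules start from the stationary distribution of the basal
chain; a 600 s burn-in establishes the pre-stimulus baseline nuclear
fraction, which is subtracted.  The output is `signal_gain` times the
baseline-subtracted nuclear fraction, sampled on the 30 s Crz1 grid;
`signal_gain = 2` maps nuclear fraction to the fluorescence units in
which the detection thresholds are defined.  Updates run in fixed
molecule-index order from one seeded generator, so identical seeds give
bitwise-identical trajectories.

Default parameters are fitted-by-us to three observed anchors, not taken
from any published table: calcineurin returns to near-baseline about
5 min after a burst (D = 0.008/step, time constant 125 s, <10% residual
at 300 s); the import/export round trip is ~3 min (k = 60, p = 0.8 gives
75 s transits with 4 s spread; `p_phos_nuc` = 0.02 gives 50 s mean
nuclear residence); and ~500 molecules shuttle per pulse.  A = 0.03 and
`q_dephos` = 0.25 place typical burst heights (0.1–3 units) in the regime
where one to three detectable pulses follow a burst.  The narrow transit
spread is what keeps successive waves of molecules distinct; the
geometric nuclear residence is the dominant decoherence source, so each
round trip widens and flattens the next pulse — the mechanism behind
every directional prediction below.

Mechanistically, the pulse count grows with ln(burst height) because
calcineurin decays exponentially: the time it stays above the effective
re-import level is proportional to the log of its peak, so each e-fold of
burst height buys a roughly constant extra time window for another
molecular round trip.

## The conformational-switch model (CSM)

The comparator model drives the same calcineurin update with a damped
calcium oscillation `amplitude·exp(−t/decay_tau)·max(0, cos(2πt/period))`
and reads nuclear Crz1 out as a Hill function `Cn^n/(K^n + Cn^n)`,
baseline-subtracted.  Its calcineurin tracks the input closely
(D = 0.05/step) and the default cooperativity n = 50 makes the readout
switch-like — fully nuclear or fully cytoplasmic — so each pulse lasts as
long as activity exceeds the threshold K.  As the oscillation decays,
excursions above K shorten: the second pulse is shorter and narrower,
the direction opposite to the TDM, which is the discriminating
prediction.  The CSM is deterministic; in ensemble comparisons,
cell-to-cell variability enters through the oscillation amplitude
(±~15%) and observation noise.

## Pulse shape and periodicity

Pulse shape is quantified by least squares with a sum of logistic-product
pulses, `baseline + Σ h_i·s(r_i(t−a_i))·s(−r_i(t−b_i))` with `s` the
standard logistic function.  By default the rise and fall midpoints are
tied, `b_i − a_i = 2/r_i`, making each pulse a self-similar bump whose
duration is proportional to 1/r — r is the *narrowness*, an inverse
width.  This choice is deliberate: with a free `b − a`, r degenerates
into an edge-steepness parameter, and numerical experiments show the
CSM's second pulse then always fits with a *smaller* r (threshold
crossings slow as the oscillation decays), destroying the width-based
distinction the narrowness is meant to capture.  A free-width variant
remains available (`tie_width=False`).  The fit is multi-start (peak-
seeded locations with enforced separation so noise spikes on one plateau
cannot seed two pulses onto the same bump, plus randomized restarts),
with r bounded between the resolvable extremes (no narrower than the
sampling, no wider than the segment) and heights bounded by four times
the data range; bound-hitting fits are flagged.  Model-to-model shape
contrasts are fitted on the simulators' native 10 s output without
smoothing, because the width differences between successive pulses are
at the edge of what the 30 s microscope grid resolves.

Periodicity of a post-burst Crz1 segment (from the cell's largest burst
to the record end, excluding cells whose largest burst falls within
5 min of either record edge) is scored by a Gaussian-process
log-likelihood ratio.  The aperiodic model is a squared-exponential
kernel plus white noise; the periodic model an exp-sine-squared kernel
plus white noise, with the period bounded in [60 s, half the segment]
and multi-started over 8 log-spaced periods.  Marginal likelihoods use a
jittered Cholesky (ladder 1e-10 → 1e-6).  Two calibration choices keep
the null honest: the periodic length-scale is bounded below at 4 (the
smooth sinusoid-like regime — with a free length-scale the periodic
kernel chases chance structure in pure noise), and one nat is charged
for the periodic model's extra hyperparameter (the period), an
AIC-style correction that puts the two maximized likelihoods on equal
footing.  So calibrated, white-noise segments score below 1 nat
essentially always, while a sinusoid at typical signal-to-noise scores
around +20 nats.

## Synthetic study conditions

The generators produce everything the pipeline consumes, with ground
truth retained.  Calcium bursts are a Poisson process (default one per
10 min over 1 h records) with log-normal heights (ln-mean 0.5, ln-sd
0.5); the waveform is a double-exponential (rise 8 s, decay 30 s — the
10–100 s burst scale) plus an alpha-function undershoot bottoming 100 s
after the apex.  The undershoot's ground-truth depth follows
`gain·(ln h + jitter)` clipped at zero, with the jitter multiplicative in
the gain so that zero gain implies exactly no undershoot; the injected
amplitude is inflated by the burst tail's value at the dip so the
realized noiseless minimum equals the recorded depth.  Crz1 pulse trains
follow each burst with Poisson counts (log-link intercept ln 2, slope
0.3 on ln height), logistic-product pulse shapes, ≥150 s separations,
and truncation (warned and flagged) at flanking bursts or the record
end.  Pixel sets mix a Gaussian nuclear population over a uniform
background.  All noise is additive Gaussian on baseline-0 signals.

What these fixtures do not emulate: correlated (non-white) imaging
noise, cell-to-cell parameter heterogeneity beyond what each test
injects, segmentation errors, morphology-dependent quantification bias,
and Crz1 fluctuations with no calcium cause.  Green tests therefore
establish that the pipeline's operations are individually correct and
jointly consistent under the stated noise model — not that real
microscopy data would yield the same operating characteristics.

## Problem sizes

The property evaluations (also re-run by `scripts/acceptance.py`) use:
10^4-step calcineurin relaxations; 10^5 transit-delay samples; 20 pixel
sets of 5000 pixels; 100 synthetic calcium records for detection
operating characteristics; 200 single-burst cells spanning two decades of
height for the analog-to-digital GLM; 200 simulated cells per model for
the shape contrast; 100 periodic and 100 aperiodic segments of 60 samples
for LLR calibration plus a 40-cell height sweep; 400–500 seeds per
affinity level; and 10^4 simulated test pairs for type-I calibration.

## Known limitations

- Which mixture component the original analysis treated as nuclear is
  not recoverable from the available text; the Gaussian-as-nuclear
  assignment is this package's documented convention.
- The TDM parameter set reproduces timescale anchors, not a fitted table;
  absolute pulse amplitudes depend on the arbitrary `signal_gain`.
- With identical parameters across simulated cells the TDM does not lose
  population synchrony after a shared burst; the synchrony-decay metric
  only decays under injected per-cell parameter jitter.
- The logistic-pulse narrowness is meaningful relative to the tied-width
  family; free-width fits measure edge steepness instead and the two are
  not comparable.
- CSM ensemble statistics depend on the amplitude-jitter window spanning
  the grazing regime of the second excursion; far above threshold the
  first two pulses become equally wide.
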