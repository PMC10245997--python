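# Methods

This note records the model the package implements, the parameter choices
that matter, and the places where the design was genuinely open.

## Signal model

The simulated H-reflex for trial *k* is a single-period sine sampled at
`n_samples = 100` evenly spaced points,

    h_sim[i] = sin(2π i / n) · a(e) · β + p[i],      i = 0 … n−1,

and the quantity fed back to the player (and averaged into performance) is
the peak-to-peak of this realized waveform, max − min.

**Amplitude map.** The noiseless peak-to-peak is affine in the wrapped error
e ∈ [0°, 180°]: pkpk(e) = c₀ + g·e with c₀ = 0.5 and g = 0.5/180 per degree,
so a(e) = pkpk(e)/2. The two endpoints (0.5 at perfect alignment, 1.0 at the
maximal error) are the operative constraints; the slope and intercept are
simply the affine interpolation between them. Because the sampling grid
contains the sine's extrema exactly (i = n/4, 3n/4 for n divisible by 4),
the noiseless peak-to-peak equals the map exactly, not just asymptotically.

**Dial geometry.** The dial is circular; angles live in [0°, 360°) and the
error is the minimal circular distance, so the signal landscape has a single
minimum at the target and a single maximum opposite it. Trial-to-trial
strategy Δθ is the *signed* minimal angular change, wrapped to [−180°, 180°);
outcome summaries use its absolute value, since signed steps of an oscillating
search would cancel while the quantity of interest is search aggressiveness.

**Biological variability.** β ~ N(μ, σ²) multiplies the sine amplitude.
μ = 1 (the canonical amplitude is the average realized one; nothing ties the
mean elsewhere, and the best-performance value 0.5 must be attainable on
average). σ² = 0.25 and 0.75 are the low/high settings. Draws use an explicit
Box–Muller transform — z = √(−2 ln u₁)·cos(2π u₂) on a seeded uniform stream
with u₁ mapped into (0, 1] — rather than a library normal generator, so the
generator is exactly the stated construction and reproducible bit-for-bit.
Negative β draws (possible at σ² = 0.75, about 12% of trials) are not
clipped: the waveform flips phase and the peak-to-peak, which is what the
player sees, stays nonnegative by construction.

**Noise.** The additive term is a_N(p − p̄) with p white Gaussian over the
sample grid, mean-subtracted, and rescaled so its dominant non-fundamental
spectral amplitude equals a_N. This is the convention the package's own
estimator inverts: `estimate_noise_power` mean-subtracts each waveform, takes
the single-sided FFT amplitude spectrum, excludes the DC and fundamental
(one-cycle-per-window, i.e. the signal) bins, and returns the largest
remaining amplitude, averaged over waveforms. The round trip
`estimate_noise_power(generate_noise(...))` is exact by construction. Default
a_N = 0.05, small against the 0.5–1.0 canonical range and always explicit in
configs and logs.

A consequence worth stating: broadband noise spreads power over ~n/2 bins, so
normalizing the *dominant* bin to a_N leaves total noise variance well above
a_N², and the peak-to-peak of the noisy waveform acquires a roughly constant
floor (≈ +0.5 at the defaults, since the range of 100 Gaussian samples is
several standard deviations). This is intended — a measured signal's
peak-to-peak is also inflated by its noise floor — but it means the noiseless
best performance of 0.5 is observed only at a_N = 0, and absolute success
rates against the fixed thresholds are low at the default noise level. The
per-sample interpretation of the noise (rather than a single per-trial
offset) was chosen because the model is a sampled waveform and its feedback
statistic is computed from the samples; a per-trial offset would cancel
entirely in the peak-to-peak and make a_N inert.

**Seeding.** Every stochastic component draws from a
`numpy.random.SeedSequence` keyed by structured integer tuples: trial k of a
run uses (run_seed, k), so trials are order-independent; run setup (target
angle, initial dial, trial seed), protocol permutations, policy decisions and
cohort generation each use their own tuple. One master seed therefore fixes
the entire experiment.

## Game protocol

Ten conditions cross feedback type (Kp, Kr, KpKr) with variability (LV, HV);
reward threshold (ET = 0.46, MT = 0.7, DT = 0.96) is crossed in under Kr
only, and KpKr runs at MT. Sessions group C1–C4, C5–C8, C9–C10; each session
has 10 runs and each condition run has 35 trials. Condition order within a
run is a seeded permutation constrained so the same ordering never repeats on
consecutive runs. Success is strict (magnitude < threshold; equality fails)
and scores move ±1 per Kr/KpKr trial; pure Kp trials carry no success flag.
The threshold labels are used exactly as given even though the *easy* value
(0.46) is numerically the most stringent criterion for a down-conditioning
task whose noiseless floor is 0.5; the labels reflect the percentile of the
source distribution they were cut from, not the simulator's geometry, and the
package does not second-guess them.

Unstated interface details were fixed as: fast step 10°, slow step 1°
(two-scale search matching the four-key layout); hidden target and initial
dial position uniform per run; the displayed score may go negative.

## Agent policies

The policies are stand-ins for human explicit strategies — plumbing, not a
contribution, and not fitted to any human data. Defaults: exploration step
20°, geometric decay 0.95 per trial (coarse-to-fine search). `hill_climb`
descends the bar height: it keeps direction while the bar falls, and on a
rise reverses *and halves* its step (floored at the slow step) — the halving
on overshoot is what lets the noiseless climber reach a terminal error within
one slow step inside 35 trials, which geometric decay alone cannot.
Equal successive bar heights keep the previous direction. `hybrid` uses
whatever the feedback exposes: hill-climbing on bar height when visible,
anchoring in place after a shown success, and pure win-stay/lose-shift under
binary-only Kr feedback — this graceful degradation is what allows one agent
to play all ten conditions of the protocol. `hill_climb` under Kr is an
error, as is `win_stay_lose_shift` under Kp.

Requested dial targets are converted to keypresses greedily (fast steps, then
slow), so any target on the slow-step grid is reached exactly.

## Validation harness

The linear mixed model is performance_mean ~ measured_variability with a
participant random intercept, fitted by REML (statsmodels MixedLM). REML is
the default because variance components are of interest and the fixed design
is tiny; ML is available through the `reml` flag. Predictions are
population-level (fixed effects only) by default — the appropriate prediction
for a participant the model has not seen — with an option to add estimated
random intercepts. Variability enters as a variance (σ²), matching the
simulator's parameterization.

The synthetic cohort generator emulates the *layout* of a real conditioning
dataset — 7 participants (5 labelled healthy, 2 stroke; the label is a
passthrough tag with no generative difference), 24 sessions × 3 runs — with
per-run variability uniform on [0.25, 0.75] and performance following the
mixed model with slope 0.228 (so the expected performance gap between the
variance endpoints is 0.114, the low-vs-high gap the simulator is built
around), intercept 0.55, participant SD 0.03 and residual SD 0.05 — scatter
chosen as a plausible fraction of the 0.5–1.0 performance range. What the
generator does *not* emulate: within-participant learning trends across
sessions, serial correlation between runs, heteroscedasticity, or any
difference between the healthy and stroke labels. Passing validation tests
therefore shows that the fitting and prediction machinery recovers known
structure from data of the right shape — not that real conditioning data
satisfies the model.

## Statistical machinery

Repeated-measures ANOVA is delegated to pingouin (with replicate runs
averaged to one value per participant × cell first; the design must be
balanced, and missing cells are reported by name). Uncorrected and
Greenhouse–Geisser-corrected p-values are reported side by side, since
sphericity cannot be assumed for three-level factors. Tukey HSD uses the
subject-by-level interaction mean square as the error term and the
studentized-range distribution with (k, (n−1)(k−1)) degrees of freedom; with
two levels it reduces exactly to the paired t-test via q = t√2. Both routes
are verified in the test suite against brute-force sums-of-squares
decompositions written from first principles.

## Problem sizes

The default experiment is 7 agents × (3 sessions × 10 runs) × 35 trials
(24 500 trials, a few seconds). Calibration checks use 10⁶ variability draws
and 10⁵ Box–Muller variates; parameter-recovery uses 100 synthetic cohorts of
504 runs each; the direction-of-effect property aggregates 50 seeds per
policy × variability cell. These sizes give the stochastic checks comfortable
margins (the 1% variance tolerance at 10⁶ draws is ~7 standard errors) while
keeping the full suite under a quarter minute.

## Known limitations

- One-dimensional strategy space with a single global minimum; real operant
  strategies are multi-dimensional and can have local optima.
- Two-level variability only; the machinery accepts any σ² ≥ 0 but the
  protocol tests two.
- The agents are heuristics; nothing about their absolute performance levels
  should be read as a prediction about humans — only the direction of
  parameter effects, which is what the tests assert.
- The noise normalization ties a_N to the dominant spectral component, not
  total power; comparing a_N across different noise shapes is not meaningful.
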