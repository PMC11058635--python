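# Methods

This note documents the model, the estimation machinery, the default
parameter values, and the design decisions behind `contpsych`, in the
spirit of a methods appendix. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The generative model

A session is a discrete-time loop at `dt = 0.05 s` (20 updates/s),
130 s long with the first 10 s excluded from analysis (2400 analyzed
samples). All angles are degrees clockwise from vertical; the "horizontal
component" of a direction is `speed * sin(angle)` with a global motion
speed of 6 deg/s.

**Stimulus.** The background direction `x` performs a Gaussian random walk
with per-step standard deviation `sigma_mu` (default 1.5 deg). Boundary
handling is by mirror reflection at `range ± buffer` (default 0–90 deg
plus a 10 deg buffer): reflection keeps increments zero-mean in the
interior and the walk range-respecting, unlike clamping (which piles
probability on the limits) or resampling (which biases steps near the
edge). A session walk is accepted only if its post-discard segment puts at
least one sample into each of 9 equal-width bins spanning the range
("coverage"); candidates are drawn with consecutive seeds, and the number
tried is recorded. The symmetric variant spans −90 to +90 deg over 250 s.
The default `sigma_mu = 1.5` was chosen so that a 120-s analyzed segment
typically covers the 90-degree rightward range within a handful of
candidate draws (the expected range of an unbounded walk of N steps is
`~1.6 sigma sqrt(N)` ≈ 117 deg at N = 2400); it is a configuration
parameter, not an estimate.

**Sensation.** The participant senses `X = x + omega`,
`Y = y + psi` (`omega, psi ~ N(0, 1.6 deg^2)`; the value 1.6 deg² is the
endpoint-variance estimate from training data, and the training assumption
makes it common to the x, y and blob channels). The model assumes constant
noise variances throughout a session, so estimates use the *steady-state*
gain of the scalar Kalman recursion rather than a time-varying gain:

    k = (-r + sqrt(r^2 + 4 r)) / 2,   r = process_var / obs_var.

For the x channel the process variance is the walk's step variance
(`k_x = 0.675` at the defaults); for the y channel it is the motor-noise
variance (`sigma_lambda^2 = 0.22 deg^2`, giving `k_y = 0.308`), because
the unpredictable part of the target's motion is the participant's own
unintended action. The y prediction is the previous estimate advanced by
the *intended* action, so motor noise enters the internal estimate only
through the observation term — multiplied by `k_y`.
Degenerate case: when both variances of a channel are zero every gain is
exact; the simulator and analysis then use the convention k = 1 for x
(trust the data) and k = 0 for y (trust the prediction).

**Perception.** `sin(y~) = sin(y_hat) - beta sin(x_hat) + d`, evaluated on
unit-speed horizontal components and mapped back through `asin`. The
argument is clipped to [−1, 1] and clip events are counted in the session
metadata (zero at the default operating point). `beta` (unitless, typical
range 0.3–0.8 across individuals) scales the induced-motion interaction;
`d` is a constant offset in horizontal-component units accommodating an
idiosyncratic bias (`d = -sin(9 deg)` reproduces a participant who sets
the target 9 deg clockwise at a vertical background).

**Action.** A unit-mass damped spring integrated by explicit Euler:
`v <- v + dt (b e - c v)`, intended step `a = dt v`, with the error `e`
read from a delay line `delta_t = 0.4 s` in the past (fractional lags are
linearly interpolated). Gaussian motor noise `lambda` is added to each
realized step. A guard raises a stability error if `|v|` exceeds
10^6 deg/s, which is how dynamically inconsistent `(b, c, delta_t)`
configurations surface rather than emitting garbage.

*Default damping.* Linearizing the lagged closed loop gives an effective
damping of roughly `c - b * delta_t`; stability therefore requires
`c > b * delta_t ≈ 0.15 s^-1` at the default spring constant
`b = 0.375 s^-2` and reaction lag 0.4 s. The default `c = 0.3 s^-1` takes
a 2x margin and yields moderately underdamped, visibly overshooting step
responses of the kind real participants produce. Lightly damped
configurations such as `(b, c) = (0.375, 0.008)` or `(0.272, 0.024)` are
valid *training-session* parameterizations when the reaction lag is small,
and the training tools recover them exactly, but they are unstable in the
lagged closed loop and are not suitable as session defaults.

**Adaptation.** Sensitivity loss accumulates linearly: at step t the
sensed horizontal component of the target is reduced by
`q * sum_{tau<t} speed * sin(y_tau)`, accumulated per update step. At
`q = 1e-4` per step, one second of 6 deg/s rightward motion (20 steps,
accumulated component 120) reduces the perceived speed to
`6 - 1e-4 * 120 = 5.988 deg/s`, a 0.2% change — the scale of adaptation
the model is meant to capture. De-adaptation subtracts the same running
sum from recorded data; applied at the true rate it inverts the
participant's compensation exactly, because the participant's extra
clockwise adjustment at step t is precisely the accumulated term.

## Training analysis

The blob stimulus steps ±10 deg every 5 s for 130 s (26 epochs; 24 after
the warm-up). Responses are aligned on the jumps, re-zeroed to the
pre-step target value, sign-flipped so every driving step is positive, and
averaged. The spring parameters are fit to this average by least squares,
with two model variants:

* `fit_spring` — the from-rest response of the lagged spring to a single
  step (appropriate when responses settle within an epoch);
* `fit_training_session` (default `replay=True`) — the model prediction
  replays the *whole* deterministic closed loop over the actual blob
  sequence and passes it through the same extract/rectify/average
  pipeline as the data. This accounts for spring state carried across
  epoch boundaries, which matters for lightly damped springs that ring
  longer than 5 s; with it, noiseless sessions are recovered to machine
  precision.

The objective is multimodal in `(b, c)`, so a coarse 6x6 grid (crossed
with two lag values) seeds a bounded trust-region refinement; the best of
the top three seeded starts wins. The reaction lag is fit as a free
parameter and additionally estimated model-free as the time at which the
average response first departs 5% of the step size from baseline; both are
reported. The endpoint variance — the sample variance (n−1 denominator) of
(target − blob) at the last sample of each epoch — estimates the shared
sensory noise. Note that for underdamped springs this statistic includes
ringing variance, not sensory noise alone; it is reported as measured.

## Inverse analysis

`x*` is the constant-gain filter run on the raw x series — the
experimenter's replica of the participant's internal background estimate
(it cannot include the participant's private sensory noise draws, which
is part of why recovered percepts correlate imperfectly with the truth).

Recovering the percept from the target series is a deconvolution problem:
naively double-differencing y amplifies the white motor noise by
`1/(b dt^2)` (three orders of magnitude at the defaults) and was found to
destroy the signal entirely. Instead the spring difference equation is
inverted by a Kalman (RTS) smoother over its own state space:

    observation   dy_t = dt * v_t + lambda_t,      lambda ~ N(0, sigma_lambda^2)
    state         v_t = (1 - dt c) v_{t-1} + dt b e_t
                  e_t = e_{t-1} + w_t,             w ~ N(0, percept_step_sd^2)

This is the minimum-variance linear estimate of the driving error given
the motor-noise variance and a random-walk smoothness prior on the percept
(`percept_step_sd`, default 1 deg/step — the scale of per-step percept
change implied by a percept with SD of a few degrees decorrelating over
the ~1 s the spring responds to). In internal comparisons the smoother
outperformed both the moving-average/double-difference scheme and a
circulant-FFT Wiener deconvolution oracle built from the true
cross-spectra. The recovered error sequence is shifted forward by the
fitted reaction lag to align the percept with the perception it estimates;
the smoothed velocity provides the intended per-step actions.

The participant's internal target estimate is then replicated by running
the constant-gain y filter on the raw data with the *recovered intended
actions* as the prediction input — mirroring the generative model, where
motor noise reaches the estimate only through the small observation gain —
and `y* = y_hat - y~`. Both final series are restricted to the
post-warm-up window.

Three lags are reported: the sensory filter's group delay
`dt (1 - k_x)/k_x`; the action lag (fitted reaction lag plus the time for
the closed-loop spring to reach half of a step); and the residual
cross-correlation lag between `sin(x*)` and `sin(y*)`, which is zero (to
within one sample) when the generative parameters are known exactly.

## Model fitting and statistics

The induced-motion fit regresses `sin(y)` on `sin(x)` by ordinary least
squares — the model is linear in horizontal-component space, so the fit is
closed-form — reporting the slope as `beta` and minus the intercept as
`d`. R² is computed on the raw sample pairs in that space. AIC uses the
least-squares convention `n ln(RSS/n) + 2K` with K = 3 (slope, offset,
error variance); absolute AIC values are convention-dependent, so only
differences are interpreted, with ΔAIC ≥ 2 flagged as significant. The
mean-square distance is taken between the 9 per-bin means of y and the
model curve `asin(beta sin x - d)` at the bin centers, in deg²; bin SDs
use the sample (n−1) denominator and empty bins carry NaN.

The adaptation rate is estimated by driving the regression intercept of
de-adapted target components on background components to a target value
(0, or a nonzero value when a genuine constant bias is being allowed for).
Because heavy over-correction clips the arcsine and breaks unimodality, a
40-point log-spaced scan over `q in [0, 1e-2]` brackets the optimum before
bounded Brent refinement at `xatol = 1e-10`.

## What the synthetic generator does and does not emulate

The simulator reproduces the structure of a continuous-correction
experiment: random-walk stimulus with coverage selection, constant-gain
sensing, the nulling percept, lagged spring action with motor noise,
blob-step training sessions, and linear-accumulation adaptation. It does
not emulate: display/rendering of the Gabor stimulus; eye movements or
fixation breaks; non-Gaussian or heteroscedastic sensorimotor noise; slow
drifts in strategy, attention or fatigue; exponential adaptation
time-courses (deliberately out of scope — accumulation is modelled as
linear); or between-participant variability beyond what the parameters
expose. Passing tests therefore demonstrate internal consistency of the
forward and inverse machinery under the model's own assumptions — the
claim a method paper's simulations support — not that human data obey
those assumptions.

## Numerical choices and degenerate inputs

- Seeds: every stochastic component takes an explicit integer seed
  (`numpy.random.default_rng`); the pipeline derives per-stage child seeds
  from one master seed via `SeedSequence`, and identical seeds give
  byte-identical outputs.
- Delimited-text I/O validates a uniform time grid to 1e-6 s and names the
  first offending row on failure.
- The smoother's observation-noise floor is 1e-12, so noiseless sessions
  invert exactly (round-trip correlation > 0.99).
- `perceive` clips its argument to [−1, 1] and counts clips; `de_adapt`
  clips corrected components to ±speed and counts clips.
- Zero-excitation inputs (constant blob, constant background, constant
  target) raise explicit unidentifiable/insufficient-data errors rather
  than returning fragile numbers.
- The full-idempotence property "re-finalizing finalized data is the
  identity" holds only at the noiseless fixed point (a fully corrected
  session); for general data the inversion treats residual variation in
  `y*` as spring-driven, so the property is tested at the fixed point.

## Known limitations

- Recovered percepts are band-limited: the spring transmits only
  frequencies near and below its natural frequency `sqrt(b)` rad/s, so
  per-sample percept jitter caused by sensory noise is unrecoverable in
  principle; at the default operating point the recovered-vs-true percept
  correlation is ≈ 0.94 against a measured band-limit ceiling of ≈ 0.95.
- `y* = y_hat - y~` subtracts angles, while the perception stage is linear
  in sines; the discrepancy is second-order for percept deviations of a
  few degrees but would grow for very poor tracking.
- The training endpoint-variance statistic conflates sensory noise with
  unsettled-spring ringing for lightly damped participants.
- Training-session spring fits from 24 noisy steps carry ~10–20% parameter
  uncertainty, which propagates into the finalized series; analyses that
  need the inversion in isolation should supply known action parameters.
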