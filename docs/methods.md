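# Methods

This note documents the models, numerical choices and limitations behind the
package, in the order the pipeline runs.

## Signal model and alignment

A session log is a single CSV stream of time-stamped samples (integer ms,
strictly increasing) carrying the crank angle (0° = right crank-arm
vertically down, increasing clockwise seen from the right), per-side crank
torque, per-side thigh angle, and optional `stim_on` / `wheel_rev` flags.
The two sensor families report with different constant latencies: the
wireless power meter (crank angle and both torques) by default 200 ms, the
thigh IMUs (internal Kalman filtering) 40 ms. A reported sample reflects
the physical state *delay* ms earlier, so alignment reduces each channel's
timestamps by its delay and then linearly interpolates every channel onto a
common uniform grid (default 100 Hz, the controller rate). The crank angle
is unwrapped before interpolation and re-wrapped to [0, 360) after, so the
360→0 seam never produces spurious jumps. No extrapolation is performed:
the head/tail of the session not covered by every shifted channel is
dropped, which is why the simulator pads sessions with partial lead-in/out
revolutions.

Because the power meter samples torque and crank angle *together*, the
torque-vs-crank-angle relation is invariant to that shared latency; the
alignment matters for cross-sensor consistency (crank vs. IMU vs. control
flags) and is essential for the phase domain, where position (IMU) and
torque (power meter) latencies differ by 160 ms.

## Cycle segmentation and the cycling phase

Crank cycles are delimited by the upward crossing of 0°, located by linear
interpolation of the unwrapped angle at each 360·k level. Only the first
crossing of each level is taken and it must be confirmed by 5° of further
travel; repeated jitter crossings of the same level are therefore harmless.
Partial head/tail revolutions are discarded. Cadence is 60000 ms / duration.

The cycling phase normalizes one leg's thigh angle onto [0, 100): a cycle
runs from one full-flexion extremum to the next, with 0–50 % covering knee
extension and 50–100 % knee flexion:

    extension: phase = 50 (θ − θ_flex) / (θ_ext − θ_flex)
    flexion:   phase = 50 + 50 (θ_ext − θ) / (θ_ext − θ_flex)

The anchors θ_flex/θ_ext are taken causally from the most recently completed
cycle (the first cycle uses its own extrema and is emitted retrospectively);
values are clipped to their half-cycle. Which raw-angle direction counts as
extension is mounting-dependent and configurable (`extension_decreasing`,
default true). Extrema are found with a prominence threshold of half the
minimum admissible range (10° by default); a smaller total range raises a
degenerate-motion error rather than inventing cycles from drift.

The cadence gate accepts a cycle iff target (1 − tol) ≤ cadence ≤
target (1 + tol), bounds inclusive — with the default 5 RPM and 50 %
tolerance, rejection happens strictly above 7.5 or below 2.5 RPM.

## Template normalization and interval detection

Each accepted cycle's torque is linearly interpolated *as a function of
position* onto a fixed template — 361 crank bins (0–360° in 1° steps) or
101 phase bins — so cycles of different and varying speed become
comparable. Bin 0 and the last bin are the same physical position; their
values are tied (averaged) after interpolation. A position gap wider than
20 bins (configurable) raises a sparse-cycle error instead of silently
bridging it. Profiles are averaged per set (arithmetic mean per bin) and
differenced into the net torque.

The detector locates the bin of maximal net torque (ties broken towards the
lowest bin index, scanning from 0) and walks circularly outward to the
nearest zero-transitions, defined as sign changes between adjacent bins.
The reported start is the first positive bin of the run containing the
maximum and the stop is one past its last positive bin, both at integer bin
resolution (detected patterns are printed as integers, so no sub-bin
interpolation is attempted). With half-open circular membership
[start, stop), stimulation covers exactly the positive bins. An
all-non-positive profile raises a no-positive-contribution error (the
muscle never helps); an all-positive profile returns a flagged full-cycle
interval. An optional circular moving average can be applied before the
search; it is off by default.

The full pipeline (`run_oida`) splits the log at the first `stim_on` flag
(or an explicit split time), gates cycles by cadence, and discards the
first accepted active cycle: the sudden movement at stimulation onset makes
it unrepresentative. `n_cycles` (default 3) accepted cycles per set are
then averaged, so a recording must contain at least `n_cycles` accepted
passive and `n_cycles + 1` accepted active cycles.

## Delay compensation and commands

The compensation shifts are pure closed forms,

    shift_start = (delay_muscle + delay_sensor) / duration_cycle × span
    shift_stop  =  delay_sensor / duration_cycle × span,

with the sensor delay chosen per control signal (crank: power meter; phase:
IMU) and span 360 or 100. Both endpoints move *earlier* (modulo the span);
since shift_start ≥ shift_stop the interval widens, and it saturates to a
flagged full cycle (with a warning) if the compensated width reaches the
span. The shifts scale inversely with cycle duration: halving the cadence
halves the shift in degrees. The cycle-duration estimate is re-evaluated
once per cycle, using the most recently completed cycle of the control
signal; before the first completion a configured fallback cadence (default
30 RPM) is used. The replayer applies half-open membership of the
compensated interval to every sample, per channel.

Session summaries count wheel-revolution events times the wheel
circumference for distance; average speed is distance over duration and
maximum speed the circumference over the shortest inter-event gap. Cadence
and power are per-crank-cycle quantities, power being the cycle mean of
total torque (left + right) times the angular velocity of the unwrapped
crank angle by finite differences. Quantities whose source channel is
missing are reported as unavailable, never as zero.

## The simulator

The generator is deliberately phenomenological: the detection pipeline
consumes only torque-vs-position, so the minimal structure that exercises
every code path is a passive torque that is a smooth periodic function of
the crank angle plus a stimulated contribution that is positive exactly on
a known interval. Per side, passive torque is the first two harmonics of
the crank angle (default amplitudes 5 and 1 N·m, legs 180° apart) — a
gravity-dominated model whose integral over a cycle is zero. The
stimulated muscle adds a raised-cosine bump (default peak 5 N·m) strictly
positive exactly on the configured true interval, with an inverted
raised-cosine lobe (default depth 1.2 × peak) on the rest of the
revolution, reflecting that the eccentric, resisting torque of a stimulated
muscle typically exceeds its concentric contribution. Thigh angles follow
offset + amplitude·cos(crank − φ_side) with the sides 180° apart, so phase
cycles are consistent with crank cycles. The crank trajectory is piecewise
constant-velocity, one cadence draw per cycle (default 5 RPM ± 10 % uniform
jitter, matching a careful hand-turned fitting). Defaults generate 4
passive and 5 active revolutions plus 0.35-revolution lead-in/out — enough
for 3 accepted cycles per set after the onset-transient cycle (simulated as
an extra decaying torque pulse, default 2 N·m, over the first quarter of
the first active revolution) is discarded and alignment trims the edges.
Sensor delays are *applied* to the emitted streams and white Gaussian noise
can be added to the torque channels; everything is deterministic under the
seed.

What the simulator does not emulate: muscle fatigue and recruitment
dynamics, rider–trike load dynamics, IMU orientation drift, dropped or
duplicated wireless packets, and any systematic torque-offset error.
Passing tests therefore demonstrate the correctness of the *algorithmic*
chain (alignment, segmentation, normalization, detection, compensation),
not robustness to every artefact of real recordings.

## Problem sizes and numerical tolerances

The recovery studies in the test-suite and acceptance script use 64
noiseless sessions on a grid of interval widths 40–320° (including
wrap-around placements) at 3–7 RPM, and 200 randomized noisy sessions;
each session is ~2 minutes of simulated pedalling at 100 Hz and runs in
~15 ms, so the whole study completes in seconds. Noiseless recovery is
exact to ±1 template bin; the residual comes from the bump being zero at
its exact endpoints and from boundary-interpolation quantization.
Cadence-invariance comparisons use an absolute tolerance of 0.01 N·m,
dominated by linear-interpolation error of the smooth torque model at
0.2–0.5° sample spacing.

## Known limitations

- **Edge localization under noise.** The nearest-zero-transition search on
  a 1°-resolution profile is an inherently noise-fragile edge estimator
  when the contribution fades smoothly into zero: near the true endpoint
  the signal drops below any white-noise floor, and the walk from the peak
  stops at the first noise-induced non-positive bin, typically well inside
  the true interval. With white torque noise of 10 % of the peak
  contribution and 3-cycle averaging, recovered endpoints are usually one
  to a few tens of bins inside the truth (the acceptance script reports the
  measured within-±5-bins fraction honestly). Real fittings mitigate this
  by the examiner's smooth motion and by the interval being consumed by a
  muscle whose force rises gradually anyway; algorithmically, profile
  smoothing (the optional moving-average flag) trades edge bias for noise
  robustness but is off by default.
- The detector reports integer bins; sub-bin edge refinement is out of
  scope.
- The passive/active split relies on `stim_on` flags or an explicit split
  time; logs with interleaved stimulation segments are not supported.
- Compensation assumes constant cadence within a cycle; rapid intra-cycle
  accelerations shift the effective latency-equivalent angle.
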