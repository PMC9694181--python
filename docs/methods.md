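# Methods

`dartkit` computes spatiotemporal gait and turning metrics from the pose
stream of a head-mounted device, scores dual-task interference against a
single-task reference, and ships a synthetic trajectory generator so the
whole pipeline can be validated without hardware. This note documents the
models, the parameters that matter, and the choices made where the design
was genuinely open.

## Coordinate and data conventions

All positions are in meters in a Y-up right-handed frame: x lateral
(positive left), y vertical, z forward at zero yaw. Yaw is rotation about
+Y, positive for a left turn; orientation is logged redundantly as Euler
angles (degrees) and scalar-first unit quaternions, and the two must agree.
All algorithms are rate-agnostic — timestamps drive every computation — and
the sampling rate is estimated from the median sample interval only to set
digital-filter coefficients. The pose CSV quantizes time and position to
1e-4 and angles/quaternions/gaze to 1e-9 on write, so one write→read cycle
is the identity at that precision and further cycles are bitwise exact.

## Gait model and step detection

During steady walking the head oscillates vertically once per step with an
amplitude of roughly 1–3 cm. Steps are detected as local maxima of the
vertical head position after a zero-phase 4th-order Butterworth band-pass
of 0.5–3.0 Hz (cadences of 30–180 steps/min; cohort means of 88–97
steps/min sit centrally in the band). A maximum counts as a step if its
prominence is at least 0.005 m and it is separated from the previous step
by at least 0.25 s (capping cadence at 240 steps/min). The first and last
0.5 s of a trace are trimmed before peak picking to suppress filter edge
transients; a peak whose true location falls inside the trimmed lead-in is
therefore not counted, which is visible in the analytic sinusoid checks.

Gait velocity is horizontal (x, z) path length divided by elapsed time.
Path length — not net displacement — is used so that closed-loop courses
yield sensible speeds. Positions are low-pass filtered at 2 Hz before
differencing; without smoothing, millimeter-level tracker jitter integrates
into a large spurious path length. Cadence is `60 · n_steps / duration` and
step length is `distance / n_steps`. `analyze_gait` measures distance,
duration and steps over one common analysis window, so the identity
`velocity = step_length · cadence / 60` holds to machine precision by
construction; it is asserted to 1e-9 on every analyzed trace. Zero-step
traces report a NaN step length rather than dividing by zero. Exclusion
intervals (turns, freezing episodes) remove both distance and time, and any
step events inside them, from the window.

## Turning model

Heading is the yaw of the quaternion-rotated forward axis,
`atan2(f_x, f_z)`, unwrapped so continuous rotation never jumps across
±180°, then low-pass filtered at 1.5 Hz. The filter is a first-order
zero-phase Butterworth on purpose: higher orders overshoot ("ring") on the
plateau of a fast turn and bias the recovered peak rate upward by several
percent, whereas the first-order response is monotone. Yaw rate is obtained
by central differences.

A turn is a maximal interval where |yaw rate| ≥ 15 deg/s, with hysteresis:
once started, the turn ends only when the rate falls below half the
threshold, so brief mid-turn dips do not split an event. Events with a net
heading change below 45° are discarded — obstacle-course sidesteps are
designed to stay below this — and same-direction events separated by less
than 0.3 s are merged. Per turn we report signed magnitude, duration, mean
velocity (|Δyaw|/duration) and peak velocity (max |rate|); per module, the
turn count, mean turn time, mean of per-turn means, and max of per-turn
peaks. The hysteresis tail makes event durations slightly longer — and mean
velocities slightly lower — than the idealized commanded profile; peak
velocity is unaffected and is the quantity compared against commanded
values.

## Dual-task scoring

Each dual-task module is percent-scaled against the single-task warm-up
reference: motor metrics are green at ≥ 90% of the reference, yellow in
[80, 90), red below 80; cognitive percent-correct is green at ≥ 85%, yellow
in [70, 85), red below 70. Boundary semantics were fixed so the bands
partition the axis exactly. The dual-task cost of a metric is its percent
decline, `100 · (single − dual) / single`, and a strictly greater than 10%
decline flags dual-task impairment. All four gait metrics (velocity,
cadence, step length, peak turn velocity) are treated as decline-type
(lower = worse), matching the interpretation of dual-task decreases as
interference; directionality is a per-metric flag in the report builder if
a future metric needs the opposite sense. Cohort-level single-vs-dual
differences use the two-sided paired t-test; a zero-variance difference
vector is flagged rather than producing an infinite statistic.

## Cognitive tasks

Two generators are implemented in full. Odd-one-out (language): five
distinct words, four drawn from one category of the packaged word bank
(13 categories) and one from outside it, odd position uniform over the five
slots, five-second response window. Spelling backwards (attention):
difficulty tiers are word lengths 3, 4 and 5+ letters. Responses are
normalized (lowercase, trimmed, punctuation stripped) before comparison — a
desk-scale stand-in for spoken-response capture; no speech recognition is
attempted. A correct answer arriving after the window closes is scored
incorrect (scoring it unscored was the plausible alternative; incorrect is
the stricter reading and is applied uniformly). Open-ended prompts carry no
correct answer, are flagged unscoreable, and are excluded from both the
numerator and denominator of percent-correct. The remaining 15 catalog
tasks are registered with domain labels and the generic percent-correct
contract but no stimulus content.

## Real-time loop

Status messages are emitted every 5 s of active module time, carrying the
motor/cognitive task ids, elapsed and remaining time, and the current
speed: horizontal path length over the trailing 5-s window. Pauses suppress
messages and are excluded from elapsed time (the alternative — wall-clock
elapsed — would make `elapsed + remaining` exceed the module duration).
"Stopped" for pace-setter feedback means a current speed below 0.1 m/s —
below any plausible walking speed, above tracker jitter; between 0.1 m/s
and the target the icon is orange, at or above target it is green. The
transport layer is an in-process generator; no networking is implemented.

## Synthetic walker

The generator commands two of {speed, cadence, step length} and implies the
third through `speed = step_length · cadence / 60`, enforcing an implied
step length in (0.1, 1.5) m. Head position is the path progression at the
commanded speed plus a vertical sinusoid at step frequency (default
amplitude 0.02 m), a lateral sinusoid at half step frequency (stride sway,
0.02 m), a 1.6 m head-height offset, and per-axis Gaussian noise (default
SD 0.003 m, our estimate of head-tracker jitter; the device's true noise
figure is not characterized). Yaw follows the path tangent with 0.1° jitter.
Defaults: 60 Hz sampling. Vertical bob at step frequency and sway at stride
frequency are standard walking kinematics and are what the gait engine's
band-pass assumes.

Courses are segment lists: straights, turns (trapezoidal angular-velocity
profile with 0.2 s ramps reaching the commanded peak; small angles degrade
to triangles that still touch the peak), and scripted stops. The obstacle
course is a closed loop of two straights joined by 180° end turns; pillars
insert four ±30° sidestep deflections (below the 45° turn threshold), and
the doorway is a geometric marker where freezing episodes cluster. The
figure-of-eight is two opposite-handed stadium loops: two left and two
right 180° turns, 720° of rotation magnitude per circuit. Freezing is
modeled as commanded full stops — progression and bob freeze, jitter
persists; no tremor or festination is modeled. Ground truth records
commanded speed/cadence/step length, per-turn windows and peaks, step times
(bob maxima) and freezing intervals.

The paired-cohort sampler draws each metric's (single, dual) pair from a
bivariate normal with the two condition means/SDs and a within-subject
correlation of 0.7 — the correlation is not empirically constrained; 0.7 is
a typical test-retest value for gait metrics and gives the paired test
realistic power at n = 47.

What the generator does *not* emulate: left/right step asymmetry, arm
motion, trunk-head decoupling during turns, non-Gaussian tracker dropouts,
and gait variability beyond white noise. Passing recovery tests therefore
demonstrates correctness of the pipeline's signal processing under the
stated gait phenomenology, not clinical validity on patient data.

## Problem sizes and tolerances

Recovery checks use 20 seeds per operating point with 60-s traces (120 s
for cadence, where the ±1 step/min check benefits from a longer window);
the identity property uses 1000 randomized 6-s traces; cohort power uses
200 replicates of n = 47. Recovery tolerance is 5% per gait metric and
±10 deg/s for peak turn velocity. These sizes keep the full suite around
ten seconds while leaving the statistical checks well-powered.

## Known limitations

Head-only sensing cannot attribute steps to a side, so no left/right
metrics are produced. Turn counts depend on the 45° minimum angle: gradual
heading drift below 15 deg/s is never segmented, and counting
course-imposed versus spontaneous turns is not distinguished. The
percent-of-reference scheme assumes a valid positive reference; modules
without a matching warm-up are skipped rather than scored.
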