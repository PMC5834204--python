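# Methods

## The task and its physics

The virtual skittles (tetherball) task is a planar throwing game.  The
thrower rotates a lever arm of length L = 40 cm about a pivot 150 cm below
the workspace origin; the ball rides on the lever tip until release.  At
release the ball detaches with the hand's position on the lever circle and
its tangential velocity, and from then on behaves as a point mass attached
to two orthogonal massless springs whose rest position is the workspace
origin.  Each axis follows

    x(t) = Ax sin(omega t + phi_x) exp(-t / tau)

(and likewise for y): a damped ellipse centred on the origin.  The
amplitudes and phases are recovered per axis from the launch state by
writing the solution in the equivalent form
`x(t) = exp(-t/tau) (x0 cos(omega t) + kx sin(omega t))` with
`kx = (vx0 + x0/tau)/omega`, so `Ax = hypot(x0, kx)` and
`phi_x = atan2(x0, kx)`; a degenerate axis maps to (0, 0).  Setting
`tau = inf` gives undamped, closed orbits; then the ball passes through the
exact antipode of its release position half a period later regardless of
release velocity — the mechanism behind the I-shape geometry.

**Scoring.**  A throw's performance error is the minimum distance between
the ball path and the target centre.  The flight is simulated over one full
oscillation period 2*pi/omega (the damped orbit spirals into the post
region, so longer horizons add no meaningful target approaches) and
truncated at the first contact with the post (centre distance below
post_radius + ball_radius; the ball is an extended disc).  Setting
post_radius to 0 removes the post entirely.  The minimum is located by a
coarse scan at 1 ms followed by golden-section refinement of the squared
distance in every local basin (40 iterations, i.e. far below the 1e-4 s
target resolution); the contact time itself is found by bisection, and
local minima of the post distance are also refined so grazing contacts
between coarse samples are not missed.  The scorer is a per-row numba
kernel: the arithmetic for one release state does not depend on how many
states are scored together, so a state scored alone, inside a grid, or
inside an error trajectory gives bit-identical results.

**Categories.**  hit: error < 1.1 cm and no post contact (the threshold at
which the display signals success); near: error in [1.1, 2.5) cm (the
target radius); invalid: post contact or error beyond the 40 cm display
range; miss otherwise.

**Conventions.**  Lever angle is measured from the workspace +x axis,
counterclockwise positive, hand at pivot + L(cos theta, sin theta); any
fixed convention is observationally equivalent.  Velocity axes of solution
spaces are the angular speed in the task's throw direction; ReleaseState
always carries the signed angular velocity.

## Solution spaces and the four task variants

Evaluating the error over an (angle x velocity) grid colours the execution
space; the sub-threshold, post-free cells form the solution manifold,
stored per angle as maximal velocity intervals (interval edges at the outer
cell edges, so one cell yields one cell-width interval).  Default ranges
are 0-180 degrees and 0-1000 deg/s at 300x300 resolution; results never
depend on the plotted range beyond cell-size effects.

`velocity_sensitivity` reports, per angle column, the coefficient of
variation of error across velocities (post-hit cells excluded; NaN for
all-post columns; exactly zero when the column's mean error is numerically
zero, since the CV of rounding noise is meaningless).  Velocity
insensitivity is exact only along the manifold itself: away from the
antipodal angle the minimum distance genuinely varies with release speed,
because slow releases fly thin, line-like orbits and fast releases fat
ellipses.

Four representative task variants ship with the package.  They are the
product of a geometry search over target/post placements and spring
constants, selected to reproduce the four classic manifold shapes, not
copies of any particular experimental configuration:

| task      | target (cm)     | post (cm), r  | omega    | tau  | direction | manifold character                          |
|-----------|-----------------|---------------|----------|------|-----------|---------------------------------------------|
| u_shape   | (-39, 39)       | (0,0), 25     | 2*pi     | 10 s | cw        | curved valley, two branches                 |
| j_shape   | (35, 60)        | (0,0), 25     | 2*pi     | 10 s | cw        | ends discontinuously against post hits      |
| box_shape | (30, 90)        | (40,0), 25    | 3*pi     | 10 s | ccw       | shallow gradients, reaches low speeds       |
| i_shape   | (13.68, 112.41) | (0,0), 25     | 3*pi     | inf  | ccw       | parallel to the velocity axis (control)     |

The i_shape target is the antipode of the 110-degree release position; with
undamped flight every release speed from that angle is an exact solution.
Its higher spring frequency matters: post clearance then requires roughly
370 deg/s, which pins the speed at which the angular band can be crossed
and therefore caps the timing window — the singular control property.

## Timing measures

An arm trajectory (lever angle at 1 kHz with a marked release sample) is
converted to an error trajectory by scoring every sample as a hypothetical
release.  Angular velocity at a sample is the OLS slope of the 20 angle
samples strictly before it (the release-state estimator), applied to every
sample and back-filled over the first 20 so indices align; a recorded
velocity series can be supplied instead.

* **Timing error** (ms): distance in time from the actual release to the
  reference.  Default rule `nearest_crossing`: among the sub-threshold
  runs of the error trajectory, take the error minimum of the run nearest
  in time to the release; fall back to the global minimum when the
  trajectory never crosses the manifold.  `global_min` and
  `window_midpoint` (reference at the selected run's midpoint) are exposed
  as alternatives.
* **Timing window** (ms): duration of the sub-threshold run containing the
  nearest-crossing reference — the count of strictly sub-threshold samples
  times the sampling interval, with no sub-sample interpolation (values are
  reported at the 1 kHz measurement resolution); zero if no sample is
  sub-threshold.

Both measures depend only on the sequence of physical launches, so they are
invariant under reparameterizing the execution variables; the Cartesian
route reconstructs each launch from the release-velocity vector alone (the
throw direction resolves the tangent ambiguity) and must reproduce the
measures exactly.

Per day, timing error is aggregated by the median and timing window by the
mean (timing errors are non-negative and skewed; windows are not).

## Synthetic data generator

No generative model of human throwing exists for this task, so the
generator is a deliberately simple harness with the statistical structure
the analysis assumes, not a cognitive claim:

* **Trajectory**: minimum-jerk angular profile
  theta(s) = start + dtheta (10 s^3 - 15 s^4 + 6 s^5) over the movement
  time, held at the end angle for a follow-through span (default 25% of
  the movement time).  Peak angular speed is 1.875 dtheta / T.
* **Noise** (all Gaussian, per throw): release-time jitter (the quantity
  under study), amplitude noise (default 1.5 degrees) and duration noise
  (default 20 ms) representing trial-to-trial execution variability.
  Sampling is deterministic given the seed; per-throw seeds derive from a
  counter-based SeedSequence over (seed, day, throw).
* **Sessions**: 240 throws per day in 4 blocks, the task's standard
  practice protocol.

`strategy_through_state` builds sweeps constrained to pass through a chosen
release state at a chosen min-jerk phase; for a fixed state, lengthening
the movement time widens the sweep and lowers its acceleration — molding
the trajectory to the manifold — without changing the release state itself.
`calibrate_strategy_to_manifold` searches such sweeps (candidate states
from the manifold at realistic release speeds of 200-1000 deg/s, a grid of
movement times and phases) for a requested noiseless timing window, placing
the planned release at the trajectory's ideal sample; an unreachable target
returns the best floor flagged unachieved.

**Practice schedules.**  A simulated learner improves along two distinct
processes: release jitter decays exponentially from 40 ms onto an 18 ms
plateau within about two days (the early, fast improvement of release
timing; the floor sits at the plateau scale of skilled throwers), and the
movement time ramps linearly from the naive to the skilled end of the
task's practice ramp, scaled by the subject's alignment parameter.  The
practice ramp — a release state plus movement-time range over which the
noiseless window grows monotonically (capped at 60 ms, the scale of highly
skilled throwing; degenerate slow sweeps that park inside shallow manifolds
are thereby excluded) — is chosen by `design_practice_ramp`, which requires
the naive end to be a working strategy (nonzero window): practicing
subjects throw hard enough to clear the post from the start.  Frozen ramps
for the four bundled tasks are included so cohorts are reproducible; on
i_shape every admissible ramp leaves the window at the band-crossing
ceiling (~28 ms), which is the point of the control task.

**Cohorts.**  Subjects differ in two once-drawn skill parameters: alignment
(0.45-1.0, how far along the ramp they progress — governing their final
timing window) and jitter scale (0.6-1.6, multiplying the jitter schedule —
governing their timing error).  These ranges put between-subject variance
on both timing measures, as in real cohorts where timing precision varies
several-fold across individuals.

What passing synthetic tests does and does not show: the generator
validates the *analysis* — that the measures recover injected timing noise,
that the qualitative practice pattern follows from jitter reduction plus
manifold alignment, and that the regression separates the two processes.
It does not model how humans explore the solution space, signal-dependent
noise, biomechanical limits, or learning dynamics within a day.

## Session statistics

Each (subject, day) session is summarised by success rate (percent hits),
median performance error, median timing error and mean timing window.  Per
day, performance error is regressed across subjects on the two timing
measures after z-scoring all three variables within that day:
y = beta1 x1 - beta2 x2 with x1 the timing error and x2 the window.  The
minus sign is a reporting convention: the fit is unconstrained OLS, and
beta2 is reported as the magnitude entering with the minus sign (positive
when longer windows reduce error), with 95% t-based confidence intervals,
R^2 and the variance-inflation factor of the two predictors.  Within-day
z-scoring is the default (each day's regression stands alone); at least 4
subjects and non-degenerate variance are required.  Inferential
repeated-measures ANOVA is out of scope; day-by-day means and SEMs are
provided for plotting learning curves.

## Numerical choices and limitations

* Coarse flight sampling 1 ms, golden-section refinement 40 iterations,
  contact bisection 50 iterations; distance minimised as its square (smooth
  at zero).  Ties in argmin resolve to the earliest time.
* The error-trajectory ideal release uses sample resolution throughout; all
  timing quantities are integer multiples of the sampling interval.
* Within wide, flat timing windows the exact argmin of the error is shallow
  and can wander by several ms under trajectory noise; this inflates late
  practice timing errors slightly and is the main caveat when interpreting
  small timing-error differences between well-aligned subjects.  The
  window-midpoint rule is exposed as a stability check.
* Scoring assumes the release state is exact; encoder quantisation and
  release-detection latency of real hardware are not modelled.
* Problem sizes: acceptance-level checks use 10 subjects x 6 days x 240
  throws per task, a 1000-state scorer-vs-oracle comparison, and
  96x96-to-300x300 grids — sizes at which every reported statistic is
  stable under the fixed seeds.
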