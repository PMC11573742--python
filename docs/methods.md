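# Methods

`fishvr` re-creates, entirely in software, the behavioral-computation stack
of a closed-loop 2D virtual-reality rig for head-fixed adult zebrafish: the
tail-tracking stage, the tail-to-force locomotion transform, the
game-engine-style rigid-body physics, the virtual Morris-water-maze (VMWM)
protocol, and the trajectory statistics used to quantify spatial learning.
Synthetic agents replace the fish, so every stage is testable on a desk
with no hardware and no animal data.

## Tail tracking

A top-view camera images the fish with the body along the image rows (row 0
= head).  Each frame is binarized (polarity configurable: the fish may be
darker or brighter than the platform), the largest connected component is
kept (smaller blobs are debris and produce a warning), and the centerline
is the sequence of per-row blob midpoints.  Rows where the blob splits into
several runs take the midpoint of the longest run.  The upper-body and
tail-end x positions are the means of the three uppermost and three
lowermost centerline points; their difference is the signed raw deviation
(positive = tail right of the upper body).

Because individual fish rest with a left/right bias that drifts over
minutes, deviations are referenced against a trailing-mean
**reference mid-position**.  The window is defined in *seconds* (default
10 s) and its sample count is `window_s x rate_hz`: the rig literature
quotes both "10 s" and "1000 data points", which only agree at a 100 Hz
camera; since the control loop runs at 10 Hz we treat seconds as the
invariant quantity and let the rate be a config field.  A noise threshold
(default 6 px, the midpoint of the practical 5-7 px range) is
*soft-subtracted*: `actual = sign(m) * max(|m| - thr, 0)` with
`m = raw - reference`.  The soft threshold keeps the left/right sign, which
the turn-direction rule needs; a hard zeroing would also discard
supra-threshold magnitude information.

The synthetic renderer draws a quadratically bent silhouette with a known
centerline; the tracking pipeline recovers the generator's tail deviation
with RMSE < 1 px over amplitudes 5-40 px (verified in the tests).

## Locomotion transform

The actual-movement signal oscillates during tail beats.  Its
**high-frequency ratio** (HFR) is computed from the magnitude spectrum of a
sliding FFT window:

    HFR = sum of |X(f)| for f in [1, 5] Hz / sum of |X(f)| for f in (0, 5] Hz

The 5 Hz upper edge is the Nyquist limit of the 10 Hz loop.  Choices the
source system leaves open, fixed here:

* **FFT window**: 32 samples (3.2 s at 10 Hz), sliding by one sample.
  Long enough to resolve the 1 Hz band edge, short enough to stay
  responsive; configurable.
* **DC handling**: the 0 Hz bin is excluded from numerator and denominator
  (any residual offset is already absorbed by the reference mid-position).
* **Amplitude = magnitude**, not power.
* An all-zero window returns HFR = 0 (0/0 convention); short warm-up
  buffers are zero-padded and flagged.

Running bounds `HFR_min`/`HFR_max` update continuously and persist across
trials within a session (they reset per agent).  The two forces are

    F_translation = gain_translation * ((HFR - HFR_min) * 10)^2
    F_rotation    = gain_rotation    * ((HFR_max - HFR) * 10)^2

with `gain_translation` defaulting to 0.75 (valid 0.5-1) and
`gain_rotation` to 0.12 (valid 0.1-0.15).  The squared terms make the two
regimes mutually exclusive: fast symmetric beats swim straight, slow or
one-sided beats turn.  Degenerate bounds (max = min) yield zero forces.
Turn direction: if the last two raw tail positions are both right of the
reference the turn is clockwise, both left counter-clockwise; when the
criterion is unmet the streaming transform holds the previous direction, so
an ongoing one-sided oscillation keeps turning the same way.

## Physics

A Unity-style point mass (mass 1, drag 1, angular drag 10000) integrated at
one step per 10 Hz control tick (dt = 0.1 s; the engine's finer internal
substep is not emulated — one deterministic step per force command).  Per
tick:

    v       <- (v + F_trans/m * dt) * max(1 - drag*dt, 0)
    w_eff   <- w + torque * dt                 # torque = +-F_rot, CW positive
    heading <- heading + w_eff * dt
    w       <- w_eff * max(1 - angular_drag*dt, 0)
    pos     <- pos + v * dt * (sin heading, cos heading)

With angular drag 10000 the angular damping factor clamps to zero: rotation
carries no momentum between ticks and is purely force-driven, while linear
motion coasts with the familiar geometric decay (terminal speed
`a F dt / (m (1-a))`, `a = 1 - drag*dt`; the simulation matches this closed
form to 1e-9).  Angles are stored in degrees (heading 0 = +Z, clockwise
positive, the engine's left-handed convention) but integrated in radians;
the torque scale is folded into `gain_rotation`, giving a maximum turn rate
of about 39 deg/s at the default gains — commensurate with the ~38 units/s
terminal swim speed on a 335-unit arena.  Speeds below 0.01 units/s snap to
zero so that a resting agent produces genuinely static frames for the
goal-headedness split.

The arena wall is impenetrable: a position leaving the disk is projected
back onto the circle and the outward radial component of the velocity is
zeroed, preserving tangential sliding.  The heading is deliberately left
unchanged — a reflecting wall would inject heading changes the agent never
commanded; the agent must steer away itself.

## VMWM protocol

Circular arena of radius 335 units; safe zone of radius 80 at (160, 160)
(5.7% of the arena area, under the 6% ceiling of the rodent maze it
mimics).  Trials are 120 s with a 30 s inter-trial interval (tail input is
ignored during the ITI; it is metadata, not simulated wall-clock, as is the
10-minute break after every ten trials and the 0.5-1 V shock voltage).
Each trial starts at one of four positions — (160, -292), (-160, -160),
(-292, 160), (0, 0); the first three equidistant (within 0.13%) from the
safe-zone center — with heading uniform on [0, 360).

Shocked-group agents receive a logged 300 ms shock pulse every 2 s from
trial onset.  "Reached the safe zone" is the agent center entering the open
disk (a point-mass model has no body extent).  Cessation on first entry is
permanent and shock is always off inside the zone; the control group is
never shocked.  The shock is an event flag only — synthetic agents ignore
it unless a policy chooses to react.

The zone is visible exactly while occupied.  Staying 5 consecutive seconds
inside (50 consecutive ticks; an exit resets the timer — sub-tick excursions
are invisible at this quantization) is a success, after which movement
stalls for the trial remainder; a trial whose final sample lies inside the
zone also succeeds.  A free-swim mode is the same arena with the safe zone
disabled.

## Synthetic data

* **Tail signals**: symmetric sinusoids, one-sided oscillations (the tail
  oscillating without crossing the midline, as occasionally seen in
  head-fixed fish — the drifting reference absorbs the bias), rest, and
  bout trains, with optional Gaussian pixel noise.
* **Random swimmers** (the chance-level construction): per tick, speed and
  turn are drawn *independently* from kinematic histograms and integrated,
  with wall projection as in the physics engine.  The default histograms
  emulate only the published shapes — a resting point mass at speed zero
  plus an exponential tail, and a symmetric zero-mean triangular turn
  distribution — scaled to the simulator's own dynamic range (speeds
  0-40 units/s, turns within +-4 deg/tick).  The exact bin contents of the
  rig histograms are not published; nothing here is fit to fish videos.
  The default ensemble is 300 trials from each start position (1200 total).
* **Goal-seeking agents** (positive control): pivot toward the safe-zone
  center when misaligned beyond 10 degrees (turn-only regime), swim
  straight when aligned (straight-swim regime), rest inside the zone.
  `strength` in [0, 1] is the per-tick probability of the goal-directed
  action versus a random one (0 reduces exactly to the random policy);
  `noise_deg` jitters the perceived bearing.  The parameter-recovery
  checks use strength 0.5 with 20 degrees of noise — a deliberately
  imperfect navigator that still reaches the zone reliably within 120 s.

What the generators deliberately do **not** model: visual cue use, learning
dynamics within a session, shock-induced freezing, bout-structured
kinematics correlated across ticks, and any fit to real fish statistics.
Passing tests therefore demonstrate that the *computational stack* is
correct and well-calibrated, not that real fish behave like the agents.

## Trajectory statistics

* **Straightness index** SI = D/L (endpoint displacement over path length),
  in [0, 1]; a zero-length path returns 0 by convention.
* **Cumulative distance**: per-frame distance to the safe-zone center
  summed until the success condition.
* **Success conversion rate**: successes / trials with at least one zone
  entry; undefined (NaN) without entries.
* **Moving success rate**: mean success of the trailing ten trials (the
  available prefix before the window fills).
* **Persistence maps** over an origin-centered square lattice of point
  places strictly inside the arena.  The default spacing of 10 units gives
  3521 places — the closest natural lattice to the ~3400 places of the
  original analysis, whose exact construction is not recoverable; the
  spacing is configurable and the count always reported, never assumed.
  Two definitions: mean distance reduction toward the place per moving
  frame (frames with no distance change are excluded; a place never moved
  relative to scores 0), and the baseline-corrected fraction of moves
  toward the place `(G/N - R)/(1 - R)` with R = 0.5, bounded in [-1, 1].
  "Toward" is a strict distance decrease; ties are excluded from both
  definitions.  Group maps are pointwise means of per-trial maps; group
  comparisons use a per-place two-sample Wilcoxon rank-sum test without
  multiplicity correction (matching how such p-value maps are presented).
  Note a subtlety verified numerically: an isotropic random walk does *not*
  have zero expected mean-reduction persistence — diffusive spreading makes
  the expected distance change toward any fixed place slightly negative —
  so null checks use rotational symmetry, not zero mean.
* **Goal headedness**: a frame is goal-directed when the *forward ray* of
  the head direction intersects the closed safe-zone disk (always true from
  inside).  The forward-ray reading was chosen over an infinite line, which
  would count frames facing directly away.  Frames are split into static
  (position unchanged from the previous frame, exact equality by default
  with a configurable epsilon for resampled data; frame 0 has no
  predecessor and is excluded) and moving; GH_static and GH_move are the
  goal-directed fractions of each class, NaN for an empty class.

With the four start positions and 2-minute trials the random-swimmer
ensemble shows elevated persistence in the upper-right quadrant — a purely
geometric artifact of the start layout (no start lies in the safe-zone
quadrant) — which fades when the trial length is quadrupled.  The
ensemble-scale checks quantify this with the upper-right-quadrant mean
minus the mean of the other three quadrants, on a 20-unit grid (877
places): the same lattice construction at a resolution that keeps the
1200-trial x 4801-frame computation inside a couple of minutes on one CPU.

## Learner classification

A shocked session is a **learner session** when it beats the day's
reference control session (highest success rate that day; ties broken by
lowest agent id) in all three of:

1. an exact one-sided binomial test of the whole-session success count at
   the reference session's success rate,
2. a one-sided two-sample Kolmogorov-Smirnov test that the session's
   full-window moving success-rate values (on the 0, 0.1, ..., 1 lattice)
   are stochastically higher than the reference's (shocked CDF below
   reference CDF), and
3. a one-sided two-sample Student t test (pooled variance; Welch available
   as an option) on the same series,

each at alpha = 1e-4, a fixed conservative Bonferroni-style threshold for
the hundreds of session-level tests such an experiment accrues (the test
count itself is data-dependent and not reproduced).  All three tests are
one-sided because the question is always "significantly higher".  A fish is
a **learner fish** when its chronologically last session is a learner
session.  The conjunction is conservative: under the null the binomial gate
alone holds the false-positive rate under alpha, and simulation over 10^4
null sessions finds a rate below 1e-3.  Synthetic reference sessions
reproduce the published reference rates (13.33%, 15%, 21.67% on days 1-3)
as exact success counts placed at random trial indices.

## Numerical and I/O choices

* One integration step per force command keeps every simulation
  deterministic given a seed; identical config + seed reproduce sessions
  byte for byte.
* All randomness flows through seeded `numpy` generators; the CLI records
  its seed and a config hash on every run.
* Trajectories are comma-delimited text (t, x, z, heading, v, omega, and
  the three flags) at 6 significant digits; -0.0 is normalized on write so
  round-trips are byte-stable.  Sessions are JSON with per-trial summaries.
* Degenerate inputs are defined, not crashed on: empty sessions have NaN
  success rate, stationary trajectories score 0 persistence, empty GH
  classes are NaN, 0/0 HFR is 0.

## Problem sizes

The ensemble-scale checks use 1200 random trials (and another 1200 at
quadrupled length) on the 20-unit grid, a 60-trial goal-agent session for
parameter recovery, 200 replicate sessions for classification power, and
100 random cases per statistic for oracle agreement — sizes chosen so the
whole verification runs in a few minutes on a single CPU while leaving
every comparison decisively resolved.

## Known limitations

* The engine emulation is a documented contract, not a bit-exact engine
  port: the source rig's 0.02 s substep, exact drag semantics and collision
  solver are not public.
* The grid producing exactly 3405 point places cannot be reconstructed;
  3521 (spacing 10) is the closest lattice.
* Success rates, SI/time/distance statistics and learner counts of real
  fish are animal data and are out of scope; the metrics that produced them
  are fully implemented and verified against oracles and synthetic agents
  instead.
* Whether the rig's shock resumed if a fish left the zone without success
  is not specified; cessation is implemented as permanent after first
  entry.
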