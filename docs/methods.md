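# Methods

## The swimmer and its hydrodynamics

The swimmer is three rigid spheres of radius `R` (default 0.1, in units of
the maximum link length `L`) joined by two extensible links of lengths
`L1`, `L2` in `[0.6, 1]`, with an actuated hinge angle `thetaA` in
`[2pi/3, 4pi/3]` at the middle sphere (`thetaA = pi` is the extended,
collinear shape).  Those bounds keep the spheres far enough apart for a
point-force (Oseen-Burger) description of the fluid coupling to hold.  At
zero Reynolds number sphere velocities are linear in the forces,
`V_i = sum_j H_ij F_j`, with the self mobility `I / (6 pi mu R)` and the
cross mobility `(I + r_ij r_ij / |r_ij|^2) / (8 pi mu |r_ij|)`.  Given the
three actuation rates (`dL1`, `dL2`, `dThetaA`, each capped at magnitude 1
in units of the characteristic rate `V_c`), the two link-kinematics vector
equations, the force-free condition and the torque-free condition close a
7x7 linear system in the six force components and the body rotation rate
of link 1.  The torque balance is taken about the centroid; since the
system is force-free the reference point is arbitrary, and the centroid
keeps the matrix well scaled.

Time integration is explicit Euler on the generalized coordinates
(`r1`, `theta1`, `L1`, `L2`, `thetaA`) at the gait time step `dt = 0.1`;
sphere positions are rebuilt from the generalized coordinates after every
step, so the link-reconstruction constraints hold to machine precision
with no kinematic drift.  The dynamics are quasi-static (no inertia), so
trajectories of prescribed strokes are nearly timestep-independent: the
net displacement of the four-phase swimming stroke changes by less than
1e-7 between `dt = 1e-3` and `dt = 1e-5`.  Actuation components whose
Euler step would leave a bound are zeroed before the solve (projection),
which keeps the projected dynamics force- and torque-free.

Verified properties: the assembled 6x6 mobility is symmetric positive
definite over random valid states; closure residuals are below 1e-10; a
reciprocal (time-reversed) stroke produces no net displacement as
`dt -> 0` (scallop theorem), and the net displacement per stroke cycle
scales as amplitude squared.  The amplitude-scaling measurement swings
both links symmetrically about a fixed mean length (0.8) so that only the
amplitude varies between runs; sweeping the amplitude by contracting from
full extension instead would change the mean geometry at the same time
and contaminate the fitted exponent with higher-order corrections.

## Locomotory strokes and the gait stage

Two controllers stand behind one interface
`controller(state, theta_T) -> actuation`:

* **Scripted oracle.**  A deterministic stroke script built from two
  closed cycles measured on the model: the four-phase
  contract/extend translation stroke (net displacement 0.0172 L per
  1.6-time cycle at amplitude 0.4, i.e. a swimming speed of about
  0.011 L per unit time), and a quadrature turning cycle (hinge swing
  paired with a link contraction, up to about 0.089 rad per 2.8-time
  cycle).  Because the swimmer has no intrinsic head or tail, the script
  aligns whichever end needs the smaller turn (exact 90-degree ties break
  counterclockwise) and swims tail-first by swapping the link order of the
  translation stroke.  The turn cycle's hinge swing is sized to the
  remaining error; below a 0.2 rad error the script stops turning and
  translates.  That threshold deliberately ignores small target wobble:
  during reinforcement-learning exploration the commanded direction
  fluctuates every sensing event, and a tighter threshold would make the
  swimmer spend nearly all its time in low-displacement turn cycles.
* **PPO gait predictor.**  A clipped-surrogate policy-gradient agent
  (two 128-unit hidden layers, generalized advantage estimation,
  clip 0.2) mapping the configuration `(L1, L2, thetaA)` and the heading
  error to the three actuation rates, rewarded by the centroid
  displacement projected on the target direction.  Discovering
  non-reciprocal stroke cycles from scratch takes on the order of
  millions of inner steps, so the default test suite only exercises the
  training mechanics; full training is run through the CLI
  (`swimchemo train-gait`).  All navigation-stage results in the test
  suite and the acceptance script therefore use the oracle controller,
  which makes them independent of gait-training quality.

## Chemical landscapes

All fields are closed-form functions of `(x, y, t)`, never rasterized:
the radially linear training field `C = 1 - r/20` (constant gradient
`dC/dr = -0.05`, negative values beyond `r = 20` left unclipped since
only differences are consumed); isotropic Gaussians of width `sigma` in
{2, 4, 6, 8, 10}; a log-normal profile along `x`
(`C = 5/(pi sigma^2) exp(-[ln(x+8)^2 + y^2]/(2 sigma^2))`, domain
`x > -8`, default `sigma = 1`); a two-peak Gaussian mixture (amplitudes
0.6/1.0, widths 2, centers (-5,0)/(5,0)) standing in for the irregular
multi-maxima landscape; and a fluctuating variant whose peaks drift at a
constant velocity, stretch radially as `sigma (1 + 3e-4 t)`, and whose
minor peaks breathe in amplitude through seeded smooth sinusoids — a
parametric, deterministic emulation of a drifting, deforming plume.  The
multi-maxima and fluctuating constructions are this package's own
parametric designs; published gait snapshots constrain them only
qualitatively (several maxima of different heights; a drifting global
maximum), so every check that uses them is structural rather than
numeric.

## The mapless navigator

A sensor at the centroid reads the field every 50 gait steps (5 time
units).  The navigator's state is the centroid displacement since the
last sensing event, the concentration change `delta_C`, and the
orientation `theta_c`; its action is a target direction handed to the
gait controller; the reward is `delta_C * alpha * |delta_r_c|` with
`alpha = 100`.  Episodes start on an annulus 8-15 L from the source
(uniform by area, uniform orientation, extended shape), and end on
entering the reach radius (the success criterion; checked at every
inner step) or at `t_max = 6000`.  Failed trials enter reach-time means
censored at `t_max`.

The reach radius defaults to 0.5 L.  The constraint that fixes it is the
shifted-source comparison: success discs of radius `r` around the
original and the displaced source (|shift| = sqrt(2)) must be disjoint,
i.e. `2r < 1.414`, or a baseline that merely station-keeps at the old
source counts as having reached the new one.  Half a swimmer length
satisfies that with margin while remaining a physically sensible
"arrived" criterion.  For the same comparison, start azimuths within 60
degrees of the displacement bearing are excluded
(`NavConfig.init_azimuth`): from those bearings any trajectory bound for
the *old* source transits the new source's disc on pure geometry, which
would credit a swimmer that senses nothing.  Both choices are
config-exposed; all success-rate results are conditional on them.

The learner is an entropy-regularized off-policy actor-critic (SAC) with
the clipped double-Q trick, polyak-averaged target networks
(`tau = 0.005`) and automatic entropy-coefficient tuning
(target entropy = -2), all networks two hidden layers of 128 units.  The
angle action is parameterized as a two-component direction head squashed
to `[-1, 1]^2` and mapped through `atan2`, which avoids the wrap
discontinuity at +-pi.  Two encoding choices matter and are deliberate:

* **Body-frame encoding** (default, `NavConfig.body_frame`): the network
  sees `delta_r_c` rotated into the swimmer's frame and emits its angle
  relative to `theta_c`, so the orientation enters through the frame
  itself.  The task is invariant under global rotations; encoding it
  this way removes that symmetry group from what the network must learn
  and makes the learned policy exactly rotation-equivariant — which is
  also what makes performance on a translated or rotated field
  mathematically identical to the training field.  Appending the raw
  `(cos, sin)` of `theta_c` as extra features
  (`NavConfig.absolute_orientation`) was measured to make policies
  azimuth-dependent (success varying by start bearing at fixed skill)
  and is off by default; the world-frame encoding of the state is
  available via `body_frame=False`.
* **Correlated warmup exploration**: initial random actions hold each
  direction for a geometric number of sensing events (mean 8) instead of
  resampling independently.  The swimmer's maximum body turn rate
  (~0.035 rad per time unit) means independently resampled directions
  produce only on-the-spot wiggling; held directions fill the replay
  buffer with the sustained runs from which the reward structure is
  learnable.

The map-based baseline is the same learner with the observation replaced
by absolute position and orientation `(x, y, cos theta_c, sin theta_c)`
and no chemical input; the reward is unchanged.  By construction it can
only memorize the training map, which is the behavior the mapless/map-
based contrast isolates.

## Training protocol and problem sizes

Navigator training is scaled to single-CPU budgets as the package's own
protocol.  Mapless training episodes start 2-9 L from the source — the
lower edge exercises the final-approach endgame, which starts at 8 L
alone leave undertrained — and are capped at 200 sensing events;
500 episodes by default.  The map-based baseline trains from 2-14 L
(its absolute-position observation only covers what it has seen), capped
at 300 events, 400 episodes.  Every 50 episodes the greedy policy is
evaluated on a fixed seeded protocol at the downstream study conditions
(starts 8-15 L, time limit tightened to 4000), and the best checkpoint
by (success rate, then mean reach time) is restored at the end; without
this selection the returned policy is whatever the last episode left
behind, and SAC policies keep drifting after they first become
competent.  Evaluations elsewhere use 10-20 trials at the full
conditions (annulus 8-15, `t_max = 6000`); the CLI runs the full
200-trial protocol.  The reproduction script trains the mapless
navigator for 350 episodes (its selected best checkpoints historically
appear by episode 300) and the baseline for the full 400.

The kinematic point-swimmer surrogate (unit step along the commanded
direction per sensing event) isolates the learner from the
hydrodynamics for the learning sanity check.  Its success radius is one
step length (1.0): a walker that hops a full unit per decision cannot
reliably enter a half-unit disc, so a smaller radius would measure step
quantization rather than the learner.

## Known limitations

* The Oseen-level mobility omits rotlet coupling, lubrication, thermal
  noise and boundaries; motion is strictly planar.
* The oracle's turning stroke, not the fluid, limits reorientation to
  ~0.035 rad per unit time, which makes target-direction changes take
  several sensing events to express — the dominant difficulty of the
  navigation learning problem at small sample budgets.
* The multi-maxima and fluctuating fields are parametric stand-ins; no
  quantitative claims are attached to them.
* Synthetic landscapes have no sensor noise; the only stochasticity in
  an evaluation episode is the initial condition.
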