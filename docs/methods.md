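# Methods

## The model

`posturesim` simulates quiet standing and perturbed balance of a planar,
muscle-driven multi-link body whose feet are rigidly attached to a
horizontally translating platform, under a neural controller that combines
constant feed-forward muscle activations with delayed proportional-
derivative (PD) feedback on muscle length and lengthening velocity.

### Plant

The body is a serial chain of rigid links (ankle-knee-hip in the sagittal
plane; subtalar-lateral-bend in the frontal plane).  Platform translation
enters the equations of motion as an inertial forcing term: in the platform
frame every link's centre of mass feels a horizontal pseudo-force
`-m * base_acc`.  There is no foot-ground contact model; the base motion is
purely kinematic.  The equations are the classic compound-pendulum form in
absolute link angles and are integrated with fixed-step explicit RK4 at
dt = 1 ms; the passive conservative chain drifts in energy by less than
0.1 % over 5 s at this step (tested).  Activation states use the same step
so the 40 ms neural delays fall exactly on the sample grid and delay reads
need no interpolation.

A fall is declared when the whole-body CoM height drops below
`fall_height_fraction` (default 0.9) times the initial CoM height; a
full-scale configuration may instead pin the absolute threshold (0.9 m for
a standard 72 kg / 0.914 m anthropometry).

### Muscles

Each actuator is Hill-type with a rigid tendon:

    F = F0 * (a * f_L(l) * f_V(v) + f_PE(l)),

with `f_L` a Gaussian of width 0.45 centred at the optimal fiber length,
`f_V` the standard hyperbolic concentric branch (shape constant 0.25) and
a slope-continuous eccentric branch saturating at 1.4, and `f_PE` an
exponential that reaches one normalized force at 60 % passive strain.
Muscle paths are affine: constant per-joint moment arms, so the length-
torque duality (moment arm = negative length gradient) is exact and
tested.  The fiber length is musculotendon length minus a constant slack;
series elasticity is omitted to avoid a stiff internal state that the
normalized force expression does not need.

### Controller

    u_i(t)    = u_ff,i + u_fb,i(t), clipped to [0.001, 1]
    u_fb,i(t) = k_p,i (L_i(t - tau_fb) - L0_i)/L0_i
              + k_d,i Ldot_i(t - tau_fb)/V_max,i

with `tau_fb = tau_trans = 40 ms`, and first-order activation dynamics
whose time constant is `t_act (0.5 + 1.5 a)` (10 ms scale) when the
delayed control exceeds the activation and `t_deact / (0.5 + 1.5 a)`
(40 ms scale) otherwise.  The total sensing-to-activation latency for a
kinematic pulse is exactly `tau_fb + tau_trans` = 80 ms on the sample
grid plus the activation lag, a physiological ~120 ms neurological delay.
Muscles in the same group share PD gains.  The clipping policy (lower
bound 0.001) is our choice; the unclipped sum is logged for diagnostics.

### Perturbation

The platform follows a quintic smoothstep, 3 cm in 200 ms by default, with
displacement, velocity and acceleration continuous and the first and
second derivatives zero at both ends.  Directions follow the standard
12-direction protocol (30 degree spacing, 0 = rightward, 90 = forward);
the direction's sine drives the sagittal plant and its cosine the frontal
plant, and responses of a full 12-direction run are composed per muscle
across the two plants.  Perturbation onset defaults to 500 ms.

## Two-stage parameter adjustment

**Stage 1 (feed-forward generation).**  With zero delays, zero
feed-forward and PD gains taken from the per-group ratio table scaled by
sweep factors (P, D), the closed loop is run unperturbed for 5 s.  When the
plant stands the whole horizon, the time-average of each muscle activation
over the 3000-5000 ms window becomes a feed-forward candidate `u_ff`; its
squared norm indexes whole-body tone.  The printed integration bounds of
the averaging formula appear in reversed order in the source description;
we integrate over [3000, 5000] ms and divide by 2000 ms, the only reading
that yields positive averages.  Candidates with identical norms (within
1e-9) are deduplicated, and `select_by_norm` picks candidates closest to
equally spaced norm targets.

**Stage 2 (gain optimization).**  For a selected `u_ff` and each
perturbation direction, per-group PD gains are optimized with CMA-ES
against

    J = w_fail (T_simu - T_fall)/T_fall + w_pos sum_j int |theta_j(t) - theta_j(0)| dt

with `w_fail = 10000`, `w_pos = 1`, `T_simu = 5000 ms`.  The literal
deviation integral would integrate signed deviations, which oscillation
could cancel; we use absolute deviations.  At `T_fall = 0` the 1/T_fall
pole is replaced by a 1e9 sentinel to keep CMA-ES ranking finite.  Gain
nonnegativity (and any upper bound) is enforced by reflecting sampled
points into the box before evaluation, which leaves the CMA-ES ranking
identical to evaluating the reflected points.  The full-scale defaults are
population 18, initial step 0.005 and 1500 iterations; the desk-scale
fixture protocol uses population 8, initial step 0.4 (matched to its
order-one gains) and at most 50 iterations with early stopping once a
standing solution is found.

CMA-ES itself is implemented in the package: the standard
(mu/mu_w, lambda) strategy with weighted recombination, cumulative
step-size adaptation and rank-1 + rank-mu covariance updates, fully
deterministic for a fixed seed.  Tests verify convergence on shifted
spheres and Rosenbrock, seeded determinism and bound handling.

### Posture-matched stage 2

A candidate's feed-forward vector is measured at the posture the
zero-delay run settles into, not at the nominal initial pose.  Re-applying
it at the nominal pose would make high tone act as a directional bias (the
tone holds a posture the plant is not in), which at desk scale — with one
lumped actuator pair per joint instead of seventy muscles — dominates its
stabilizing effect.  Stage 2 therefore starts each candidate from the
posture its tone actually maintains: the mean pose of the generating run
over the averaging window becomes the initial pose, and the feedback
target lengths are recomputed there.  This mirrors quiet stance, where
posture and tonic activation are mutually consistent, and leaves intrinsic
muscle stiffness and damping as the tone's only dynamic effect.

### Reflex-gain ceiling

Fixture optimizations bound the proportional gains at 3.5 times the ratio
table and the delayed velocity gains at a flat 1.0 per group.  Delayed
velocity feedback is physiologically limited (it amplifies sensor noise,
and at an 80 ms loop delay it feeds energy into the fast knee/hip modes);
beyond the ceiling, damping must come from the muscles' own
force-velocity slope, which scales with feed-forward tone.  This is the
mechanism behind the headline behaviour on the fixture: the highest-tone
candidate stands in all 12 directions within a few CMA-ES iterations,
while the lowest-tone candidate cannot be stabilized for a backward
translation within the full budget at any tested seed.

## Evaluation pipelines

**Directional responses.**  The response magnitude of a muscle for one
direction is the baseline-subtracted integral of its activation 70-270 ms
after perturbation onset (baseline: mean activation 50-150 ms before
onset), in seconds.  The printed lower integration bound (0) conflicts
with the stated 70-270 ms observation window; we integrate 70-270 ms, the
window that matches the comparison protocol.  Twelve-direction vectors are
normalized to [0, 1] by the maximum (negatives clipped to 0) for radar
display and min-max mapped to [-1, +1] for cosine similarity.  The null
distribution of similarities against a reference vector is estimated from
100,000 random vectors with components uniform on [-1, 1]; its standard
deviation is ~1/sqrt(12) = 0.289, and observed similarities are placed on
the null with a normal-approximation CDF.

**Passive ankle stiffness.**  Over 0-70 ms after onset of a backward
(270 degree) translation — before reactive activation changes can act —
the ankle torque attributable to passive elasticity plus the active force
of the feed-forward component (using a_ff, not the instantaneous
activation) is regressed on ankle angle, velocity and acceleration
(central differences, endpoints dropped):
`T = K theta + B theta_dot + I theta_dd + C`, with theta in degrees so K
is in N m/deg.  Relative stiffness is `2 K_rad / (m g h)` with K converted
to per-radian; values below one mean passive mechanisms alone cannot
stabilize the inverted pendulum.  The torque-angle generator used as the
fitting oracle builds its derivatives with the same central-difference
operator, so the noiseless fit recovers the generating coefficients to
machine precision.

On the fixture plants the stiffness trend is measured on the single-link
ankle inverted pendulum — the plant the critical-stiffness concept is
defined on — with a gentle 1.5 cm probe translation rather than the
standard 3 cm.  On a rigid-foot kinematic base the 0-70 ms window sees
only a fraction of a degree of ankle rotation, while the force-velocity
torque scales with the platform velocity: at 3 cm amplitude its nonlinear
remainder (beyond what the viscosity term absorbs) is an order of
magnitude larger than the `K theta` signal and the regression cannot
identify K.  Stiffness is a linear-regime quantity, and small-amplitude
probes are standard practice in experimental ankle-stiffness estimation;
at 1.5 cm the fit identifies K deterministically, the tone trend is
positive, and every relative stiffness lies strictly between 0 and 1.
The deepest-droop candidates sit beyond the optimum of the active
force-length curve, where rising tone no longer raises stiffness — the
trend is therefore monotone over most of the tone range with
high-tone exceptions, matching the qualitative full-scale picture.

## Fixtures and what they do (and do not) show

The fixture plants use standard anthropometry (72 kg total, CoM ~0.914 m
above the ankle) and lumped group-equivalent actuators whose maximum
isometric forces aggregate both legs' muscles of a group; they are sized
so that recovery from the standard 3 cm translation genuinely engages the
activation ceiling, which keeps the standing problem nontrivial.  All
muscles sit at normalized fiber length 0.94 in the initial pose (ascending
limb), so stretch raises active force and tone contributes real intrinsic
stiffness and damping.  The fixture gain table is the standard 11-group
ratio pattern multiplied by 36 to map the dimensionless gains onto the
lumped-actuator normalization.

Desk-scale results demonstrate that every computational stage behaves as
specified and that the qualitative phenomena (tone-dependent standing,
subcritical and tone-increasing passive stiffness) are reproduced by the
mechanism built into the model.  They do not reproduce full-scale numbers
that depend on the 70-muscle, 15-DoF anatomy or on external EMG reference
data (directional gain trends, specific similarity values, the absolute
stiffness table), and the frontal plant's symmetric two-link chain cannot
express asymmetric strategies.  Sizes used here: 12-point (P, D) sweep
grids, 3 selected candidates, CMA-ES with population 8 and at most 50
iterations per direction.

## Numerical choices and degenerate inputs

- dt is capped at 1 ms; delay lags that are integer multiples of dt are
  read exactly, others by linear interpolation; reads before t = 0 return
  the initial value (system at rest at target before start).
- Simulations start with activations equal to the clipped feed-forward
  vector (tone established before t = 0).
- Runs are truncated at the first sample below the fall threshold;
  non-finite states raise a divergence error carrying the partial
  trajectory, which the objective treats as an immediate fall.
- `normalize_unit_max` rejects all-nonpositive vectors; `normalize_signed`
  rejects constant vectors; the stiffness fit rejects rank-deficient
  designs (e.g. constant angle); cosine similarity rejects zero vectors.
- Selection ties in `select_by_norm` break toward the smaller norm.

## Known limitations

- Rigid tendon, constant moment arms, no pennation; no foot-ground
  contact, so centre-of-pressure constraints and heel-off are absent.
- Only proprioceptive feedback (muscle length/velocity); no visual or
  vestibular channels, no intermittent control.
- The desk-scale failure of the lowest-tone candidate depends on the
  reflex-gain ceiling; with unbounded delayed velocity gains the
  three-link chain can be stabilized at any tested tone.
- Frontal and sagittal plants are dynamically uncoupled; diagonal
  perturbations are handled by projection and per-muscle composition.
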