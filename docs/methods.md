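# Methods

## Model

The package optimizes deterministic (open-loop) controls of stochastic
plants over the induced dynamics of the state's first two moments.  The
modelling assumption is that movement *planning* fixes u(t) ahead of
execution: no state estimate is fed back during the movement, so the only
way the controller can influence trial-to-trial variability is through
the plant's control-dependent mechanics (stiffness/viscosity raised by
co-contraction) and through control-dependent noise.

For bilinear drifts — linear in the state with control–state product
terms N_i u_i x — the state is a Gaussian process and the mean/covariance
ODEs are exact, as is the reduction of the expected quadratic cost to a
deterministic functional of (m, P, u).  For general drifts the package
uses first-order Gaussian statistical linearization: m follows the drift,
P follows the Lyapunov equation driven by the drift Jacobian F(m, u, t)
evaluated along the mean.  This closure is exact whenever the drift is
affine in the state at fixed control (true for every 1-dof plant shipped
here, where the nonlinearity lives in the controls) and approximate for
the two-joint arm.  State-dependent diffusion is closed by evaluating
G at the mean, G(m,u,t)G(m,u,t)'; richer closures are out of scope.  The
quality of the closure is testable by forward Euler–Maruyama ensembles
(`sooc.simulate`), and the test-suite does so.

## Plants and parameters

* **Antagonist-pendulum forearm** (posture): I θ'' = T(u1−u2) −
  K(u1+u2)θ − bθ' + mgl_c sin θ + noise, with the upright unstable
  orientation at θ = 0.  Defaults: m = 1.44 kg, l_c = 0.21 m,
  I = 0.0588 kg m², b = 1 N m s/rad, T = K = 1, acceleration noise
  G = (0, 0.1)'.  A hand-held load (m_load = 2.268 kg at l = 0.35 m)
  raises I by m_load l² and the gravity coefficient by m_load g l.  The
  "joint stiffness" reported for this plant is the muscular part
  K(u1+u2), compared against the destabilizing gravitational level
  mgl_c.
* **Joint-level torque/stiffness plant**: state (Θ, Θ', Δ, Δ') where Θ is
  a reference trajectory obeying rigid-body dynamics under the net torque
  control τ, and Δ the stochastic deviation, stiffened by the control
  κ ≥ 0.  The damping co-modulates with stiffness so that the deviation
  subsystem keeps a constant damping ratio ζ = 1/2 for every κ: damping
  torque 2ζ√(I K_s κ) Δ'.  (The source material prints "K_d = I K_s"
  next to the ζ = 1/2 statement; the two are dimensionally incompatible
  and the constant-damping-ratio reading is implemented.)  K_s is not
  printed anywhere; K_s = 1 is used, making κ the joint stiffness in
  N m/rad.  Torque-multiplicative noise: diffusion 0.2 τ / I on Δ''.
  Since the Θ subsystem is deterministic and decoupled (horizontal
  plane), its covariance rows are structurally zero; the transcription
  pins them and drops their (identically zero) defect rows.
* **One-joint two-muscle arm**: muscle torque τ_i = −a_i T_i with tension
  T_i = (k0 + k u_i)(r_i u_i + (l0 − lm_i) + a_i θ) + (b0 + b u_i) a_i θ',
  all coefficients from the published single-joint parameter set
  (I = 0.0588 kg m², k = 1621.6, k0 = 810.8 N/m, b = 108.1,
  b0 = 54.1 N s/m, a = 2.5 cm, r_i = ∓2.182 cm, l0 − lm = −5.67 / −0.436
  cm).  Activations enter torque, stiffness and viscosity, so
  co-contraction stiffens the joint.  Noise (co-contraction-aware,
  acceleration level): d(|u1−u2|^1.5 + 0.01|u1+u2|^1.5) with d = 4.
* **Two-joint six-muscle arm**: standard planar two-link rigid-body
  dynamics with constant moment arms and muscle tensions of the same
  affine form.  The published six-muscle coefficients live in an external
  reference; the shipped defaults are a **surrogate** set (anthropometric
  two-link values; one-joint-style muscle coefficients for all six
  muscles; rest lengths anchored so passive stretch vanishes at the
  mid-reach posture).  Only ordering/property-level claims are made for
  this plant — stiffness and effort orderings across field gain, variance
  weight and noise level, and variance-geometry properties — never exact
  numbers.  Additive torque noise is mapped through M(q)^{-1} (a
  state-dependent diffusion, closed at the mean).

## Tasks

* Posture hold: R = I, Q = Q_f = diag(1e4, 1e3), t_f = 5 s, final mean
  pinned at zero, final covariance free.
* Cyclic joint-level reach: effort τ² + ακ², running + terminal deviation
  variance q_var(E[Δ²] + q_v E[Δ'²]); equal initial and final covariance
  (cyclic constraint); defaults q_var = 1e4, α = 1, q_v = 0.01,
  I = 0.072 kg m², b = 0.
* Muscle-level reach: effort u'u, terminal covariance penalty
  q_var·diag(1, 0.1) (radian units); mean driven 25° → 65° as a hard
  terminal constraint from zero initial covariance.  Activation bounds
  are [0, ∞): the published effort of the strongly co-contracted
  condition implies mean activations slightly above 1, so no upper bound
  is imposed (a cap is configurable).
* Two-joint reach: effort + ½|mean Cartesian acceleration|² (smoothness,
  computed symbolically by differentiating the forward kinematics through
  the drift) + q_var times the task-space terminal positional covariance,
  either its trace (point target, mean pinned) or its projection onto a
  line normal (point-to-line task, where the mean endpoint is constrained
  onto the line and final mean velocity to zero).

## Transcription and solver

The equivalent deterministic problem is transcribed with trapezoidal
collocation over the stacked moment state z = (m, vech P): the
n(n+1)/2-entry upper triangle parameterizes the covariance, which keeps P
symmetric by construction and removes redundant states.  All NLP
derivatives (defects, objective, terminal constraints) are exact,
generated once per plant with sympy and evaluated vectorized over nodes.
No PSD projection is applied during optimization; PSD is asserted post
hoc with tolerance 1e-8 (the Lyapunov-form dynamics preserve it).

The NLP is solved with scipy.optimize: SLSQP by default (fast, certifies
a KKT point), `trust-constr` or a hybrid (interior-point exploration +
SLSQP polish) for the larger/stiffer problems where SLSQP's line search
stalls from a cold start.  The objective handed to the solver is
normalized by its value at the initial guess so that the stopping
tolerance acts on an O(1) quantity.  Initial guesses: constant (or
task-supplied) controls, linearly interpolated means, covariance obtained
by forward Runge–Kutta propagation of the moment ODEs (clipped for
unstable plants); for the posture task the guess control is a stabilizing
co-contraction 20% above the divergence level; warm-starting one solve
from a related one is supported and used in the test-suite.  Degenerate
NLP directions from deterministic subsystems (structurally zero
covariance rows) are pinned and their 0 = 0 defect rows removed —
scipy's SLSQP rejects rank-deficient equality sets otherwise.

Grid sizes: 100 nodes for the 1-dof reaching/posture problems, 60 for the
cyclic joint-level task, 40 for the two-joint tasks (the test-suite uses
30–32 for the two-joint orderings; the optimal cost moves by well under
0.5% on grid doubling, which the suite checks).  Quadrature for the
running cost is trapezoidal on the same grid as the defects.

Moment propagation outside the NLP uses adaptive RK45 (rtol 1e-9) or
fixed-step RK4 on the transcription grid.  Euler–Maruyama ensembles use a
1 ms default step, independent Gaussian increments, divergence flagging
at |state| > 1e6 or NaN, and a recorded seed; validation compares sample
and predicted moments elementwise in standard-error units (default
threshold z = 4).

## Serialization

Trajectories are written as CSV (t, u_j, m_i, P_ij upper triangle,
row-major; a plain-text schema file accompanies each run) plus a JSON
manifest with solver status, options, seed and the cost breakdown.
Metrics reported by the table writers are always recomputed from the
serialized trajectory, never cached.

## Co-contraction index

The activation-overlap definition IC = 100·2∫min(u1,u2)/∫(u1+u2) is the
default; IC = 100·∫min/∫max is shipped as `min_over_max`.  The index
definition used by the experimental studies this task imitates is not
part of the reproduced material, and the index is the one reach metric
that is sensitive to it: for the standard (t_f = 475 ms, q_var = 50)
reach the same optimal trajectory scores 66.8% (overlap) or 50.2%
(min-over-max), while endpoint std, peak velocity and effort match the
published values to better than 1.2%.  Multi-start solves converge to the
same optimum and forcing lower co-contraction strictly worsens the cost,
so the discrepancy is attributable to the index definition, not to the
solution.  `scripts/acceptance.py` reports the min-over-max values.

## What the simulations do and do not show

The synthetic experiments are solved under the exact modelling
assumptions above: Gaussian (or Gaussian-closed) state distributions,
noise-free parameters, no activation dynamics, no tendon compliance, no
reflex circuitry, movement durations fixed a priori.  Passing tests show
that the moment reduction, the transcription and the metrics are
internally consistent and reproduce the published 1-dof numbers; they do
not show that the surrogate two-joint parameter set matches any
particular human arm, nor that real motor variability is Gaussian.

## Known limitations

* Hermite–Simpson transcription is declared in the options enum but not
  implemented; only trapezoidal collocation is available.
* The mean-evaluated closure for state-dependent diffusion ignores the
  covariance's effect on E[GG']; acceptable here because M(q)^{-1} varies
  slowly over the reach workspace.
* The uncontrolled-posture divergence is slower than the "about one
  second" sometimes quoted for this setup: with b = 1 N m s/rad and
  G = (0, 0.1)', half of the sample paths exceed |θ| > 30° only by
  ≈ 2.4 s (all by 4 s).  The qualitative instability statement is what
  the tests assert.
* Free-final-time problems, closed-loop (feedback-gain) optimization and
  non-Gaussian closures are out of scope.
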