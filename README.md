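# sooc — stochastic optimal open-loop control of musculoskeletal plants

`sooc` plans feedforward (open-loop) motor commands for noisy
musculoskeletal systems.  Instead of optimizing a feedback law, it asks:
what deterministic control u(t) minimizes an expected cost when the plant

    dx_t = f(x_t, u(t), t) dt + G(x_t, u(t), t) dw_t

is driven by noise and no state feedback is available during the movement?
For such systems the controller can still shape trial-to-trial variability
— by co-contracting antagonist muscles it raises joint stiffness and
viscosity, which attenuates the noise without producing net torque.  The
package exists to study exactly that trade-off: when is muscle
co-contraction (mechanical impedance) worth its effort cost?

## The reduction at the core

Because u(t) is deterministic, the first two moments m(t) = E[x_t] and
P(t) = Cov[x_t] obey closed ordinary differential equations.  For a
bilinear drift (A + Σ_i N_i u_i) x + B u they are exact:

    m' = (A + Σ N_i u_i) m + B u
    P' = (A + Σ N_i u_i) P + P (A + Σ N_i u_i)' + G G'

and the expected quadratic cost reduces identically to

    C(u) = ∫ (u'Ru + m'Qm + tr(QP)) dt + m_f'Q_f m_f + tr(Q_f P_f),

a deterministic optimal-control problem in (m, P, u).  For nonlinear
plants the same structure holds under Gaussian statistical linearization,
with A replaced by the drift Jacobian along the mean.  `sooc` transcribes
this deterministic problem trapezoidally (node-wise controls and moment
states, defect equality constraints) and solves the resulting NLP with
exact, symbolically generated derivatives.

Built-in plants:

* an inverted-pendulum forearm with an antagonist muscle pair (posture),
* a joint-level plant with separate net-torque and stiffness controls,
* a one-joint two-muscle arm whose activations set both torque and
  intrinsic viscoelasticity (printed parameter set),
* a two-joint six-muscle arm (surrogate parameter set), optionally inside
  a divergent force field F = βx.

Noise models: constant acceleration-level noise, torque-multiplicative
noise, and a co-contraction-aware signal-dependent noise for which
balanced activation is ~100× quieter than reciprocal activation at the
same total drive.

## Worked example

Reproduce the fast co-contracted elbow reach (40° in 400 ms under
signal-dependent noise, terminal-variance weight q_var = 500):

```python
import sooc

plant = sooc.kk_onejoint()                       # printed muscle params
task = sooc.missenard_cost(q_var=500.0, t_f=0.400)
problem = sooc.OCProblem.from_task(plant, task)
traj = sooc.solve(problem, sooc.SolverOptions(n_nodes=100))
print(traj.status)
print(sooc.reach_summary(traj))
```

prints

```
converged
{'EPstd_deg': 1.8929491090391188, 'PV_deg_s': 177.54137816520813,
 'Effort': 0.9469854130127517, 'IC_pct': 90.1311815997587}
```

i.e. the optimal strategy reaches the 5°-wide target with a terminal
positional standard deviation of 1.89° (comfortably inside the target)
at a 178°/s peak velocity, but pays for it with a large effort
(0.947 = 94.7 on the ×10⁻² scale) spent mostly on co-contracting the
flexor and extensor — the co-contraction index is 90% under the
activation-overlap definition (82% under min-over-max).  Dropping q_var
to 1 makes the solution almost purely reciprocal (IC < 0.5%) and the
endpoint scatter grows to 3.35°.

The same machinery runs from the command line:

```bash
sooc presets                      # list built-in experiments
sooc solve missenard_cocontract --out runs/fast
sooc simulate hogan_unloaded --out runs/posture --paths 500
sooc table1 --out runs/table
sooc report runs/fast
```

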