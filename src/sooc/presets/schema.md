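# Experiment config schema (YAML)

```yaml
preset: missenard_cocontract     # required; see `sooc presets`
overrides:                       # optional; preset keyword arguments
  t_f: 0.4                       # movement duration [s]
  q_var: 500.0                   # terminal-variance weight (rad^2 units)
  n_nodes: 100                   # transcription grid size
solver:                          # optional; SolverOptions fields
  method: slsqp                  # slsqp | trust-constr | hybrid
  nlp_tolerance: 1.0e-10
  max_iterations: 500
```

Preset keyword arguments (all optional, with the published defaults):

* `missenard_*`: `t_f` [s], `q_var`, `d` (signal-dependent noise gain),
  `n_nodes`.
* `hogan_*`: `t_f` [s], `n_nodes`.
* `bennett_cyclic`: `t_f`, `q_var`, `alpha`, `q_v`, `amplitude` [rad],
  `n_nodes`.
* `burdet_*`: `q_var`, `beta` [N/m], `sigma` [N m], `t_f`, `n_nodes`.
* `point_to_line_*`: `q_var`, `sigma`, `n_nodes`.

Angles in user-facing reach configs are degrees (reports are deg, deg/s);
cost weights act on radians internally.
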