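# somadev

Embodied emergence and early sensorimotor development, at desk scale.

`somadev` is a research simulator for a question at the root of
developmental robotics and computational neuroscience: how much behaviour
and brain organization can emerge from *uncoupled* per-actuator controllers
whose only communication channel is the physical body they share?  The
package implements that principle twice:

* **An insect-like robot.**  Twelve legs, each driven by its own chaotic
  quadratic map `f(x) = 1 − αx²` (chaotic for `α ≥ 1.4011…`) reading only
  that leg's joint angle.  Coupled through the disc body and anisotropic
  foot-ground traction, the maps entrain into a phase pattern that propels
  the robot; hitting a wall collapses the pattern and a new one — and a new
  heading — emerges within a fraction of a second.
* **A simplified human fetus.**  Twenty muscles, each with its own
  FitzHugh–Nagumo (Bonhoeffer–van der Pol) central-pattern-generator
  oscillator and afferent feedback, a skin of ~300 tactile elements, fluid
  or flat-plane environments, Hebbian tactile→motor spinal learning, and a
  spiking cortical sheet (LIF + STDP, exactly 5:1 excitatory:inhibitory)
  that passively learns the receptor stream and self-organizes body-part
  response maps.

The analysis layer provides Lyapunov exponents, phase-locking values and
phase-constellation similarity, detrended fluctuation analysis, jerk- and
contact-event rates, body-map segregation and multimodal-integration
indices.

## A worked example

```
$ python examples/chaos_onset.py
alpha=1.00: lyapunov exponent = -13.4689 nats/iter (periodic)
alpha=1.30: lyapunov exponent = -0.4279 nats/iter (periodic)
alpha=1.50: lyapunov exponent = +0.2417 nats/iter (chaotic)
alpha=2.00: lyapunov exponent = +0.6931 nats/iter (chaotic)

chaos onset (bisection on exponent sign): alpha = 1.4012
lyapunov exponent at alpha=2: 0.6931  (ln 2 = 0.6931, tent-map conjugacy)
```

The onset is the period-doubling accumulation point of the controller map;
above it each leg receives an aperiodic drive.  Running the emergence
experiment itself:

```
$ python examples/insect_locomotion.py
per-seed net displacement (m): [0.26, 0.461, 0.17, 0.226, 0.259]
per-seed phase-stabilization time (s): [0.495, 0.495, 0.495, 0.495, 0.495]
median displacement: 0.259 m
[PASS] displacement_above_passive_baseline
[PASS] stable_plv_within_deadline
```

A passive robot never moves, so every centimetre of displacement is
emergent; the half-second stabilization time is the transient from random
leg motion to a standing inter-leg phase pattern.  The other scripts in
`examples/` run the wall-adaptation, body-map, closed-loop-development and
synthetic-stream analyses the same way, each printing the quantities it
computes and a line on what they mean.

The `somadev` command-line tool wraps the experiment families
(`somadev insect-locomotion|wall-adaptation|bodymap|multimodal|closedloop`,
with `--seed/--seeds/--config/--outdir/--export-csv` and `--full` for
paper-scale 1000 s sessions) and writes JSON reports.

## Layout

```
src/somadev/
  controllers.py        chaotic-map and BVP/spinal controller elements
  embodiment/           bodies, environments, reduced 2D physics, receptors
  spinal_plasticity.py  Oja-style Hebbian tactile->motor learning
  cortex/               LIF+STDP spiking sheet (numba kernel)
  metrics.py            Lyapunov, PLV/constellation, DFA, event rates, maps
  fixtures.py           synthetic streams and scripted trajectories
  experiments/          the four experiment families + reports
docs/methods.md         model equations, defaults, design choices, limits
examples/               one narrative script per capability
```

See `docs/methods.md` for the governing equations, every default with its
rationale, and the model's known limitations.
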