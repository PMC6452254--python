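# Model and methods

`somadev` simulates the emergence of embodied behaviour from per-actuator
controllers that never talk to each other directly: all coordination must
arise through the shared body and its environment.  Two embodiments are
implemented — a radially symmetric multi-legged robot driven by chaotic
maps, and a simplified sagittal human fetus driven by spinal
FitzHugh–Nagumo oscillators — together with a Hebbian spinal learning loop
and a scaled-down spiking cortical sheet that learns the receptor stream.

## Controller elements

**Quadratic map.** Each leg's element iterates `f(x) = 1 - alpha*x**2` on
the convex mixture `(1-eps_self-eps_mix)*s + eps_self*u + eps_mix*mean(u)`
of its sensor, its own previous output and the population mean.  The map is
chaotic for `alpha` above the period-doubling accumulation point at
1.4011…, which `metrics.chaos_onset_alpha` recovers by bisection on the
sign of the Lyapunov exponent (orbit average of `ln|2*alpha*x|`; at
`alpha=2` the tent-map conjugacy gives exactly `ln 2`).

Defaults: `alpha=1.9`, `eps_self=0.5`, `eps_mix=0.05`, sensor scale
0.45 rad, control tick 30 ms.  The large self-iteration share is a
structural requirement, not a tuning nicety: with a sensor-dominated input
the closed map/spring/mass loop always possesses a stable mechanical fixed
point.  Writing the quasi-static loop as `K*theta = tau_max * f(theta /
theta_scale)`, the parabola and the spring line always intersect on the
branch where `f' < 0`, i.e. where the feedback *adds* stiffness; the leg
either freezes there or jams at a joint limit (both observed).  Only when
the element retains roughly half of its own iterate does it keep producing
an autonomous chaotic drive which the body then filters and couples.  The
30 ms tick places the map's spectral content at the legs' ~5 Hz mechanical
resonance.  Both parameters are configuration; the shipped values are the
ones under which locomotion reliably emerges.

**BVP / FitzHugh–Nagumo oscillator.**  `dv/dt = c(v - v^3/3 - w + drive)`,
`dw/dt = (v + a - b w)/c` with the classic `a=0.7, b=0.8, c=3`,
semi-implicit Euler at 1 ms, and a `time_scale` of 12 model-units/s so the
limit cycle period is ~0.8 s (slow fetal movement tempo).  Zero drive gives
a unique rest state at `v = -1.1994`; tonic drive 0.875 puts every muscle's
oscillator on its relaxation limit cycle.  Oscillators are initialized at
independent uniformly random phases *along the limit cycle* — generic
initial conditions would otherwise bunch the phases and antagonist pairs
would cancel.

**Spinal unit.**  One oscillator per muscle; spindle length/velocity
afferents pass through a gamma gain, tendon tension bypasses it, and the
squashed sum modulates the oscillator drive (gain 0.3).  The afferent signs
are movement-assistive (`w_length=-1, w_velocity=-0.3`): a classic
stretch-excites reflex was also implemented and phase-locks each antagonist
pair into co-contraction, freezing the body — a stabilizing reflex is the
wrong default for a system whose purpose is generating exploratory
movement.  Activation is `clip((v + 1.2)/2.4, 0, 1)`.

## Body and physics

Bodies are trees of rod segments with rotary joints (torsional springs,
viscous damping), antagonist muscle pairs with a Gaussian length–tension
overlap factor, and skin taxels on both surfaces of every segment.  The
dynamics are a *reduced* articulated model: each joint integrates a 1-DOF
equation with a fixed rest-pose subtree inertia, plus a 3-DOF rigid base;
point forces are projected onto ancestor joints with cross products.
Inertial coupling and Coriolis terms are neglected.  Consequences: energy
bookkeeping is exact for the modelled terms (the passive-dissipation tests
pass machine-tight in fluid), but exact global force balance is not
guaranteed when joints saturate at their limits — the static ground
reaction tracks the body weight only to within a factor of ~2.

Integration is semi-implicit Euler with every velocity-proportional damping
term (joint, muscle, drag, contact, stiction slope) applied implicitly per
degree of freedom; this is unconditionally stable for any overestimate of
the damping coefficient and is what allows 2–4 ms steps despite the small
inertias of hand and foot segments.  Contacts are one-sided penalty springs
with damping; ground friction is Coulomb-like with a `tanh` stiction
approximation; taxel–taxel self-collision uses the same stiffness as the
self-touch sensing, so skin cannot interpenetrate and a self-touch is a
transient event.  Left/right limbs live in parallel sagittal planes and are
excluded from mutual collision.

Environments: `uterus_fluid` (98% buoyancy, linear drag 4/s per unit mass,
soft circular wall sized to the body), `flat_plane` (gravity, stiff ground,
the extreme-preterm condition), and the top-down `walled_arena` for the
robot with anisotropic foot traction (a foot sliding radially outward grips
6 N·s/m, retracting slides at 0.6) — the ratchet that converts radial leg
oscillation into thrust.  Arena walls are soft (60 N/m) with tangential
grip so that a collision is a sustained interaction rather than a
millisecond bounce.

## Receptors

Tactile pressure per taxel = environmental contact normal force +
self-touch pseudo-contact force + (in fluid) resistance pressure
`skin_drag * |v|` proportional to the local skin speed.  (A leading-surface
variant `max(v·n, 0)` was also explored for the closed-loop experiment; it
neither breaks the antagonist symmetry of the Hebbian credit nor preserves
the within-limb correlation structure, so the magnitude form is the
default.)  Spindle length/velocity are signed
joint coordinates per muscle, tendon tension is the magnitude of the last
muscle torque.  The optional cameras are two 16×16 orthographic rasters
sampled in front of the face along the face normal.

## Phase analysis

Inter-leg coordination is read from the sensed joint angles.  The raw map
outputs dither with a common period-2 alternation at the tick rate, which
pins Hilbert-phase PLV near 1 for every pair regardless of coordination;
the body-timescale angles carry the meaningful phases.  Two observables are
used: the mean pairwise PLV on sliding 1 s windows, and the *constellation
similarity* — the circular correlation between the instantaneous vector of
pairwise phase differences and a reference pattern.  Wall adaptation is
invisible in the PLV level (the new pattern is as locked as the old one)
but unmistakable in the constellation, which collapses from ~0.7 to ~0.1
at contact and re-forms.

## Cortex

LIF neurons (tau_m 20 ms, threshold −50 mV, reset/rest −65 mV, refractory
2 ms, exponential synaptic filtering tau 5 ms, 1 ms steps, one-step spike
delay) on a unit sheet; exactly 5/6 excitatory; connection probability 0.6
at distance zero decaying with a Gaussian kernel of width 0.18; lognormal
excitatory weights, uniform inhibitory weights at −4× the excitatory mean
(Dale's principle enforced; STDP only on excitatory→excitatory synapses).
Per-neuron lognormal background-drive heterogeneity (sigma 0.4 on a 200 Hz
Poisson input) produces the right-skewed, lognormal-like rate distribution
and a mean depolarization of several mV above rest during activity.

Receptor channels are rate-coded as inhomogeneous Poisson spikes
(`rate = 100 Hz * value` after per-channel 95th-percentile normalization)
into a topographic input map: one patch per body part arranged on a ring in
the somatosensory zone (70% of the sheet), with the hand/arm patch placed
adjacent to the visual strip as at the cortical hand-area border; 20 target
neurons per channel with patch scatter sigma 0.1 — wide enough that naive
response maps overlap and learning has room to sharpen or blur them.

Pair-based additive STDP with A+ = 0.012, A− = 0.014 (tau 20 ms both,
weights clipped to [0, 1]).  The mild depression dominance means
uncorrelated coincidences decay while causally driving afferents survive —
this is what sharpens the intrauterine body map.  The default can be
overridden separately for afferent synapses; the postnatal multimodal
exposure uses a potentiation-biased setting (critical-period association
learning) plus weak diffuse "exuberant" visual projections over the whole
sheet.

## Spinal Hebbian learning

Full tactile→motor matrices (taxels × muscles) for both the alpha pathway
(adds to activation) and the oscillator drive, updated with an Oja-style
rule `dW = lr (pre·post − post² W)` and clipped to [0, w_max].  Tactile
input to the loop is normalized by a running 95th percentile, high-pass
filtered by a 1 s receptor-adaptation EMA (rapidly adapting
mechanoreceptors), and credited to a 0.25 s eligibility trace of past
activation rather than to coincident activity, so consequences are
assigned to the muscle activity that caused them.  The learned alpha drive
has its per-muscle tonic component adapted away (2 s EMA) so learning adds
phasic bursts instead of saturating co-contraction.

## Experiments and their statistics

All condition contrasts use paired seeds (identical networks and bodies
across conditions), one-sided paired t-tests or sign tests at 0.05, and the
configured durations below.  Scaled problem sizes were chosen so a full
analysis runs on a desk machine: cortical sheets of 600–2000 neurons
(default 2000), learning sessions of 40–100 s (default 100 s), 5–10 seeds.

* **Insect locomotion** (20 s, 5 seeds): net displacement against the
  exactly-zero passive baseline, and the first epoch where windowed PLV
  stays within a 0.15 band for 1.5 s.
* **Wall adaptation** (40 s, 0.5 m half-arena): first sustained (≥0.15 s)
  wall contact; constellation collapse below 0.6× the pre-contact
  similarity; re-entrainment when the PLV level regains its pre-contact
  criterion and stays stable; heading from 3–4 s displacement windows.
* **Body maps**: per seed and condition, simulate spontaneous movement,
  train the cortex on the tactile+proprioceptive stream, probe every part
  (150 Hz, 5 trials, evoked minus baseline counts), and score
  1 − mean pairwise cosine overlap of the rectified maps.
* **Multimodal**: identical 40-week bodies on the plane; a scripted arm
  sweep from outside the visual field across the face gives synchronized
  visual/tactile/proprioceptive input (visual–arm correlation ≈ 0.7);
  after identical 30 s exposures the combined-versus-unimodal response
  norm ratio is compared by sign test.
* **Closed-loop development** (90 s, gains ×1/×2/×3): windowed jerk events
  (acceleration bursts above 300 rad/s² of any joint, one event per burst
  within a 0.3 s refractory) and decisive
  hand–face contact events (pseudo-contact force above 0.25 N, 2 s
  debounce); onsets are sustained exceedances of the 10–30 s baseline.

## Known limitations

* The reduced dynamics are not a multibody solver: no inertial coupling,
  approximate global force balance, joint limits as velocity-clamping.
* The synthetic-stream generator reproduces only the second-order
  correlation structure of receptor input, so passing cortex tests on it
  demonstrates sensitivity to that structure and nothing about
  higher-order features of real movement statistics.
* Two documented desk-scale shortfalls, analysed in detail in the tests
  they affect: the multimodal-integration contrast holds only on average
  (the per-seed variability of the second-order effect exceeds its size,
  and plasticity settings that enlarge it destroy the body-map contrast),
  and the closed-loop developmental ordering expresses in individual runs
  but not as a seed-majority (sign-constrained Hebbian credit lands nearly
  symmetrically on antagonists, and the resulting co-contraction eats most
  of the amplification; the circuitry that would break the tie —
  reciprocal inhibition — is deliberately outside the model's scope).
* Vision is a crude orthographic raster; no occlusion ordering, no
  retina.
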