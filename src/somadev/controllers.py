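"""Per-actuator controller elements and the spinal circuit wrapper.

Two controller families are provided, both deliberately *uncoupled* at the
signal level — any coordination between actuators must emerge through the
shared body and environment:

* :class:`ChaoticUnit` — the quadratic map ``f(x) = 1 - alpha*x**2`` embedded
  in a sensory-motor loop, with optional weak self-feedback and mean-field
  input mixing.
* :class:`BVPUnit` / :class:`SpinalUnit` — a Bonhoeffer-van der Pol
  (FitzHugh-Nagumo) relaxation oscillator per muscle, acting as a central
  pattern generator, with alpha/gamma motor-neuron style afferent feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ChaoticUnit",
    "BVPUnit",
    "SpinalUnit",
    "logistic_step",
    "chaotic_controller_step",
    "bvp_step",
    "spinal_step",
    "ChaoticController",
    "SpinalController",
    "BVP_REST",
]


class DomainError(ValueError):
    """An input left the documented domain of an operation."""


class ConfigurationError(ValueError):
    """Mutually inconsistent component configuration."""


class NumericalDivergenceError(FloatingPointError):
    """A state variable became non-finite; carries the step index."""

    def __init__(self, msg: str, step: int | None = None):
        super().__init__(msg)
        self.step = step


# ---------------------------------------------------------------------------
# Chaotic map element
# ---------------------------------------------------------------------------

def logistic_step(x, alpha):
    """One iterate of the quadratic map ``f(x) = 1 - alpha * x**2``.

    The map is chaotic for alpha between ~1.4011 and 2 and maps [-1, 1] into
    [1 - alpha, 1] which stays inside [-1, 1] for alpha in [0, 2].

    Parameters
    ----------
    x : float or array
        Map state, must satisfy ``|x| <= 1``.
    alpha : float or array
        Map parameter in [0, 2].
    """
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 2):
        raise DomainError(f"alpha out of [0, 2]: {float(np.max(alpha)):g}")
    if np.any(np.abs(x) > 1 + 1e-12):
        bad = float(x.flat[int(np.argmax(np.abs(x)))])
        raise DomainError(f"map state out of [-1, 1]: {bad:g}")
    out = 1.0 - alpha * np.clip(x, -1.0, 1.0) ** 2
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class ChaoticUnit:
    """A quadratic-map element in a sensory-motor loop.

    ``x`` doubles as the last motor output ``u``: on each control tick the
    effective input (sensor + weak self feedback + mean-field mixing) is
    pushed through the map and becomes the new state/output.
    """

    alpha: float = 1.7
    x: float = 0.1
    eps_self: float = 0.05
    eps_mix: float = 0.05

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 2.0):
            raise DomainError(f"alpha out of [0, 2]: {self.alpha:g}")
        if abs(self.x) > 1.0:
            raise DomainError(f"map state out of [-1, 1]: {self.x:g}")
        if not (0.0 <= self.eps_self < 1.0 and 0.0 <= self.eps_mix < 1.0):
            raise DomainError("eps_self and eps_mix must lie in [0, 1)")
        if self.eps_self + self.eps_mix >= 1.0:
            raise DomainError(
                f"eps_self + eps_mix must be < 1, got {self.eps_self + self.eps_mix:g}"
            )


def chaotic_controller_step(s, units: Sequence[ChaoticUnit]):
    """Advance every chaotic element one tick against sensor vector ``s``.

    The effective input of unit *i* is the convex mixture
    ``(1 - eps_self - eps_mix)*s_i + eps_self*u_i + eps_mix*mean(u)`` where
    ``u`` are the previous outputs; the new output is one map iterate of it.
    Unit states are updated in place and the output vector is returned.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (len(units),):
        raise ConfigurationError(
            f"sensor vector length {s.shape} does not match {len(units)} units"
        )
    if np.any(np.abs(s) > 1 + 1e-12):
        raise DomainError("sensor values must lie in [-1, 1]")
    u_prev = np.array([un.x for un in units])
    mean_u = float(np.mean(u_prev))
    out = np.empty(len(units))
    for i, un in enumerate(units):
        eff = (1.0 - un.eps_self - un.eps_mix) * s[i] + un.eps_self * u_prev[i] \
            + un.eps_mix * mean_u
        # convex mixture of values in [-1, 1] stays in [-1, 1]
        un.x = logistic_step(eff, un.alpha)
        out[i] = un.x
    return out


# ---------------------------------------------------------------------------
# Bonhoeffer-van der Pol (FitzHugh-Nagumo) oscillator
# ---------------------------------------------------------------------------

#: Resting state of the oscillator with the default parameters and zero drive
#: (root of v^3 + 0.75 v + 2.625 = 0 and the w-nullcline).
BVP_REST = (-1.1994158, -0.62426975)

_DEFAULT_BVP = {"a": 0.7, "b": 0.8, "c": 3.0, "time_scale": 12.0}


@dataclass
class BVPUnit:
    """FitzHugh-Nagumo excitable/oscillatory element.

    Dynamics (in dimensionless model time)::

        dv/dt = c * (v - v**3/3 - w + drive)
        dw/dt = (v + a - b*w) / c

    ``time_scale`` converts wall-clock seconds to model time units so the
    limit-cycle period lands in the ~1 s range typical of slow fetal
    movements.  With zero drive the default parameters give a unique stable
    fixed point (:data:`BVP_REST`); constant drive roughly in (0.35, 1.4)
    puts the fixed point on the unstable middle branch and yields a bounded
    relaxation limit cycle.
    """

    v: float = BVP_REST[0]
    w: float = BVP_REST[1]
    params: dict = field(default_factory=lambda: dict(_DEFAULT_BVP))

    def __post_init__(self):
        for k, dv in _DEFAULT_BVP.items():
            self.params.setdefault(k, dv)


def bvp_step(unit: BVPUnit, drive: float, dt: float) -> BVPUnit:
    """Advance a BVP oscillator one fixed step of ``dt`` seconds.

    Semi-implicit (symplectic-style) Euler: ``v`` is updated explicitly and
    ``w`` then uses the fresh ``v``.  Explicit stability of the fast variable
    requires ``time_scale*c*dt`` well below 1; with the defaults
    (``c=3, time_scale=12``) that means dt below ~25 ms, and the package
    default of 1 ms has ample margin.
    """
    if dt <= 0:
        raise DomainError(f"dt must be positive, got {dt:g}")
    p = unit.params
    h = p["time_scale"] * dt
    v, w = unit.v, unit.w
    v = v + h * p["c"] * (v - v ** 3 / 3.0 - w + drive)
    w = w + h * (v + p["a"] - p["b"] * w) / p["c"]
    if not (np.isfinite(v) and np.isfinite(w)):
        raise NumericalDivergenceError(
            f"BVP state diverged (v={v!r}, w={w!r})", step=None
        )
    unit.v, unit.w = float(v), float(w)
    return unit


# ---------------------------------------------------------------------------
# Spinal unit: oscillator + alpha/gamma motor-neuron pathway
# ---------------------------------------------------------------------------

@dataclass
class SpinalUnit:
    """One muscle's spinal circuit: CPG oscillator plus afferent feedback.

    There is exactly one unit per muscle and units never connect to each
    other directly; all cross-muscle coordination is mediated by the body.
    ``gamma_mn`` scales spindle (length/velocity) sensitivity, mimicking the
    gamma motor-neuron control of spindle gain; Golgi tendon input bypasses
    it.  ``drive_bias`` is the tonic descending drive that puts the
    oscillator in its rhythmic regime.
    """

    oscillator: BVPUnit = field(default_factory=BVPUnit)
    alpha_mn: float = 0.0
    gamma_mn: float = 1.0
    afferent_gain: float = 0.3
    drive_bias: float = 0.875
    w_length: float = -1.0
    w_velocity: float = -0.3
    w_tension: float = 0.5
    v_rest: float = -1.2
    v_span: float = 2.4

    def __post_init__(self):
        if self.gamma_mn < 0:
            raise DomainError(f"gamma_mn must be >= 0, got {self.gamma_mn:g}")


def spinal_step(unit: SpinalUnit, afferents: Mapping[str, float], dt: float,
                extra_drive: float = 0.0, extra_activation: float = 0.0) -> float:
    """Advance one muscle's spinal circuit and return activation in [0, 1].

    The oscillator is driven by the tonic bias plus gamma-scaled, squashed
    afferent feedback (spindle length/velocity through the gamma gain, tendon
    tension directly).  ``extra_drive`` / ``extra_activation`` are the
    learned tactile contributions to the oscillator and the alpha
    motor-neuron (see :mod:`somadev.spinal_plasticity`).  Activation is a
    clipped linear squash of the fast variable.
    """
    aff = (unit.gamma_mn * (unit.w_length * float(afferents.get("spindle_length", 0.0))
                            + unit.w_velocity * float(afferents.get("spindle_velocity", 0.0)))
           + unit.w_tension * float(afferents.get("tendon_tension", 0.0)))
    if not np.isfinite(aff):
        raise DomainError("afferent values must be finite")
    drive = unit.drive_bias + unit.afferent_gain * float(np.tanh(aff)) + extra_drive
    bvp_step(unit.oscillator, drive, dt)
    act = (unit.oscillator.v - unit.v_rest) / unit.v_span + extra_activation
    unit.alpha_mn = float(np.clip(act, 0.0, 1.0))
    return unit.alpha_mn


# ---------------------------------------------------------------------------
# Body-level controller wrappers (used by somadev.embodiment.simulate)
# ---------------------------------------------------------------------------

class ChaoticController:
    """One chaotic map per joint actuator; sensors are scaled joint angles.

    The map output in [-1, 1] is interpreted directly as a normalized torque
    command.  ``theta_scale`` (rad) maps joint angle to the sensor range.
    """

    def __init__(self, n_units: int, alpha=1.7, eps_self=0.05, eps_mix=0.05,
                 theta_scale: float = 0.6, seed: int | None = None):
        alphas = np.broadcast_to(np.asarray(alpha, dtype=float), (n_units,))
        rng = np.random.default_rng(seed)
        x0 = rng.uniform(-0.9, 0.9, size=n_units)
        self.units = [
            ChaoticUnit(alpha=float(a), x=float(x), eps_self=eps_self, eps_mix=eps_mix)
            for a, x in zip(alphas, x0)
        ]
        self.theta_scale = theta_scale
        self.kind = "torque"

    @property
    def n_units(self):
        return len(self.units)

    def reset(self, seed: int | None = None):
        rng = np.random.default_rng(seed)
        for un in self.units:
            un.x = float(rng.uniform(-0.9, 0.9))

    def step(self, frame, dt_control: float):
        """Map a receptor frame to normalized torque commands in [-1, 1]."""
        s = np.clip(np.asarray(frame.joint_angles) / self.theta_scale, -1.0, 1.0)
        return chaotic_controller_step(s, self.units)

    def outputs(self):
        return np.array([un.x for un in self.units])


class SpinalController:
    """One spinal circuit (BVP oscillator + afferent pathway) per muscle.

    Vectorized over muscles for speed; the dynamics per muscle are exactly
    those of :func:`spinal_step` on a :class:`SpinalUnit` (verified by a
    regression test).  When a
    :class:`~somadev.spinal_plasticity.SpinalWeights` object and a positive
    learning rate are supplied the controller closes the tactile->motor loop
    and adapts the weights online with Oja-style Hebbian learning.
    """

    def __init__(self, n_muscles: int, drive_bias=0.875, afferent_gain=0.3,
                 gamma_mn=1.0, weights=None, learning_rate: float = 0.0,
                 bvp_dt: float = 0.001, seed: int | None = None,
                 phase_jitter: float = 1.0, params: dict | None = None,
                 w_length=-1.0, w_velocity=-0.3, w_tension=0.5,
                 v_rest=-1.2, v_span=2.4,
                 osc_drive_scale: float = 0.25, alpha_drive_scale: float = 3.0):
        rng = np.random.default_rng(seed)
        self.n_muscles = n_muscles
        self.params = dict(_DEFAULT_BVP)
        self.params.update(params or {})
        # seed each oscillator at a uniformly random phase of its limit
        # cycle (relaxation oscillators otherwise collapse onto nearby
        # phases from generic initial conditions)
        u = BVPUnit(params=dict(self.params))
        burn = int(round(3.0 / 0.001))
        orbit = np.empty((burn, 2))
        for k in range(burn):
            bvp_step(u, drive_bias, 0.001)
            orbit[k] = (u.v, u.w)
        pick = rng.integers(burn - 1200, burn, size=n_muscles)
        jit = np.clip(phase_jitter, 0.0, 1.0)
        self.v = orbit[pick, 0] * jit + BVP_REST[0] * (1 - jit)
        self.w = orbit[pick, 1] * jit + BVP_REST[1] * (1 - jit)
        self.drive_bias = drive_bias
        self.afferent_gain = afferent_gain
        self.gamma_mn = gamma_mn
        self.w_length, self.w_velocity, self.w_tension = w_length, w_velocity, w_tension
        self.v_rest, self.v_span = v_rest, v_span
        self.weights = weights
        self.learning_rate = learning_rate
        # learned tactile pathways are bounded so the oscillator stays in
        # its rhythmic drive band and the alpha pathway cannot saturate
        # activation on its own
        self.osc_drive_scale = osc_drive_scale
        self.alpha_drive_scale = alpha_drive_scale
        self.bvp_dt = bvp_dt
        self.kind = "activation"
        self._tactile_norm = None
        self._tactile_ema = None
        self.adapt_tau = 1.0  # s; mechanoreceptor adaptation time constant
        # eligibility trace over recent activation: tactile consequences are
        # credited to the muscle activity that caused them (~a quarter
        # movement cycle earlier), not to the coincident activity
        self._act_trace = np.zeros(n_muscles)
        self.eligibility_tau = 0.25  # s
        # the tonic component of the learned drive adapts away per muscle,
        # so learning adds phasic bursts instead of saturating co-contraction
        self._extra_ema = np.zeros(n_muscles)
        self.extra_adapt_tau = 2.0  # s
        self.activations = np.zeros(n_muscles)

    @property
    def n_units(self):
        return self.n_muscles

    def step(self, frame, dt_control: float):
        from . import spinal_plasticity as sp

        n = self.n_muscles
        extra_drive = np.zeros(n)
        extra_act = np.zeros(n)
        tac = None
        if self.weights is not None:
            if self._tactile_norm is None:
                self._tactile_norm = sp.RunningPercentileNormalizer()
            raw = self._tactile_norm.update(frame.tactile)
            # rapidly adapting receptors: the learned loop sees the phasic
            # (above-baseline) component, so feedback arrives as bursts
            if self._tactile_ema is None:
                self._tactile_ema = raw.copy()
            lam = dt_control / max(self.adapt_tau, dt_control)
            self._tactile_ema += lam * (raw - self._tactile_ema)
            tac = np.clip(raw - self._tactile_ema, 0.0, 1.0)
            extra_raw = self.alpha_drive_scale * sp.spinal_drive(self.weights, tac)
            lam_x = dt_control / max(self.extra_adapt_tau, dt_control)
            self._extra_ema += lam_x * (extra_raw - self._extra_ema)
            extra_act = extra_raw - self._extra_ema
            extra_drive = self.osc_drive_scale * np.tanh(
                self.weights.gain * (tac @ self.weights.W_osc))
        aff = (self.gamma_mn * (self.w_length * np.asarray(frame.spindle_length)
                                + self.w_velocity * np.asarray(frame.spindle_velocity))
               + self.w_tension * np.asarray(frame.tendon_tension))
        drive = self.drive_bias + self.afferent_gain * np.tanh(aff) + extra_drive
        p = self.params
        n_sub = max(1, int(round(dt_control / self.bvp_dt)))
        h = p["time_scale"] * dt_control / n_sub
        v, w = self.v, self.w
        for _ in range(n_sub):
            v = v + h * p["c"] * (v - v ** 3 / 3.0 - w + drive)
            w = w + h * (v + p["a"] - p["b"] * w) / p["c"]
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(w))):
            raise NumericalDivergenceError("spinal oscillator state diverged")
        self.v, self.w = v, w
        acts = np.clip((v - self.v_rest) / self.v_span + extra_act, 0.0, 1.0)
        self.activations = acts
        if self.weights is not None and self.learning_rate > 0 and tac is not None:
            lam_e = dt_control / max(self.eligibility_tau, dt_control)
            self._act_trace += lam_e * (acts - self._act_trace)
            sp.hebbian_update(self.weights, tac, self._act_trace,
                              self.learning_rate)
        return acts

    def outputs(self):
        return self.v.copy()
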