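"""Synthetic input generators.

These let the cortex, plasticity and metrics layers be exercised without
running body physics: receptor streams with controlled block-modular
correlation structure (the uterus-vs-plane contrast reduced to its
second-order statistics), oscillatory multichannel signals for
phase-locking tests, and kinematic scripted trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReceptorStream",
    "SyntheticStreamSpec",
    "synth_receptor_stream",
    "synth_oscillatory_signals",
    "scripted_trajectory",
]


@dataclass
class ReceptorStream:
    """A time-major block of receptor channel values at a fixed frame rate.

    The common currency between physics trajectories, synthetic generators
    and the cortex: ``values`` is (n_frames, n_channels), nonnegative, with
    one part label per channel used for somatotopic input mapping.
    """

    values: np.ndarray
    dt: float
    part_labels: list
    modality: list = field(default_factory=list)  # per channel: tactile/proprio/visual

    @property
    def n_channels(self):
        return self.values.shape[1]

    @property
    def duration(self):
        return self.values.shape[0] * self.dt


@dataclass
class SyntheticStreamSpec:
    """Block-modular Gaussian latent-factor receptor stream description.

    Channels are partitioned into blocks (body "parts"); pairwise latent
    correlation is ``rho_in`` within a block and ``rho_out`` between blocks,
    realized by one global factor, one factor per block, and channel noise.
    Values are shifted by ``offset`` standard deviations before clipping at
    zero so rectification barely distorts the correlation structure.
    """

    n_channels: int
    block_labels: list
    rho_in: float = 0.6
    rho_out: float = 0.0
    noise_sd: float = 1.0
    duration: float = 100.0
    dt: float = 0.01
    offset: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if len(self.block_labels) != self.n_channels:
            raise ValueError("block partition must cover all channels")
        if not (0.0 <= self.rho_out <= self.rho_in <= 1.0):
            raise ValueError(
                f"need 0 <= rho_out <= rho_in <= 1, got rho_in={self.rho_in}, "
                f"rho_out={self.rho_out}")


def synth_receptor_stream(spec: SyntheticStreamSpec) -> ReceptorStream:
    """Generate a nonnegative receptor stream hitting target block correlations.

    Construction: ``x_c = sqrt(rho_out)*g + sqrt(rho_in-rho_out)*f_block(c)
    + sqrt(1-rho_in)*eps_c`` gives unit-variance latents with exactly the
    target within/between-block correlations (guaranteed positive
    semi-definite by construction); the output is
    ``noise_sd * max(x + offset, 0)``.
    """
    rng = np.random.default_rng(spec.seed)
    n_t = int(round(spec.duration / spec.dt))
    labels = np.asarray(spec.block_labels)
    blocks = {b: np.nonzero(labels == b)[0] for b in dict.fromkeys(spec.block_labels)}
    g = rng.standard_normal((n_t, 1))
    x = np.sqrt(max(spec.rho_out, 0.0)) * g \
        + np.sqrt(max(1.0 - spec.rho_in, 0.0)) * rng.standard_normal((n_t, spec.n_channels))
    amp_b = np.sqrt(max(spec.rho_in - spec.rho_out, 0.0))
    for idx in blocks.values():
        x[:, idx] += amp_b * rng.standard_normal((n_t, 1))
    vals = spec.noise_sd * np.clip(x + spec.offset, 0.0, None)
    return ReceptorStream(values=vals, dt=spec.dt, part_labels=list(spec.block_labels),
                          modality=["tactile"] * spec.n_channels)


def synth_oscillatory_signals(n: int, frequency: float, phase_offsets=None,
                              jitter_sd: float = 0.0, duration: float = 10.0,
                              fs: float = 100.0, seed: int | None = None) -> np.ndarray:
    """Sinusoids with fixed phase offsets plus (random-walk) phase jitter.

    ``jitter_sd`` is the per-sample standard deviation of independent phase
    increments per channel; large values decorrelate the channels' phases.
    Returns an (n, n_samples) array.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    rng = np.random.default_rng(seed)
    if phase_offsets is None:
        phase_offsets = np.zeros(n)
    phase_offsets = np.asarray(phase_offsets, dtype=float)
    n_t = int(round(duration * fs))
    t = np.arange(n_t) / fs
    jitter = np.cumsum(rng.standard_normal((n, n_t)) * jitter_sd, axis=1)
    return np.sin(2 * np.pi * frequency * t[None, :] + phase_offsets[:, None] + jitter)


def scripted_trajectory(body, script, env=None, dt: float = 0.01,
                        visual_on: bool = False):
    """Kinematic trajectory interpolating joint-angle targets, with sensing.

    ``script`` is a list of ``(time_s, {joint_name: angle})`` waypoints with
    strictly increasing times; angles are linearly interpolated, velocities
    come from finite differences, and receptor frames (including self-touch
    pseudo-contacts and optional vision) are computed by the regular sensing
    pipeline.  No dynamics are involved — this is a probe/fixture generator.
    """
    from .embodiment import Environment, Trajectory, sensing
    from .embodiment.bodies import compiled

    if env is None:
        env = Environment.flat_plane()
    times = [float(t) for t, _ in script]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("script times must be strictly increasing")
    cb = compiled(body)
    name_to_joint = {j.name: k for k, j in enumerate(body.joints)}
    duration = times[-1] if times else 0.0
    n_frames = int(round(duration / dt)) + 1
    tgrid = np.arange(n_frames) * dt
    q = np.zeros((n_frames, cb.n_joints))
    if script:
        key_q = np.zeros((len(script), cb.n_joints))
        for r, (_, targets) in enumerate(script):
            if r > 0:
                key_q[r] = key_q[r - 1]
            for name, ang in targets.items():
                key_q[r, name_to_joint[name]] = ang
        for j in range(cb.n_joints):
            q[:, j] = np.interp(tgrid, times, key_q[:, j])
    qd = np.gradient(q, dt, axis=0) if n_frames > 1 else np.zeros_like(q)
    traj = Trajectory.allocate(body, cb, n_frames, dt, visual_on=visual_on,
                               config_hash="scripted", seed=None)
    from .embodiment.physics import BodyState

    for k in range(n_frames):
        state = BodyState.initial(cb)
        state.q = q[k].copy()
        state.qd = qd[k].copy()
        frame = sensing.sense(body, state, env, visual_on=visual_on)
        traj.record(k, tgrid[k], state, frame, np.zeros(max(cb.n_muscles, cb.n_joints)))
    return traj
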