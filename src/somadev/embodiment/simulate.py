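"""Closed-loop simulation: controller <-> body <-> environment.

The controller is ticked at a coarse control cadence (default 10 ms); body
physics runs at a finer fixed step in between, holding the last motor
command.  Trajectories are sampled at the control cadence, and identical
seeds/configs give bit-identical output.
"""

from __future__ import annotations

import numpy as np

from .bodies import BodySpec, compiled
from .environments import Environment
from .physics import BodyState, muscle_joint_torques, physics_step
from .sensing import sense
from .trajectory import Trajectory, config_hash
from ..controllers import ConfigurationError

__all__ = ["simulate", "initial_state"]


def initial_state(body: BodySpec, env: Environment, seed=None,
                  joint_noise: float = 0.1) -> BodyState:
    """Seeded initial state with small joint-angle perturbations.

    In the uterus the body starts at the chamber centre; on the flat plane
    it is placed just above the ground so it settles onto contacts; the
    insect starts at the arena centre.
    """
    cb = compiled(body)
    rng = np.random.default_rng(seed)
    state = BodyState.initial(cb)
    state.q = joint_noise * rng.uniform(-1.0, 1.0, cb.n_joints) \
        * np.minimum(np.abs(cb.jlo), np.abs(cb.jhi))
    state.q = np.clip(state.q, cb.jlo, cb.jhi)
    if env.kind == "uterus_fluid":
        c = np.asarray(env.wall["center"], dtype=float)
        state.base[:2] = c
        state.base[2] = np.pi / 2  # trunk axis up
        # centre the body's bounding box on the chamber
        from .physics import Kinematics
        kin = Kinematics(cb, state)
        state.base[:2] += c - kin.taxel_pos.mean(axis=0)
    elif env.kind == "flat_plane" and env.ground:
        state.base[2] = np.pi / 2
        from .physics import Kinematics
        kin = Kinematics(cb, state)
        low = kin.taxel_pos[:, 1].min() if cb.n_taxels else 0.0
        state.base[1] += 0.002 - low
    return state


def simulate(body: BodySpec, env: Environment, controller, duration: float,
             dt: float = 0.002, control_dt: float = 0.01, seed=None,
             visual_on: bool = False, state: BodyState | None = None,
             joint_noise: float = 0.1) -> Trajectory:
    """Run the body/controller/environment loop for ``duration`` seconds.

    Returns a trajectory sampled every ``control_dt``; a zero duration gives
    a single-frame trajectory of the initial state.
    """
    cb = compiled(body)
    if controller is not None:
        n_expected = cb.n_muscles if controller.kind == "activation" else cb.n_joints
        if controller.n_units != n_expected:
            raise ConfigurationError(
                f"controller has {controller.n_units} units but the body needs "
                f"{n_expected} ({controller.kind} control)")
    n_sub = max(1, int(round(control_dt / dt)))
    dt_sub = control_dt / n_sub
    n_frames = int(round(duration / control_dt)) + 1
    if state is None:
        state = initial_state(body, env, seed=seed, joint_noise=joint_noise)
    chash = config_hash({
        "body": body.name, "n_joints": cb.n_joints, "n_muscles": cb.n_muscles,
        "n_taxels": cb.n_taxels, "env": env.kind, "duration": duration,
        "dt": dt, "control_dt": control_dt, "seed": seed,
        "controller": type(controller).__name__ if controller else None,
    })
    traj = Trajectory.allocate(body, cb, n_frames, control_dt,
                               visual_on=visual_on, config_hash=chash, seed=seed)
    tau_scale = np.zeros(cb.n_joints)
    np.add.at(tau_scale, cb.m_joint, cb.m_tau)
    tau_scale = np.maximum(tau_scale / 2.0, 1e-9)  # per-joint actuator scale
    from .physics import Kinematics
    from .sensing import TOUCH_FACTOR
    for k in range(n_frames):
        t = k * control_dt
        kin = Kinematics(cb, state)
        close = None
        if cb.touch_i.size and not env.planar:
            # shared self-touch broad-phase for this tick
            diff = kin.taxel_pos[cb.touch_i] - kin.taxel_pos[cb.touch_j]
            d2 = np.einsum("pc,pc->p", diff, diff)
            marg = 3.0 * TOUCH_FACTOR * (cb.seg_rad[cb.t_seg[cb.touch_i]]
                                         + cb.seg_rad[cb.t_seg[cb.touch_j]])
            close = np.nonzero(d2 < marg ** 2)[0]
        frame = sense(body, state, env, visual_on=visual_on, kin=kin,
                      candidate_pairs=close)
        muscle_damp = None
        if controller is None:
            motor = np.zeros(cb.n_muscles if cb.n_muscles else cb.n_joints)
            torques = np.zeros(cb.n_joints)
        else:
            motor = np.asarray(controller.step(frame, control_dt), dtype=float)
            if controller.kind == "activation":
                torques, muscle_damp = muscle_joint_torques(
                    cb, state, motor, include_viscous=False)
            else:
                torques = motor * tau_scale
        traj.record(k, t, state, frame, motor)
        if k == n_frames - 1:
            break
        for _ in range(n_sub):
            physics_step(body, state, torques, env, dt_sub,
                         joint_damping_extra=muscle_damp, close_pairs=close)
    return traj
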