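"""Receptor models: skin taxels, muscle spindles, tendon organs, cameras.

One :func:`sense` call turns an instantaneous body state into a
:class:`ReceptorFrame`: tactile pressure per taxel (contact normal forces,
fluid-resistance pressure proportional to local skin speed in the uterus,
and self-touch pseudo-contacts), proprioception per muscle (spindle
length/velocity from the joint the muscle spans, tendon tension from its
last torque), and an optional pair of 16x16 camera images from eyes in the
head looking along the face direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bodies import BodySpec, compiled
from .environments import Environment
from .physics import BodyState, Kinematics

__all__ = ["ReceptorFrame", "sense", "VISION_SHAPE"]

VISION_SHAPE = (2, 16, 16)

#: self-touch threshold multiplier on the sum of the two taxels' segment
#: radii; taxels already sit on the skin surface, so a fraction of the
#: combined radii approximates surface proximity
TOUCH_FACTOR = 0.3
TOUCH_STIFFNESS = 80.0  # N/m pseudo-contact force slope


@dataclass
class ReceptorFrame:
    tactile: np.ndarray            # per-taxel pressure, N, >= 0
    spindle_length: np.ndarray     # per-muscle normalized stretch
    spindle_velocity: np.ndarray   # per-muscle stretch rate
    tendon_tension: np.ndarray     # per-muscle |torque|, N*m
    joint_angles: np.ndarray
    joint_velocities: np.ndarray
    contact_normal: np.ndarray     # per-taxel environmental contact force, N
    self_contacts: list = field(default_factory=list)  # (taxel_i, taxel_j, force)
    visual: np.ndarray | None = None   # (2, 16, 16) in [0, 1]


def sense(body: BodySpec, state: BodyState, env: Environment,
          visual_on: bool = False, kin: Kinematics | None = None,
          candidate_pairs=None) -> ReceptorFrame:
    """Compute one receptor frame.

    ``kin`` and ``candidate_pairs`` let the simulation loop share the
    forward kinematics and the self-touch broad-phase between sensing and
    physics within a control tick.
    """
    cb = compiled(body)
    if kin is None:
        kin = Kinematics(cb, state)
    tactile = state.contact_forces.copy()
    contact_normal = state.contact_forces.copy()

    # fluid-resistance pressure on moving skin, proportional to local speed
    if env.skin_drag > 0 and cb.n_taxels:
        v_tax = kin.point_vel(kin.taxel_pos, cb.t_seg)
        tactile += env.skin_drag * np.sqrt(
            np.einsum("pc,pc->p", v_tax, v_tax))

    # self-touch pseudo-contacts between non-adjacent, same-plane segments
    self_contacts = np.zeros((0, 3))
    if cb.touch_i.size:
        sel = (np.arange(cb.touch_i.size) if candidate_pairs is None
               else candidate_pairs)
        ti, tj = cb.touch_i[sel], cb.touch_j[sel]
        diff = kin.taxel_pos[ti] - kin.taxel_pos[tj]
        d = np.sqrt(np.einsum("pc,pc->p", diff, diff))
        thresh = TOUCH_FACTOR * (cb.seg_rad[cb.t_seg[ti]]
                                 + cb.seg_rad[cb.t_seg[tj]])
        hit = d < thresh
        if np.any(hit):
            f = TOUCH_STIFFNESS * (thresh[hit] - d[hit])
            i_hit, j_hit = ti[hit], tj[hit]
            np.add.at(tactile, i_hit, f)
            np.add.at(tactile, j_hit, f)
            self_contacts = np.stack([i_hit.astype(float),
                                      j_hit.astype(float), f], axis=1)

    # proprioception: spindle stretch is positive when the joint moves
    # against the muscle's pull direction; tendon tension from last torques
    th = state.q[cb.m_joint]
    om = state.qd[cb.m_joint]
    spindle_len = -cb.m_sign * th
    spindle_vel = -cb.m_sign * om
    tension = np.abs(state.muscle_torques)

    visual = _render_eyes(cb, kin) if visual_on else None
    return ReceptorFrame(tactile=tactile, spindle_length=spindle_len,
                         spindle_velocity=spindle_vel, tendon_tension=tension,
                         joint_angles=state.q.copy(),
                         joint_velocities=state.qd.copy(),
                         contact_normal=contact_normal,
                         self_contacts=self_contacts, visual=visual)


def _render_eyes(cb, kin: Kinematics) -> np.ndarray:
    """Crude orthographic raster of body segments in front of the face.

    Each eye samples a 16x16 grid over a window extending 0.05-0.33 m along
    the head axis and +-0.15 m across it; pixel intensity falls off linearly
    with the distance from the nearest non-head segment centerline.  A hand
    in front of the face lights pixels; anything behind the head does not.
    """
    try:
        head = cb.seg_names.index("head")
    except ValueError:
        return np.zeros(VISION_SHAPE)
    # gaze along the face normal (the ventral, face-taxel side of the head),
    # not along the head axis — the eyes look out of the face
    axis = kin.seg_dir[head]
    fwd = np.array([-axis[1], axis[0]])
    side = axis
    eye_base = kin.seg_origin[head] + 0.6 * cb.seg_len[head] * axis \
        + cb.seg_rad[head] * fwd
    img = np.zeros(VISION_SHAPE)
    u = (np.arange(16) - 7.5) / 7.5 * 0.15
    v = 0.05 + np.arange(16) / 15.0 * 0.28
    exclude = {head}
    # also exclude neck (adjacent, always in frame corner)
    if "neck" in cb.seg_names:
        exclude.add(cb.seg_names.index("neck"))
    segs = [s for s in range(cb.n_seg) if s not in exclude and cb.seg_len[s] > 0]
    if not segs:
        return img
    a = np.array([kin.seg_origin[s] for s in segs])
    b = np.array([kin.seg_tip[s] for s in segs])
    rad = np.array([cb.seg_rad[s] for s in segs])
    for e, off in enumerate((-0.012, 0.012)):
        eye = eye_base + off * side
        # world points of the pixel grid: rows = depth v, cols = lateral u
        P = (eye[None, None, :] + v[:, None, None] * fwd[None, None, :]
             + u[None, :, None] * side[None, None, :])
        Pf = P.reshape(-1, 2)
        d_min = np.full(Pf.shape[0], np.inf)
        for k in range(len(segs)):
            ab = b[k] - a[k]
            L2 = float(ab @ ab) + 1e-12
            tpar = np.clip(((Pf - a[k]) @ ab) / L2, 0.0, 1.0)
            proj = a[k] + tpar[:, None] * ab
            d = np.linalg.norm(Pf - proj, axis=1) - rad[k]
            d_min = np.minimum(d_min, d)
        inten = np.clip(1.0 - np.clip(d_min, 0.0, None) / 0.02, 0.0, 1.0)
        img[e] = inten.reshape(16, 16)
    return img
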