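"""Articulated 2D body specifications and their compiled array form.

Bodies are trees of rod-like segments connected by rotary joints with
torsional springs, actuated by antagonist muscle pairs, and covered with
discrete tactile elements (taxels).  Two builders are provided: a radially
symmetric multi-legged "insect" robot (top-down planar) and a simplified
sagittal human fetus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Segment", "Joint", "Muscle", "Taxel", "BodySpec",
           "build_insect_body", "build_fetus_body", "compiled", "CompiledBody",
           "REGION_VOCAB"]

REGION_VOCAB = ("face", "hand", "foot", "other")


@dataclass
class Segment:
    name: str
    mass: float          # kg
    length: float        # m (0 for a disc-like base)
    radius: float        # m


@dataclass
class Joint:
    name: str
    parent: str
    child: str
    lo: float = -1.0     # rad
    hi: float = 1.0
    attach: tuple = (0.0, 0.0)   # attachment point in the parent frame (m)
    rest_offset: float = 0.0     # child axis angle rel. parent at q=0


@dataclass
class Muscle:
    name: str
    joint: str
    sign: int            # +1 flexor, -1 extensor
    max_torque: float    # N*m
    theta_opt: float = 0.0
    width: float = 1.2   # rad, length-tension bell width
    damping: float = 0.02  # N*m*s viscous


@dataclass
class Taxel:
    id: str
    segment: str
    frac: float          # position along the segment axis in [0, 1]
    side: int            # +1 / -1 surface side
    region: str          # face/hand/foot/other
    part: str            # body part grouping for somatotopy


@dataclass
class BodySpec:
    name: str
    segments: list
    joints: list
    muscles: list
    taxels: list
    springs: dict = field(default_factory=lambda: {"K": 2.0, "damping": 0.15})
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names")
        children = {j.child for j in self.joints}
        parents_ok = set(names)
        for j in self.joints:
            if j.parent not in parents_ok or j.child not in parents_ok:
                raise ValueError(f"joint {j.name} references unknown segment")
        # tree rooted at the first (base) segment
        if names[0] in children:
            raise ValueError("base segment must not be a joint child")
        if len(children) != len(self.joints) or len(self.joints) != len(names) - 1:
            raise ValueError("joint graph must be a tree rooted at the base segment")
        jn = {j.name for j in self.joints}
        by_joint: dict[str, list] = {}
        for m in self.muscles:
            if m.joint not in jn:
                raise ValueError(f"muscle {m.name} references unknown joint {m.joint}")
            by_joint.setdefault(m.joint, []).append(m.sign)
        for jname, signs in by_joint.items():
            if not (any(s > 0 for s in signs) and any(s < 0 for s in signs)):
                raise ValueError(f"joint {jname} lacks an antagonist muscle pair")
        tids = [t.id for t in self.taxels]
        if len(set(tids)) != len(tids):
            raise ValueError("taxel ids must be unique")
        for t in self.taxels:
            if t.region not in REGION_VOCAB:
                raise ValueError(f"taxel region {t.region!r} not in {REGION_VOCAB}")

    @property
    def parts(self):
        return sorted({t.part for t in self.taxels})


# ---------------------------------------------------------------------------
# Compiled (array) form
# ---------------------------------------------------------------------------

class CompiledBody:
    """Array view of a BodySpec plus precomputed kinematic bookkeeping."""

    def __init__(self, body: BodySpec):
        segs = body.segments
        self.n_seg = len(segs)
        self.n_joints = len(body.joints)
        self.n_muscles = len(body.muscles)
        self.n_taxels = len(body.taxels)
        idx = {s.name: i for i, s in enumerate(segs)}
        self.seg_names = [s.name for s in segs]
        self.seg_len = np.array([s.length for s in segs])
        self.seg_mass = np.array([s.mass for s in segs])
        self.seg_rad = np.array([s.radius for s in segs])
        self.parent = np.full(self.n_seg, -1, dtype=int)
        self.joint_of_seg = np.full(self.n_seg, -1, dtype=int)
        self.attach = np.zeros((self.n_seg, 2))
        self.rest_offset = np.zeros(self.n_seg)
        self.child_seg = np.zeros(self.n_joints, dtype=int)
        self.joint_names = [j.name for j in body.joints]
        self.jlo = np.array([j.lo for j in body.joints])
        self.jhi = np.array([j.hi for j in body.joints])
        for k, j in enumerate(body.joints):
            c, p = idx[j.child], idx[j.parent]
            self.parent[c] = p
            self.joint_of_seg[c] = k
            self.attach[c] = j.attach
            self.rest_offset[c] = j.rest_offset
            self.child_seg[k] = c
        # topological order (parents before children)
        order, seen = [], {0}
        pending = list(range(1, self.n_seg))
        while pending:
            for s in list(pending):
                if self.parent[s] in seen:
                    order.append(s)
                    seen.add(s)
                    pending.remove(s)
        self.topo = np.array(order, dtype=int)
        # ancestor-joint incidence: anc[s, j] True if joint j lies on base->s path
        self.anc = np.zeros((self.n_seg, self.n_joints), dtype=bool)
        for s in self.topo:
            p = self.parent[s]
            self.anc[s] = self.anc[p]
            self.anc[s, self.joint_of_seg[s]] = True
        self.K = float(body.springs.get("K", 2.0))
        self.jdamp = float(body.springs.get("damping", 0.15))
        # muscles
        jidx = {j.name: k for k, j in enumerate(body.joints)}
        self.m_joint = np.array([jidx[m.joint] for m in body.muscles], dtype=int)
        self.m_sign = np.array([m.sign for m in body.muscles])
        self.m_tau = np.array([m.max_torque for m in body.muscles])
        self.m_opt = np.array([m.theta_opt for m in body.muscles])
        self.m_width = np.array([m.width for m in body.muscles])
        self.m_damp = np.array([m.damping for m in body.muscles])
        self.muscle_names = [m.name for m in body.muscles]
        # taxels
        self.t_seg = np.array([idx[t.segment] for t in body.taxels], dtype=int)
        self.t_local = np.stack([
            np.array([t.frac * segs[idx[t.segment]].length,
                      t.side * segs[idx[t.segment]].radius])
            for t in body.taxels]) if body.taxels else np.zeros((0, 2))
        self.t_region = np.array([t.region for t in body.taxels])
        self.t_part = np.array([t.part for t in body.taxels])
        self.t_ids = [t.id for t in body.taxels]
        # taxel pair candidates for self-touch: segments neither identical nor
        # adjacent in the tree, and not an opposite-side (left/right) pair —
        # mirrored limbs live in parallel sagittal planes and never collide
        adj = np.zeros((self.n_seg, self.n_seg), dtype=bool)
        for s in range(1, self.n_seg):
            adj[s, self.parent[s]] = adj[self.parent[s], s] = True
        np.fill_diagonal(adj, True)
        side = np.array([1 if n.endswith("_l") else -1 if n.endswith("_r") else 0
                         for n in self.seg_names])
        ti, tj = np.triu_indices(self.n_taxels, k=1)
        si, sj = self.t_seg[ti], self.t_seg[tj]
        ok = ~adj[si, sj] & (side[si] * side[sj] >= 0)
        self.touch_i, self.touch_j = ti[ok], tj[ok]
        self.M_total = float(self.seg_mass.sum())
        # rest-pose inertias (effective subtree inertia per joint; base inertia)
        q0 = np.zeros(self.n_joints)
        ang, org = self._fk_frames(q0, np.zeros(3))
        com = org + 0.5 * self.seg_len[:, None] * _dirs(ang)
        jorg = org[self.child_seg]
        self.I_joint = np.zeros(self.n_joints)
        for k in range(self.n_joints):
            subtree = self.anc[:, k]
            d2 = np.sum((com[subtree] - jorg[k]) ** 2, axis=1)
            own = self.seg_mass[subtree] * (self.seg_len[subtree] ** 2 / 12.0
                                            + self.seg_rad[subtree] ** 2 / 4.0)
            self.I_joint[k] = float(np.sum(own + self.seg_mass[subtree] * d2)) + 1e-6
        d2b = np.sum((com - org[0]) ** 2, axis=1)
        ownb = self.seg_mass * (self.seg_len ** 2 / 12.0 + self.seg_rad ** 2 / 2.0)
        self.I_base = float(np.sum(ownb + self.seg_mass * d2b)) + 1e-6
        self.kind = body.meta.get("kind", "generic")
        self.foot_segs = np.array(
            [idx[n] for n in body.meta.get("traction_segments", [])], dtype=int)
        self.parts = body.parts

    def _fk_frames(self, q, base_pose):
        """Segment world angles and origins for given joint angles/base pose."""
        ang = np.empty(self.n_seg)
        org = np.empty((self.n_seg, 2))
        ang[0] = base_pose[2]
        org[0] = base_pose[:2]
        for s in self.topo:
            p = self.parent[s]
            ang[s] = ang[p] + self.rest_offset[s] + q[self.joint_of_seg[s]]
            ca, sa = np.cos(ang[p]), np.sin(ang[p])
            ax, ay = self.attach[s]
            org[s] = org[p] + np.array([ca * ax - sa * ay, sa * ax + ca * ay])
        return ang, org


def _dirs(ang):
    return np.stack([np.cos(ang), np.sin(ang)], axis=-1)


def compiled(body: BodySpec) -> CompiledBody:
    """Cached CompiledBody for a spec (rebuilt if the spec object changes)."""
    cb = getattr(body, "_compiled", None)
    if cb is None:
        cb = CompiledBody(body)
        object.__setattr__(body, "_compiled", cb)
    return cb


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_insect_body(n_legs: int = 12, K: float = 0.5, disc_radius: float = 0.12,
                      leg_length: float = 0.12, leg_mass: float = 0.12,
                      disc_mass: float = 1.2, max_torque: float = 2.0,
                      n_rim_taxels: int = 24, damping: float = 0.02) -> BodySpec:
    """Radially symmetric multi-legged robot (top-down planar).

    ``n_legs`` legs hang from the rim of a central disc on rotary joints with
    torsional springs of constant ``K``; each joint angle is the sensor of
    its leg's controller and the controller output drives the leg torque.
    Swinging a leg moves its foot both tangentially and radially, and
    anisotropic foot-ground traction turns radial oscillation into thrust.
    """
    if n_legs < 3:
        raise ValueError(f"need at least 3 legs, got {n_legs}")
    if K <= 0:
        raise ValueError("K must be positive")
    segs = [Segment("disc", disc_mass, 0.0, disc_radius)]
    joints, muscles, taxels = [], [], []
    for i in range(n_legs):
        phi = 2 * np.pi * i / n_legs
        name = f"leg_{i}"
        segs.append(Segment(name, leg_mass, leg_length, 0.012))
        joints.append(Joint(f"hip_{i}", "disc", name, lo=-0.9, hi=0.9,
                            attach=(disc_radius * np.cos(phi),
                                    disc_radius * np.sin(phi)),
                            rest_offset=phi))
        muscles.append(Muscle(f"flex_{i}", f"hip_{i}", +1, max_torque))
        muscles.append(Muscle(f"ext_{i}", f"hip_{i}", -1, max_torque))
        taxels.append(Taxel(f"tip_{i}", name, 1.0, +1, "foot", f"leg_{i}"))
    for k in range(n_rim_taxels):
        # rim taxels live on the disc "segment" via side offsets; the disc has
        # zero length so place them with frac 0 and rotate via per-taxel part
        phi = 2 * np.pi * k / n_rim_taxels
        taxels.append(Taxel(f"rim_{k}", "disc", 0.0, +1, "other", "body"))
    body = BodySpec("insect", segs, joints, muscles, taxels,
                    springs={"K": K, "damping": damping},
                    meta={"kind": "insect",
                          "traction_segments": [f"leg_{i}" for i in range(n_legs)],
                          "rim_taxels": n_rim_taxels})
    # rim taxels need true polar placement on the disc; store local coords
    cb = compiled(body)
    rim = [k for k, t in enumerate(body.taxels) if t.id.startswith("rim_")]
    for k in rim:
        j = int(body.taxels[k].id.split("_")[1])
        phi = 2 * np.pi * j / len(rim)
        cb.t_local[k] = disc_radius * np.array([np.cos(phi), np.sin(phi)])
    return body


# Fetal geometry at 32 weeks (m, kg); other ages scale these.
_FETUS_32W = {
    # name: (mass, length, radius)
    "trunk_lower": (0.40, 0.085, 0.042),
    "trunk_upper": (0.42, 0.085, 0.045),
    "neck":        (0.05, 0.020, 0.020),
    "head":        (0.45, 0.095, 0.048),
    "upper_arm":   (0.045, 0.058, 0.013),
    "forearm":     (0.035, 0.050, 0.011),
    "hand":        (0.020, 0.036, 0.009),
    "thigh":       (0.080, 0.062, 0.016),
    "shank_foot":  (0.060, 0.085, 0.013),
}

# (parent, child base name, attach frac along parent, rest offset rad,
#  lo, hi, actuated); joint angles are deviations from the flexed rest posture
_FETUS_TOPO = [
    ("trunk_lower", "trunk_upper", 1.0, 0.25, -0.5, 0.7, True),    # spine
    ("trunk_upper", "neck",        1.0, 0.30, -0.4, 0.6, True),    # neck_base
    ("neck",        "head",        1.0, 0.15, -0.4, 0.5, False),   # head_joint
    ("trunk_upper", "upper_arm",   0.92, -2.6, -1.2, 1.2, True),   # shoulder
    ("upper_arm",   "forearm",     1.0, -2.10, -0.5, 1.4, True),   # elbow
    ("forearm",     "hand",        1.0, -0.20, -0.7, 0.7, False),  # wrist
    ("trunk_lower", "thigh",       0.04, 2.45, -1.0, 1.0, True),   # hip
    ("thigh",       "shank_foot",  1.0, -2.30, -0.5, 1.4, True),   # knee
]


def build_fetus_body(age_weeks: float = 32.0, taxel_distribution: str = "humanlike",
                     taxel_count: int = 300, humanlike_fraction: float = 0.7,
                     K: float = 0.6, damping: float = 0.08,
                     muscle_strength: float = 1.1) -> BodySpec:
    """Simplified sagittal 2D human fetus in a flexed natural posture.

    14 segments (head, neck, two trunk segments, and per side: upper arm,
    forearm, hand, thigh, shank+foot), antagonist muscle pairs on the 10
    actuated joints (spine, neck base, shoulders, elbows, hips, knees), and
    ``taxel_count`` skin taxels.  ``humanlike`` concentrates
    ``humanlike_fraction`` of the taxels on face/hand/foot skin (dense where
    human mechanoreceptor density is high); ``uniform`` spreads them evenly
    per unit of skin arc.  Geometry and mass scale monotonically with
    gestational age; left/right limbs overlap in the sagittal plane but
    interact with the environment independently.
    """
    if not (24.0 <= age_weeks <= 42.0):
        raise ValueError(f"age_weeks out of [24, 42]: {age_weeks:g}")
    if taxel_count < 20:
        raise ValueError(f"taxel_count must be >= 20, got {taxel_count}")
    if taxel_distribution not in ("humanlike", "uniform"):
        raise ValueError(f"unknown taxel distribution {taxel_distribution!r}")
    scale = (42.0 + 1.125 * (age_weeks - 32.0)) / 42.0  # crown-heel proxy
    mscale = scale ** 3
    segs = []
    for name, (m, L, r) in _FETUS_32W.items():
        if name in ("upper_arm", "forearm", "hand", "thigh", "shank_foot"):
            for side in ("l", "r"):
                segs.append(Segment(f"{name}_{side}", m * mscale, L * scale, r * scale))
        else:
            segs.append(Segment(name, m * mscale, L * scale, r * scale))
    seg_by = {s.name: s for s in segs}
    joints, muscles = [], []

    def _add_joint(parent, child, frac, off, lo, hi, actuated, jname):
        pl = seg_by[parent].length
        joints.append(Joint(jname, parent, child, lo=lo, hi=hi,
                            attach=(frac * pl, 0.0), rest_offset=off))
        if actuated:
            # strong enough to deflect the joint spring by ~1 rad
            tq = muscle_strength * K * mscale
            muscles.append(Muscle(f"{jname}_flex", jname, +1, tq))
            muscles.append(Muscle(f"{jname}_ext", jname, -1, tq))

    for parent, child, frac, off, lo, hi, act in _FETUS_TOPO:
        if child in ("upper_arm", "forearm", "hand", "thigh", "shank_foot"):
            for side in ("l", "r"):
                p = parent if parent in seg_by else f"{parent}_{side}"
                base = {"upper_arm": "shoulder", "forearm": "elbow", "hand": "wrist",
                        "thigh": "hip", "shank_foot": "knee"}[child]
                _add_joint(p, f"{child}_{side}", frac, off, lo, hi, act,
                           f"{base}_{side}")
        else:
            jname = {"trunk_upper": "spine", "neck": "neck_base",
                     "head": "head_joint"}[child]
            _add_joint(parent, child, frac, off, lo, hi, act, jname)

    # skin patches: (segment, region, part, arc weight)
    patches = []
    for s in segs:
        part = ("head" if s.name in ("head", "neck") else
                "trunk" if s.name.startswith("trunk") else
                "arm_l" if s.name.endswith("_l") and ("arm" in s.name or "hand" in s.name) else
                "arm_r" if s.name.endswith("_r") and ("arm" in s.name or "hand" in s.name) else
                "leg_l" if s.name.endswith("_l") else "leg_r")
        arc = 2.0 * max(s.length, 2 * s.radius)
        if s.name == "head":
            patches.append((s.name, "face", part, 0.5 * arc))   # front surface
            patches.append((s.name, "other", part, 0.5 * arc))  # back surface
        elif s.name.startswith("hand"):
            patches.append((s.name, "hand", part, arc))
        elif s.name.startswith("shank_foot"):
            patches.append((s.name, "foot", part, 0.4 * arc))   # distal = foot
            patches.append((s.name, "other", part, 0.6 * arc))
        else:
            patches.append((s.name, "other", part, arc))

    dense = {"face", "hand", "foot"}
    w = np.array([p[3] for p in patches])
    if taxel_distribution == "uniform":
        alloc = w / w.sum()
    else:
        hi_mask = np.array([p[1] in dense for p in patches])
        alloc = np.zeros(len(patches))
        alloc[hi_mask] = humanlike_fraction * w[hi_mask] / w[hi_mask].sum()
        alloc[~hi_mask] = (1 - humanlike_fraction) * w[~hi_mask] / w[~hi_mask].sum()
    counts = np.maximum(np.round(alloc * taxel_count).astype(int), 1)

    taxels = []
    for (sname, region, part, _w), c in zip(patches, counts):
        is_front = region in ("face",) or not (sname == "head" or sname.startswith("shank_foot"))
        for k in range(c):
            if sname == "head":
                frac = (k + 0.5) / c
                side = +1 if region == "face" else -1
            elif sname.startswith("shank_foot"):
                frac = 0.6 + 0.4 * (k + 0.5) / c if region == "foot" else 0.6 * (k + 0.5) / c
                side = +1 if k % 2 == 0 else -1
            else:
                frac = (k + 0.5) / c
                side = +1 if k % 2 == 0 else -1
            taxels.append(Taxel(f"{sname}.{region}.{k}", sname, float(frac),
                                side, region, part))
    return BodySpec("fetus", segs, joints, muscles, taxels,
                    springs={"K": K * mscale, "damping": damping * mscale},
                    meta={"kind": "fetus", "age_weeks": age_weeks,
                          "taxel_distribution": taxel_distribution,
                          "scale": scale})
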