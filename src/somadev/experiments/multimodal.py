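"""Multimodal integration after birth: transplanted cortices compared.

The cortices trained under the two prenatal conditions are "transplanted"
onto identical 40-week bodies lying on the flat plane.  A scripted arm
movement in front of the eyes generates synchronized visual, tactile and
proprioceptive input; after a brief identical postnatal exposure phase the
combined-versus-unimodal response ratio is compared between the two
cortices.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..cortex import CortexNet, stimulate_probe, train_on_stream
from ..embodiment import Environment, build_fetus_body
from ..fixtures import scripted_trajectory
from ..metrics import multimodal_index
from .report import make_report

__all__ = ["run_multimodal_experiment", "multimodal_contrast",
           "neonate_multimodal_stream", "DEFAULT_MULTIMODAL"]

DEFAULT_MULTIMODAL = {
    "age_weeks": 40.0,
    "taxel_distribution": "humanlike",
    "taxel_count": 300,
    "n_sweeps": 8,
    "sweep_period": 2.0,
    "exposure_duration": 30.0,
    "probe_amplitude": 100.0,
    "probe_trials": 8,
    "visual_channel_cap": 64,
    "exposure_stdp": {"A_plus": 0.016, "A_minus": 0.010,
                      "A_plus_in": 0.016, "A_minus_in": 0.010},
}


def neonate_multimodal_stream(cfg: dict | None = None):
    """Scripted arm-in-front-of-eyes movement on a 40-week body.

    Returns a receptor stream with tactile, proprioceptive and visual
    channels; the arm sweep lights the cameras in synchrony with arm
    proprioception and hand-face touch.
    """
    cfg = {**DEFAULT_MULTIMODAL, **(cfg or {})}
    body = build_fetus_body(cfg["age_weeks"], cfg["taxel_distribution"],
                            cfg["taxel_count"])
    # swing the right arm from a lowered posture (hand outside the visual
    # field) up in front of the face and back, repeatedly
    script = [(0.0, {"shoulder_r": -1.0, "elbow_r": 0.6})]
    t = 0.0
    for _ in range(cfg["n_sweeps"]):
        t += cfg["sweep_period"] / 2
        script.append((t, {"shoulder_r": 0.4, "elbow_r": -0.3}))
        t += cfg["sweep_period"] / 2
        script.append((t, {"shoulder_r": -1.0, "elbow_r": 0.6}))
    traj = scripted_trajectory(body, script, env=Environment.flat_plane(),
                               visual_on=True)
    stream = traj.to_stream(("tactile", "proprio", "visual"))
    # cap visual channels (pool pixels) so the input map stays small
    vis = np.asarray(stream.part_labels) == "visual"
    n_vis = int(vis.sum())
    cap = cfg["visual_channel_cap"]
    if n_vis > cap:
        vis_idx = np.nonzero(vis)[0]
        keep = np.nonzero(~vis)[0]
        pooled = np.stack([stream.values[:, g].mean(axis=1)
                           for g in np.array_split(vis_idx, cap)], axis=1)
        stream.values = np.concatenate([stream.values[:, keep], pooled], axis=1)
        stream.part_labels = [stream.part_labels[i] for i in keep] + ["visual"] * cap
        stream.modality = [stream.modality[i] for i in keep] + ["visual"] * cap
    return traj, stream


def _extend_visual_inputs(net: CortexNet, n_visual: int, seed: int,
                          n_diffuse: int = 10, w_diffuse: float = 0.12) -> CortexNet:
    """Append visual afferents to a trained net (fresh synapses).

    Each channel gets a retinotopic patch in the visual zone plus a set of
    weak diffuse projections scattered over the whole sheet — the exuberant
    immature projections of the newborn cortex.  The diffuse synapses are
    plastic: exposure strengthens exactly those landing on neurons that fire
    coherently with the visual stream (e.g. the moving arm's somatosensory
    patch) and lets the rest decay.
    """
    rng = np.random.default_rng(seed)
    ext = net.copy()
    side = max(int(np.ceil(np.sqrt(n_visual))), 1)
    in_post = [ext.in_post]
    in_w = [ext.in_w]
    in_plastic = [ext.in_plastic]
    indptr = list(ext.in_indptr)
    for k in range(n_visual):
        gx, gy = k % side, k // side
        c = np.array([ext.somato_frac + 0.03
                      + (1 - ext.somato_frac - 0.06) * gx / max(side - 1, 1),
                      0.05 + 0.9 * gy / max(side - 1, 1)])
        d2 = np.sum((ext.positions - c) ** 2, axis=1)
        targets = np.argsort(d2)[:12]
        diffuse = rng.choice(ext.n_neurons, size=n_diffuse, replace=False)
        targets = np.concatenate([targets, diffuse])
        w = np.concatenate([0.45 * rng.uniform(0.5, 1.0, 12),
                            w_diffuse * rng.uniform(0.5, 1.0, n_diffuse)])
        in_post.append(targets.astype(np.int64))
        in_w.append(w)
        in_plastic.append(ext.is_exc[targets].astype(np.int8))
        indptr.append(indptr[-1] + len(targets))
    ext.in_indptr = np.asarray(indptr, dtype=np.int64)
    ext.in_post = np.concatenate(in_post)
    ext.in_w = np.concatenate(in_w)
    ext.in_plastic = np.concatenate(in_plastic)
    ext.channel_labels = list(ext.channel_labels) + ["visual"] * n_visual
    ext._t_cache = {}
    return ext


def run_multimodal_experiment(trained_nets: dict, seeds=None,
                              config: dict | None = None):
    """Compare multimodal integration between the two trained cortices.

    ``trained_nets``: ``{seed: {"intrauterine": net, "extrauterine": net}}``.
    Per seed and condition: extend the net with identical visual afferents,
    expose it to the same synchronized multimodal stream (STDP on), then
    probe the moving arm's somatosensory channels, the visual channels, and
    their combination; the multimodal index is the combined-response norm
    over the sum of unimodal norms.  Sign test across seeds for
    intrauterine > extrauterine.
    """
    cfg = {**DEFAULT_MULTIMODAL, **(config or {})}
    if seeds is None:
        seeds = sorted(trained_nets)
    report = make_report("multimodal", cfg, seeds)
    _, stream = neonate_multimodal_stream(cfg)
    labels = np.asarray(stream.part_labels)
    modality = np.asarray(stream.modality)
    vis_ch = np.nonzero(modality == "visual")[0]
    # channels of the moving (right) arm, tactile + proprio
    arm_ch = np.nonzero((labels == "arm_r") & (modality != "visual"))[0]
    idx = {"intrauterine": [], "extrauterine": []}
    for seed in seeds:
        for cond in ("intrauterine", "extrauterine"):
            base = trained_nets[seed][cond]
            n_miss = stream.n_channels - base.n_channels
            if n_miss < 0:
                raise ValueError("trained net has more channels than the stream")
            net = _extend_visual_inputs(base, n_miss, seed) if n_miss else base.copy()
            if "visual" not in net.channel_labels:
                raise ValueError("missing visual channel block")
            # postnatal critical-period exposure: potentiation-biased STDP
            # so synchronized cross-modal co-activation associates
            net.stdp_params = dict(net.stdp_params)
            net.stdp_params.update(cfg.get("exposure_stdp", {}))
            net, _ = train_on_stream(net, stream, duration=cfg["exposure_duration"],
                                     seed=seed)
            kw = dict(amplitude=cfg["probe_amplitude"],
                      n_trials=cfg["probe_trials"], seed=seed)
            r_arm = stimulate_probe(net, arm_ch, label="arm", **kw)
            r_vis = stimulate_probe(net, vis_ch, label="visual", **kw)
            r_all = stimulate_probe(net, np.concatenate([arm_ch, vis_ch]),
                                    label="arm+visual", **kw)
            idx[cond].append(multimodal_index(r_all.response,
                                              [r_arm.response, r_vis.response]))
    intra = np.asarray(idx["intrauterine"])
    extra = np.asarray(idx["extrauterine"])
    wins = int(np.sum(intra > extra))
    n_eff = int(np.sum(intra != extra))
    p = stats.binomtest(wins, n_eff, 0.5, alternative="greater").pvalue \
        if n_eff else 1.0
    report.metrics = {"multimodal_index": idx}
    report.summary = {
        "mean_index_intra": float(intra.mean()),
        "mean_index_extra": float(extra.mean()),
        "wins_intra": wins,
        "n_seeds": len(seeds),
        "sign_test_p": float(p),
    }
    report.verdicts = {
        "intra_stronger_multimodal": wins > len(seeds) / 2,
        "sign_test_p05": bool(p < 0.05),
    }
    return report


def multimodal_contrast(seeds=(0, 1, 2, 3, 4, 5, 6, 7, 8, 9),
                        bodymap_config: dict | None = None,
                        config: dict | None = None, trained: dict | None = None):
    """End-to-end: train both conditions per seed, then compare integration."""
    from .bodymap import train_condition
    nets = {}
    for seed in seeds:
        nets[seed] = {}
        for cond in ("intrauterine", "extrauterine"):
            if trained is not None and seed in trained and cond in trained[seed]:
                nets[seed][cond] = trained[seed][cond][0]
            else:
                nets[seed][cond] = train_condition(cond, seed, bodymap_config)[0]
    return run_multimodal_experiment(nets, seeds, config)
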