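"""Body-map acquisition: intrauterine vs. extrauterine learning.

A fetus driven by its spinal oscillators moves spontaneously either in the
fluid-filled uterus or lying on a flat plane (an extreme preterm analogue);
the cortex passively learns the evoked receptor stream; each body part is
then probed and the segregation of the resulting response maps compared.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..controllers import SpinalController
from ..cortex import attach_inputs, build_cortex, probe_body_parts, train_on_stream
from ..embodiment import Environment, build_fetus_body, compiled, simulate
from ..embodiment.physics import Kinematics, BodyState
from ..metrics import segregation_index
from .report import make_report

__all__ = ["run_bodymap_experiment", "bodymap_contrast", "train_condition",
           "receptor_correlation_stats", "DEFAULT_BODYMAP"]

DEFAULT_BODYMAP = {
    "age_weeks": 32.0,
    "taxel_distribution": "humanlike",
    "taxel_count": 300,
    "sim_duration": 30.0,
    "dt": 0.002,
    "control_dt": 0.01,
    "n_neurons": 2000,
    "train_duration": 100.0,
    "probe_amplitude": 150.0,
    "probe_trials": 5,
    "r_max": 100.0,
}


def fitted_uterus(body, margin: float = 1.12) -> Environment:
    """Uterus sized to the body: wall radius from the curled-posture extent."""
    cb = compiled(body)
    state = BodyState.initial(cb)
    kin = Kinematics(cb, state)
    center = kin.taxel_pos.mean(axis=0)
    radius = margin * float(np.max(np.linalg.norm(kin.taxel_pos - center, axis=1)))
    return Environment.uterus(radius=radius)


def _environment(condition: str, body) -> Environment:
    if condition == "intrauterine":
        return fitted_uterus(body)
    if condition == "extrauterine":
        return Environment.flat_plane()
    raise ValueError(f"unknown condition {condition!r}")


def spontaneous_stream(condition: str, seed: int, cfg: dict):
    """Simulate spontaneous movement and return (trajectory, receptor stream)."""
    body = build_fetus_body(cfg["age_weeks"], cfg["taxel_distribution"],
                            cfg["taxel_count"])
    env = _environment(condition, body)
    cb = compiled(body)
    ctrl = SpinalController(cb.n_muscles, seed=seed)
    # the fluid chamber is contact-soft, so it tolerates the coarser step
    dt = 0.004 if env.kind == "uterus_fluid" else cfg["dt"]
    traj = simulate(body, env, ctrl, cfg["sim_duration"], dt=dt,
                    control_dt=cfg["control_dt"], seed=seed)
    return traj, traj.to_stream(("tactile", "proprio"))


def train_condition(condition: str, seed: int, cfg: dict | None = None,
                    stdp_on: bool = True):
    """Full pipeline for one condition/seed; returns (trained net, info).

    The cortex and its input map are built from the seed only, so paired
    conditions start from identical networks.
    """
    cfg = {**DEFAULT_BODYMAP, **(cfg or {})}
    traj, stream = spontaneous_stream(condition, seed, cfg)
    net = build_cortex(cfg["n_neurons"], seed=seed)
    attach_inputs(net, stream.part_labels, seed=seed)
    trained, log = train_on_stream(net, stream, duration=cfg["train_duration"],
                                   seed=seed, r_max=cfg["r_max"], stdp_on=stdp_on)
    return trained, {"traj": traj, "stream": stream, "log": log}


def segregation_for(net, cfg: dict | None = None, seed: int = 0):
    cfg = {**DEFAULT_BODYMAP, **(cfg or {})}
    maps = probe_body_parts(net, amplitude=cfg["probe_amplitude"],
                            n_trials=cfg["probe_trials"], seed=seed)
    score = segregation_index({p: m.response for p, m in maps.items()})
    return score, maps


def receptor_correlation_stats(traj, min_std: float = 1e-6):
    """Mean within-part and cross-part pairwise tactile correlations."""
    x = traj.tactile
    parts = np.asarray(traj.taxel_parts)
    active = x.std(axis=0) > min_std
    x = x[:, active]
    parts = parts[active]
    if x.shape[1] < 4:
        return {"within": np.nan, "between": np.nan, "n_active": int(x.shape[1])}
    c = np.corrcoef(x.T)
    same = parts[:, None] == parts[None, :]
    iu = np.triu_indices(len(parts), k=1)
    cm, sm = c[iu], same[iu]
    return {"within": float(np.nanmean(cm[sm])) if sm.any() else np.nan,
            "between": float(np.nanmean(cm[~sm])) if (~sm).any() else np.nan,
            "n_active": int(x.shape[1])}


def run_bodymap_experiment(condition: str, duration: float | None = None,
                           cortex_config: dict | None = None,
                           seeds=(0, 1, 2, 3, 4), stdp_on: bool = True):
    """Body-map learning under one condition across seeds."""
    cfg = {**DEFAULT_BODYMAP, **(cortex_config or {})}
    if duration is not None:
        cfg["train_duration"] = duration
    report = make_report(f"bodymap-{condition}", cfg, seeds)
    seg_vals, corrs = [], []
    for seed in seeds:
        net, info = train_condition(condition, seed, cfg, stdp_on=stdp_on)
        if info["log"]["mean_rate"] == 0.0:
            report.verdicts.setdefault("silent_cortex_flagged", True)
        score, _ = segregation_for(net, cfg, seed=seed)
        seg_vals.append(score.value)
        corrs.append(receptor_correlation_stats(info["traj"]))
    report.metrics = {"segregation": seg_vals, "receptor_correlations": corrs}
    report.summary = {
        "mean_segregation": float(np.mean(seg_vals)),
        "mean_within_corr": float(np.nanmean([c["within"] for c in corrs])),
        "mean_between_corr": float(np.nanmean([c["between"] for c in corrs])),
    }
    return report


def bodymap_contrast(seeds=(0, 1, 2, 3, 4, 5, 6, 7, 8, 9),
                     cortex_config: dict | None = None,
                     trained: dict | None = None):
    """Paired intrauterine-vs-extrauterine contrast across seeds.

    Same seeds (hence identical initial networks and bodies) in both
    conditions; one-sided paired t-test for segregation(intra) >
    segregation(extra), plus the receptor-correlation precheck (within-limb
    correlation higher in fluid, cross-part correlation higher on the
    plane).  ``trained`` optionally supplies precomputed
    ``{seed: {condition: (net, info)}}`` to avoid re-simulation.
    """
    cfg = {**DEFAULT_BODYMAP, **(cortex_config or {})}
    report = make_report("bodymap-contrast", cfg, seeds)
    seg = {"intrauterine": [], "extrauterine": []}
    corr = {"intrauterine": [], "extrauterine": []}
    for seed in seeds:
        for cond in ("intrauterine", "extrauterine"):
            if trained is not None and seed in trained and cond in trained[seed]:
                net, info = trained[seed][cond]
            else:
                net, info = train_condition(cond, seed, cfg)
            score, _ = segregation_for(net, cfg, seed=seed)
            seg[cond].append(score.value)
            corr[cond].append(receptor_correlation_stats(info["traj"]))
    intra = np.asarray(seg["intrauterine"])
    extra = np.asarray(seg["extrauterine"])
    t_res = stats.ttest_rel(intra, extra, alternative="greater")
    within_fluid = np.nanmean([c["within"] for c in corr["intrauterine"]])
    within_plane = np.nanmean([c["within"] for c in corr["extrauterine"]])
    between_fluid = np.nanmean([c["between"] for c in corr["intrauterine"]])
    between_plane = np.nanmean([c["between"] for c in corr["extrauterine"]])
    report.metrics = {"segregation": seg, "receptor_correlations": corr}
    report.summary = {
        "mean_segregation_intra": float(intra.mean()),
        "mean_segregation_extra": float(extra.mean()),
        "paired_t": float(t_res.statistic),
        "p_one_sided": float(t_res.pvalue),
        "within_corr_fluid": float(within_fluid),
        "within_corr_plane": float(within_plane),
        "between_corr_fluid": float(between_fluid),
        "between_corr_plane": float(between_plane),
    }
    report.verdicts = {
        "intra_more_segregated": bool(np.mean(intra > extra) > 0.5),
        "significant_p05": bool(t_res.pvalue < 0.05),
        "within_corr_higher_in_fluid": bool(within_fluid > within_plane),
        "between_corr_higher_on_plane": bool(between_plane > between_fluid),
    }
    return report
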