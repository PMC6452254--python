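"""Scaled-down spiking cortical sheet: LIF neurons with STDP.

Neurons live on a flat unit square; 5/6 are excitatory and 1/6 inhibitory
(the 5:1 ratio held exactly), with distance-dependent random connectivity
and Dale's principle enforced.  Receptor channels project topographically
into a somatosensory zone (one patch per body part) and a visual zone and
are rate-coded into inhomogeneous Poisson spikes.  Pair-based additive STDP
acts on excitatory->excitatory synapses (recurrent and afferent) only.

Internal units: millivolts and milliseconds.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from ..controllers import ConfigurationError, NumericalDivergenceError
from ._kernels import run_network

__all__ = ["CortexNet", "CortexState", "ResponseMap", "build_cortex",
           "attach_inputs", "lif_step", "stdp_update", "run_resting",
           "train_on_stream", "stimulate_probe", "lif_fi_rate",
           "DEFAULT_LIF", "DEFAULT_STDP"]

DEFAULT_LIF = {"tau_m": 20.0, "v_rest": -65.0, "v_thresh": -50.0,
               "v_reset": -65.0, "refractory": 2.0, "tau_syn": 5.0}
#: Depression-dominant pair balance: sharpens representations by letting
#: uncorrelated coincidences decay.  The afferent balance can be overridden
#: separately (A_plus_in/A_minus_in), e.g. for critical-period phases.
DEFAULT_STDP = {"A_plus": 0.012, "A_minus": 0.014,
                "A_plus_in": 0.012, "A_minus_in": 0.014,
                "tau_plus": 20.0, "tau_minus": 20.0, "w_max": 1.0}


@dataclass
class CortexNet:
    n_neurons: int
    positions: np.ndarray            # (n, 2) on the unit square
    is_exc: np.ndarray               # bool per neuron
    indptr: np.ndarray               # recurrent CSR by presynaptic neuron
    post_idx: np.ndarray
    w: np.ndarray                    # signed weights (Dale's principle)
    plastic: np.ndarray              # int8 per synapse (E->E only)
    lif_params: dict = field(default_factory=lambda: dict(DEFAULT_LIF))
    stdp_params: dict = field(default_factory=lambda: dict(DEFAULT_STDP))
    # afferent inputs (CSR by channel); empty until attach_inputs
    in_indptr: np.ndarray = field(default_factory=lambda: np.zeros(1, dtype=np.int64))
    in_post: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    in_w: np.ndarray = field(default_factory=lambda: np.zeros(0))
    in_plastic: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    in_w_max: float = 1.0
    channel_labels: list = field(default_factory=list)
    part_centers: dict = field(default_factory=dict)
    somato_frac: float = 0.7
    bg_rate: float = 200.0           # Hz Poisson background per neuron
    bg_w: float = 0.3                # mV/ms kick per background spike
    bg_scale: np.ndarray | None = None  # per-neuron excitability multiplier
    seed: int | None = None
    _t_cache: dict = field(default_factory=dict, repr=False)

    @property
    def ei_ratio(self):
        return int(np.sum(self.is_exc)) // max(int(np.sum(~self.is_exc)), 1)

    @property
    def n_channels(self):
        return len(self.in_indptr) - 1

    def copy(self):
        c = _copy.deepcopy(self)
        c._t_cache = {}
        return c

    def transpose_index(self):
        """Incoming-synapse views (by postsynaptic neuron), cached."""
        if "t" not in self._t_cache:
            self._t_cache["t"] = _transpose(self.indptr, self.post_idx,
                                            self.n_neurons)
            self._t_cache["tin"] = _transpose(self.in_indptr, self.in_post,
                                              self.n_neurons)
        return self._t_cache["t"], self._t_cache["tin"]


def _transpose(indptr, post, n):
    order = np.argsort(post, kind="stable")
    tindptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(tindptr[1:], post, 1)
    tindptr = np.cumsum(tindptr)
    pre = np.searchsorted(indptr, np.arange(len(post)), side="right") - 1
    return tindptr.astype(np.int64), order.astype(np.int64), pre[order].astype(np.int64)


@dataclass
class CortexState:
    v: np.ndarray
    refr: np.ndarray
    isyn: np.ndarray
    inbox: np.ndarray
    tr_pre: np.ndarray
    tr_post: np.ndarray
    tr_ch: np.ndarray

    @classmethod
    def initial(cls, net: CortexNet):
        n = net.n_neurons
        return cls(v=np.full(n, net.lif_params["v_rest"]),
                   refr=np.zeros(n, dtype=np.int64),
                   isyn=np.zeros(n), inbox=np.zeros(n),
                   tr_pre=np.zeros(n), tr_post=np.zeros(n),
                   tr_ch=np.zeros(max(net.n_channels, 1)))


@dataclass
class ResponseMap:
    stimulus: str
    response: np.ndarray      # per-neuron evoked rate increase, spikes/s
    amplitude: float
    duration: float
    n_trials: int
    seed: int | None


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_cortex(n_neurons: int = 2000, connection_radius: float = 0.18,
                 connection_prob: float = 0.6, seed: int | None = 0,
                 w_exc: float = 0.22, w_inh_factor: float = 4.0,
                 lif_params: dict | None = None,
                 stdp_params: dict | None = None) -> CortexNet:
    """Place neurons on a unit sheet with distance-decaying random synapses.

    ``connection_prob`` is the probability at zero distance; it decays with
    a Gaussian kernel of width ``connection_radius``.  Exactly five sixths
    of the neurons are excitatory (a configuration error otherwise);
    excitatory weights are lognormal around ``w_exc`` and inhibitory
    weights are ``-w_inh_factor`` times the mean excitatory weight.
    """
    if n_neurons < 120 or n_neurons % 6 != 0:
        raise ConfigurationError(
            f"n_neurons must be >= 120 and divisible by 6 for an exact 5:1 "
            f"E:I ratio, got {n_neurons}")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 1.0, size=(n_neurons, 2))
    is_exc = np.zeros(n_neurons, dtype=bool)
    is_exc[rng.permutation(n_neurons)[: 5 * n_neurons // 6]] = True
    indptr = [0]
    posts, ws, plast = [], [], []
    w_i = -w_inh_factor * w_exc
    for i in range(n_neurons):
        d2 = np.sum((pos - pos[i]) ** 2, axis=1)
        p = connection_prob * np.exp(-d2 / (2 * connection_radius ** 2))
        p[i] = 0.0
        targets = np.nonzero(rng.random(n_neurons) < p)[0]
        posts.append(targets)
        if is_exc[i]:
            ws.append(w_exc * rng.lognormal(mean=-0.5, sigma=1.0, size=len(targets)))
            plast.append(is_exc[targets].astype(np.int8))
        else:
            ws.append(np.full(len(targets), w_i))
            plast.append(np.zeros(len(targets), dtype=np.int8))
        indptr.append(indptr[-1] + len(targets))
    stdp = dict(DEFAULT_STDP)
    stdp.update(stdp_params or {})
    lif = dict(DEFAULT_LIF)
    lif.update(lif_params or {})
    bg_scale = rng.lognormal(mean=-0.08, sigma=0.4, size=n_neurons)
    return CortexNet(
        bg_scale=bg_scale,
        n_neurons=n_neurons, positions=pos, is_exc=is_exc,
        indptr=np.asarray(indptr, dtype=np.int64),
        post_idx=(np.concatenate(posts).astype(np.int64) if posts else
                  np.zeros(0, dtype=np.int64)),
        w=np.concatenate(ws) if ws else np.zeros(0),
        plastic=np.concatenate(plast) if plast else np.zeros(0, dtype=np.int8),
        lif_params=lif, stdp_params=stdp, seed=seed)


def attach_inputs(net: CortexNet, part_labels, modality=None,
                  targets_per_channel: int = 20, w_in: float = 0.45,
                  in_w_max_factor: float = 3.0, patch_sigma: float = 0.1,
                  seed: int | None = 0) -> CortexNet:
    """Topographic afferent map: one somatosensory patch per body part.

    Somatic parts get patch centers inside the somatosensory zone
    (``x < somato_frac``), ``visual`` channels map retinotopically into the
    remaining strip.  Each channel connects to its ``targets_per_channel``
    nearest neurons around a jittered point near its part's center.
    Channel->excitatory synapses are plastic.
    """
    rng = np.random.default_rng(seed)
    labels = list(part_labels)
    # fixed somatotopic ordering: hand/arm regions sit at angle 0, i.e.
    # nearest the visual strip, so cross-modal recurrent synapses exist
    # within the local connection radius (as at the real hand-area border)
    canonical = ["arm_r", "arm_l", "head", "trunk", "leg_l", "leg_r"]
    found = {p for p in labels if p != "visual"}
    parts = [p for p in canonical if p in found] + sorted(found - set(canonical))
    n_parts = max(len(parts), 1)
    centers = {}
    for k, p in enumerate(parts):
        ang = 2 * np.pi * k / n_parts
        centers[p] = np.array([0.35 + 0.22 * np.cos(ang),
                               0.5 + 0.33 * np.sin(ang)])
    vis_idx = [i for i, p in enumerate(labels) if p == "visual"]
    n_vis = len(vis_idx)
    in_indptr = [0]
    in_post, in_w, in_plastic = [], [], []
    vis_count = 0
    for i, p in enumerate(labels):
        if p == "visual":
            side = max(int(np.ceil(np.sqrt(n_vis))), 1)
            gx, gy = vis_count % side, vis_count // side
            c = np.array([net.somato_frac + 0.03 + (1 - net.somato_frac - 0.06) * gx / max(side - 1, 1),
                          0.05 + 0.9 * gy / max(side - 1, 1)])
            vis_count += 1
        else:
            c = centers[p] + rng.normal(0.0, patch_sigma, 2)
        d2 = np.sum((net.positions - c) ** 2, axis=1)
        targets = np.argsort(d2)[:targets_per_channel]
        in_post.append(targets)
        in_w.append(w_in * rng.uniform(0.5, 1.0, len(targets)))
        in_plastic.append(net.is_exc[targets].astype(np.int8))
        in_indptr.append(in_indptr[-1] + len(targets))
    net.in_indptr = np.asarray(in_indptr, dtype=np.int64)
    net.in_post = np.concatenate(in_post).astype(np.int64)
    net.in_w = np.concatenate(in_w)
    net.in_plastic = np.concatenate(in_plastic)
    net.in_w_max = in_w_max_factor * w_in
    net.channel_labels = labels
    net.part_centers = centers
    net._t_cache = {}
    return net


# ---------------------------------------------------------------------------
# Reference single-step LIF (numpy; oracle for the numba kernel)
# ---------------------------------------------------------------------------

def lif_step(net: CortexNet, state: CortexState, input_current, dt: float):
    """One LIF step (dt in ms, currents in mV/ms); returns (spikes, state).

    ``dV = dt/tau_m * (v_rest - V) + dt * I``; threshold crossing emits a
    spike, resets the membrane and enforces the refractory period.  Synaptic
    currents from last step's spikes decay exponentially with ``tau_syn``.
    This numpy path is the reference the numba kernel is tested against.
    """
    if dt > 1.0:
        raise ValueError(f"dt must be <= 1 ms, got {dt:g}")
    p = net.lif_params
    state.isyn = state.isyn * np.exp(-dt / p["tau_syn"]) + state.inbox
    state.inbox = np.zeros_like(state.inbox)
    refr = state.refr > 0
    state.refr[refr] -= 1
    state.v[refr] = p["v_reset"]
    I = state.isyn + np.asarray(input_current, dtype=float)
    state.v[~refr] += dt / p["tau_m"] * (p["v_rest"] - state.v[~refr]) \
        + dt * I[~refr]
    if not np.all(np.isfinite(state.v)):
        raise NumericalDivergenceError("membrane potential diverged")
    spikes = np.nonzero((state.refr == 0) & (state.v >= p["v_thresh"]))[0]
    state.v[spikes] = p["v_reset"]
    state.refr[spikes] = int(round(p["refractory"] / dt))
    np.add.at(state.inbox, net.post_idx[np.concatenate(
        [np.arange(net.indptr[i], net.indptr[i + 1]) for i in spikes])]
        if len(spikes) else np.zeros(0, dtype=int),
        net.w[np.concatenate(
            [np.arange(net.indptr[i], net.indptr[i + 1]) for i in spikes])]
        if len(spikes) else np.zeros(0))
    return spikes, state


def stdp_update(net: CortexNet, pre_trace, post_trace, pre_spiked, post_spiked):
    """Apply one pair-based STDP update to all plastic recurrent synapses.

    For every plastic synapse i->j: if j spiked, ``dw = +A_plus *
    pre_trace[i]`` (pre-before-post potentiation); if i spiked, ``dw =
    -A_minus * post_trace[j]`` (post-before-pre depression).  Weights are
    clipped to [0, w_max].  Returns the updated weight array.
    """
    s = net.stdp_params
    pre = np.searchsorted(net.indptr, np.arange(len(net.post_idx)), side="right") - 1
    post = net.post_idx
    dw = np.zeros_like(net.w)
    mask = net.plastic.astype(bool)
    dw[mask & np.asarray(post_spiked)[post]] += \
        s["A_plus"] * np.asarray(pre_trace)[pre][mask & np.asarray(post_spiked)[post]]
    dw[mask & np.asarray(pre_spiked)[pre]] -= \
        s["A_minus"] * np.asarray(post_trace)[post][mask & np.asarray(pre_spiked)[pre]]
    net.w = np.where(mask, np.clip(net.w + dw, 0.0, s["w_max"]), net.w)
    return net.w


def lif_fi_rate(net_or_params, I: float) -> float:
    """Closed-form steady firing rate of one LIF neuron at constant drive.

    ``rate = 1 / (t_ref + tau_m * ln(I*tau_m / (I*tau_m - (v_th - v_rest))))``
    in spikes/ms for I in mV/ms; returns spikes/s.  Zero below rheobase.
    """
    p = net_or_params.lif_params if hasattr(net_or_params, "lif_params") else net_or_params
    drive = I * p["tau_m"]
    gap = p["v_thresh"] - p["v_rest"]
    if drive <= gap:
        return 0.0
    t = p["refractory"] + p["tau_m"] * np.log(drive / (drive - gap))
    return 1000.0 / t


# ---------------------------------------------------------------------------
# Batched runs (numba kernel)
# ---------------------------------------------------------------------------

def _run(net, state, rates, duration_ms, dt, stdp_on, seed, bg_rate=None,
         record_cap=0):
    (tindptr, tsyn, tpre), (tin_indptr, tin_syn, tin_ch) = net.transpose_index()
    p, s = net.lif_params, net.stdp_params
    n_steps = int(round(duration_ms / dt))
    if rates is None or rates.size == 0:
        rates = np.zeros((1, max(net.n_channels, 1)))
        steps_per_frame = max(n_steps, 1)
    else:
        steps_per_frame = max(int(round(duration_ms / dt / rates.shape[0])), 1)
    counts = np.zeros(net.n_neurons, dtype=np.int64)
    rec_nid = np.zeros(record_cap, dtype=np.int64)
    rec_t = np.zeros(record_cap)
    bg = net.bg_rate if bg_rate is None else bg_rate
    bg_scale = net.bg_scale if net.bg_scale is not None else np.ones(net.n_neurons)
    n_rec, sum_v, dw_acc = run_network(
        net.indptr, net.post_idx, net.w, net.plastic,
        tindptr, tsyn, tpre,
        net.in_indptr, net.in_post, net.in_w, net.in_plastic,
        tin_indptr, tin_syn, tin_ch,
        np.ascontiguousarray(rates, dtype=np.float64), steps_per_frame,
        n_steps, dt,
        state.v, state.refr, state.isyn, state.inbox,
        state.tr_pre, state.tr_post, state.tr_ch,
        p["v_rest"], p["v_thresh"], p["v_reset"], p["tau_m"],
        int(round(p["refractory"] / dt)), p["tau_syn"],
        stdp_on, s["A_plus"], s["A_minus"],
        s.get("A_plus_in", s["A_plus"]), s.get("A_minus_in", s["A_minus"]),
        s["tau_plus"], s["tau_minus"], s["w_max"], net.in_w_max,
        bg * bg_scale, net.bg_w, np.uint32(seed) & 0x7FFFFFFF,
        counts, rec_nid, rec_t)
    if not np.all(np.isfinite(state.v)):
        raise NumericalDivergenceError("membrane potential diverged")
    return {"counts": counts, "sum_v": sum_v, "dw": dw_acc, "n_steps": n_steps,
            "spike_nid": rec_nid[:n_rec], "spike_t": rec_t[:n_rec]}


def run_resting(net: CortexNet, duration: float = 10.0, bg_rate: float | None = None,
                seed: int = 0, dt: float = 1.0, record_spikes: bool = False):
    """Spontaneous activity statistics over ``duration`` seconds.

    Returns per-neuron rates, E/I population rates, mean membrane
    depolarization relative to rest, and a ``degenerate`` flag when the
    network stays silent (not an exception).
    """
    if duration < 10.0:
        raise ValueError("need duration >= 10 s for resting statistics")
    state = CortexState.initial(net)
    cap = int(2e6) if record_spikes else 0
    out = _run(net, state, None, duration * 1000.0, dt, False, seed,
               bg_rate=bg_rate, record_cap=cap)
    rates = out["counts"] / duration
    res = {
        "rates": rates,
        "e_rate": float(rates[net.is_exc].mean()),
        "i_rate": float(rates[~net.is_exc].mean()),
        "mean_depolarization": out["sum_v"] / (net.n_neurons * out["n_steps"])
        - net.lif_params["v_rest"],
        "degenerate": bool(out["counts"].sum() == 0),
    }
    if record_spikes:
        res["spike_neuron"] = out["spike_nid"]
        res["spike_time_s"] = out["spike_t"] / 1000.0
    return res


def train_on_stream(net: CortexNet, stream, duration: float | None = None,
                    seed: int = 0, r_max: float = 100.0, dt: float = 1.0,
                    normalize: bool = True, stdp_on: bool = True):
    """STDP learning on a receptor stream; returns (trained net, log).

    Receptor values are rate-coded as inhomogeneous Poisson spikes with
    ``rate = r_max * value`` after per-channel 95th-percentile
    normalization.  The stream's channels must match the attached input
    map.  The log reports the cumulative absolute weight change.
    """
    if stream.n_channels != net.n_channels:
        raise ConfigurationError(
            f"stream has {stream.n_channels} channels but the input map covers "
            f"{net.n_channels}")
    vals = stream.values
    if normalize:
        scale = np.quantile(vals, 0.95, axis=0)
        vals = np.clip(vals / np.maximum(scale, 1e-9), 0.0, 1.0)
    rates = r_max * vals
    if duration is None:
        duration = stream.duration
    n_frames_needed = int(round(duration / stream.dt))
    reps = int(np.ceil(n_frames_needed / max(rates.shape[0], 1)))
    if reps > 1:
        rates = np.tile(rates, (reps, 1))
    rates = rates[:n_frames_needed]
    trained = net.copy()
    state = CortexState.initial(trained)
    w0 = trained.w.copy()
    in_w0 = trained.in_w.copy()
    out = _run(trained, state, rates, duration * 1000.0, dt, stdp_on, seed)
    log = {
        "cumulative_dw": float(out["dw"]),
        "net_dw": float(np.sum(np.abs(trained.w - w0))
                        + np.sum(np.abs(trained.in_w - in_w0))),
        "mean_rate": float(out["counts"].sum() / trained.n_neurons
                           / (duration if duration else 1.0)),
    }
    return trained, log


def stimulate_probe(net: CortexNet, channels, amplitude: float = 150.0,
                    n_trials: int = 5, seed: int = 0, t_baseline: float = 0.3,
                    t_evoked: float = 0.3, dt: float = 1.0,
                    label: str = "") -> ResponseMap:
    """Evoked-minus-baseline response map for a channel subset.

    Each trial runs a baseline window (background only) and an evoked window
    with the given channels driven at ``amplitude`` Hz; the response is the
    per-neuron rate difference averaged over trials.  STDP is frozen during
    probing.
    """
    channels = np.asarray(channels, dtype=int)
    if channels.size == 0:
        raise ConfigurationError("empty probe channel set")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    probe_net = net.copy()  # probing must not alter the trained weights
    resp = np.zeros(net.n_neurons)
    rates = np.zeros((1, net.n_channels))
    rates[0, channels] = amplitude
    state = CortexState.initial(probe_net)
    for trial in range(n_trials):
        base = _run(probe_net, state, None, t_baseline * 1000.0, dt, False,
                    seed * 10007 + 2 * trial)
        ev = _run(probe_net, state, rates, t_evoked * 1000.0, dt, False,
                  seed * 10007 + 2 * trial + 1)
        resp += ev["counts"] / t_evoked - base["counts"] / t_baseline
    return ResponseMap(stimulus=label or f"{len(channels)} channels",
                       response=resp / n_trials, amplitude=amplitude,
                       duration=t_evoked, n_trials=n_trials, seed=seed)


def probe_body_parts(net: CortexNet, amplitude: float = 150.0,
                     n_trials: int = 5, seed: int = 0,
                     modalities=("tactile",), channel_modality=None,
                     **kw) -> dict:
    """One tactile response map per body part (all its channels together)."""
    labels = np.asarray(net.channel_labels)
    maps = {}
    for part in sorted({p for p in net.channel_labels if p != "visual"}):
        sel = labels == part
        if channel_modality is not None:
            sel &= np.isin(np.asarray(channel_modality), list(modalities))
        ch = np.nonzero(sel)[0]
        if ch.size == 0:
            continue
        maps[part] = stimulate_probe(net, ch, amplitude=amplitude,
                                     n_trials=n_trials, seed=seed,
                                     label=part, **kw)
    return maps
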