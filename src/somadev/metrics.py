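"""Analysis statistics for emergent behaviour and learning outcomes.

Covers the dynamical-systems side (Lyapunov exponent of the controller map,
phase-locking values, detrended fluctuation analysis) and the behavioural /
cortical side (jerk and contact event rates, body-map segregation,
multimodal integration, onset detection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import hilbert

__all__ = [
    "largest_lyapunov_map",
    "chaos_onset_alpha",
    "phase_sync_matrix",
    "windowed_plv",
    "phase_pattern_similarity",
    "rolling_pattern_stability",
    "dfa_exponent",
    "jerk_event_times",
    "jerk_event_rate",
    "contact_event_times",
    "contact_event_rate",
    "SegregationScore",
    "segregation_index",
    "multimodal_index",
    "onset_time",
    "surrogate_plv_bound",
]


# ---------------------------------------------------------------------------
# Lyapunov exponent of the quadratic map
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lyap_orbit(alpha, n_iter, burn_in, x0):
    x = x0
    for _ in range(burn_in):
        x = 1.0 - alpha * x * x
    acc = 0.0
    eps = 1e-12
    for _ in range(n_iter):
        d = abs(2.0 * alpha * x)
        if d < eps:
            d = eps  # orbit touching x=0 exactly; guard the log
        acc += np.log(d)
        x = 1.0 - alpha * x * x
    return acc / n_iter


def largest_lyapunov_map(alpha: float, n_iter: int = 1_000_000,
                         burn_in: int = 1_000, x0: float = 0.1) -> float:
    """Largest Lyapunov exponent (nats/iteration) of ``f(x)=1-alpha*x**2``.

    Orbit average of ``ln|f'(x)| = ln|2*alpha*x|`` after a burn-in.  At
    alpha=2 the map is conjugate to the tent map and the exponent is ln 2.
    """
    if not (0.0 <= alpha <= 2.0):
        raise ValueError(f"alpha out of [0, 2]: {alpha:g}")
    if n_iter < 10_000 or burn_in < 1_000:
        raise ValueError("need n_iter >= 1e4 and burn_in >= 1e3 for a stable estimate")
    return float(_lyap_orbit(float(alpha), int(n_iter), int(burn_in), float(x0)))


def chaos_onset_alpha(lo: float = 1.3, hi: float = 1.5, tol: float = 1e-3,
                      n_iter: int = 1_000_000, burn_in: int = 1_000,
                      x0: float = 0.1) -> float:
    """Bisect on the sign of the Lyapunov exponent to locate chaos onset.

    For the quadratic map the boundary is the period-doubling accumulation
    point at alpha = 1.4011...
    """
    f_lo = largest_lyapunov_map(lo, n_iter, burn_in, x0)
    f_hi = largest_lyapunov_map(hi, n_iter, burn_in, x0)
    if not (f_lo <= 0.0 < f_hi):
        raise ValueError("bracket does not straddle the chaos onset")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if largest_lyapunov_map(mid, n_iter, burn_in, x0) > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Phase synchronization
# ---------------------------------------------------------------------------

def _phases(signals: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phases per channel; returns (phases, valid_mask)."""
    x = np.asarray(signals, dtype=float)
    valid = x.std(axis=1) > 1e-12
    ph = np.zeros_like(x)
    if method == "hilbert":
        xm = x - x.mean(axis=1, keepdims=True)
        ph[valid] = np.angle(hilbert(xm[valid], axis=1))
    elif method == "zero_crossing":
        for i in np.nonzero(valid)[0]:
            xi = x[i] - np.mean(x[i])
            up = np.nonzero((xi[:-1] <= 0) & (xi[1:] > 0))[0]
            if len(up) < 2:
                valid[i] = False
                continue
            t = np.arange(x.shape[1])
            cyc = np.interp(t, up, np.arange(len(up)), left=0, right=len(up) - 1)
            ph[i] = 2 * np.pi * cyc
    else:
        raise ValueError(f"unknown phase method {method!r}")
    return ph, valid

def phase_sync_matrix(signals, method: str = "hilbert") -> np.ndarray:
    """Pairwise phase-locking values (PLV) of a multichannel time series.

    ``PLV_ij = |mean_t exp(i*(phi_i - phi_j))|`` with instantaneous phases
    from the analytic signal (default) or linear interpolation between
    upward zero crossings.  Entries involving (near-)constant channels,
    whose phase is undefined, are NaN; the diagonal is 1 for valid channels.
    PLV is invariant to constant phase offsets and symmetric under channel
    relabeling.
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (n_channels >= 2, n_samples) array")
    ph, valid = _phases(x, method)
    z = np.exp(1j * ph)
    plv = np.abs(z @ z.conj().T) / x.shape[1]
    plv[~valid, :] = np.nan
    plv[:, ~valid] = np.nan
    np.fill_diagonal(plv, np.where(valid, 1.0, np.nan))
    return plv


def windowed_plv(signals, fs: float, window_s: float = 1.0, hop_s: float = 0.25,
                 method: str = "hilbert"):
    """Mean off-diagonal PLV on sliding windows.

    Returns ``(t_centers, mean_plv)``; windows where every pair is undefined
    yield NaN.
    """
    x = np.asarray(signals, dtype=float)
    win = max(8, int(round(window_s * fs)))
    hop = max(1, int(round(hop_s * fs)))
    starts = np.arange(0, x.shape[1] - win + 1, hop)
    times = (starts + win / 2) / fs
    out = np.full(len(starts), np.nan)
    iu = np.triu_indices(x.shape[0], k=1)
    for k, s0 in enumerate(starts):
        m = phase_sync_matrix(x[:, s0:s0 + win], method=method)
        vals = m[iu]
        if np.any(np.isfinite(vals)):
            out[k] = np.nanmean(vals)
    return times, out


def phase_pattern_similarity(signals, fs: float, ref_window,
                             window_s: float = 0.5, hop_s: float = 0.15,
                             method: str = "hilbert"):
    """Similarity of the instantaneous phase constellation to a reference.

    The constellation is the vector of pairwise phase differences.  The
    reference is its circular mean over ``ref_window`` (seconds); the
    returned time course is ``|mean_ij exp(i*(dphi_ij(t) - dphi_ij_ref))|``
    over sliding windows — 1 when the phase relationship matches the
    reference pattern, near 0 when it has been abandoned.
    """
    x = np.asarray(signals, dtype=float)
    ph, valid = _phases(x, method)
    if valid.sum() < 2:
        raise ValueError("need at least 2 non-constant channels")
    iu = np.triu_indices(x.shape[0], k=1)
    keep = valid[iu[0]] & valid[iu[1]]
    z = np.exp(1j * (ph[iu[0][keep]] - ph[iu[1][keep]]))
    n = x.shape[1]
    i0, i1 = (max(int(round(t * fs)), 0) for t in ref_window)
    if i1 <= i0 or i1 > n:
        raise ValueError("reference window outside the signal")
    ref = z[:, i0:i1].mean(axis=1)
    ref /= np.abs(ref) + 1e-12
    win = max(int(round(window_s * fs)), 2)
    hop = max(int(round(hop_s * fs)), 1)
    starts = np.arange(0, n - win + 1, hop)
    times = (starts + win / 2) / fs
    sim = np.empty(len(starts))
    for k, s0 in enumerate(starts):
        zw = z[:, s0:s0 + win].mean(axis=1)
        zw /= np.abs(zw) + 1e-12
        sim[k] = np.abs(np.mean(zw * np.conj(ref)))
    return times, sim


def rolling_pattern_stability(signals, fs: float, window_s: float = 0.5,
                              hop_s: float = 0.15, method: str = "hilbert"):
    """Window-to-window stability of the phase constellation.

    1 when consecutive windows share the same pairwise phase-difference
    pattern (a settled coordination), low while the pattern is reorganizing.
    """
    x = np.asarray(signals, dtype=float)
    ph, valid = _phases(x, method)
    iu = np.triu_indices(x.shape[0], k=1)
    keep = valid[iu[0]] & valid[iu[1]]
    z = np.exp(1j * (ph[iu[0][keep]] - ph[iu[1][keep]]))
    win = max(int(round(window_s * fs)), 2)
    hop = max(int(round(hop_s * fs)), 1)
    starts = np.arange(0, x.shape[1] - win + 1, hop)
    zws = []
    for s0 in starts:
        zw = z[:, s0:s0 + win].mean(axis=1)
        zws.append(zw / (np.abs(zw) + 1e-12))
    times = (starts[1:] + win / 2) / fs
    stab = np.array([np.abs(np.mean(zws[k + 1] * np.conj(zws[k])))
                     for k in range(len(zws) - 1)])
    return times, stab


def surrogate_plv_bound(signals, n_surrogates: int = 99, q: float = 0.95,
                        seed: int | None = None, method: str = "hilbert") -> float:
    """95th-percentile mean-PLV bound from circular-shift surrogates.

    Each surrogate independently rotates every channel by a random circular
    shift, destroying cross-channel phase relations while preserving each
    channel's autocorrelation.
    """
    x = np.asarray(signals, dtype=float)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(x.shape[0], k=1)
    vals = np.empty(n_surrogates)
    for k in range(n_surrogates):
        sur = np.stack([np.roll(ch, rng.integers(1, x.shape[1])) for ch in x])
        vals[k] = np.nanmean(phase_sync_matrix(sur, method=method)[iu])
    return float(np.quantile(vals, q))


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis
# ---------------------------------------------------------------------------

def dfa_exponent(series, windows=None, order: int = 1) -> float:
    """DFA scaling exponent of a 1D series (first-order detrending).

    0.5 for white noise, 1.5 for integrated white noise (a random walk);
    values above 0.5 indicate long-range positive correlation.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = len(x)
    if n < 1024:
        raise ValueError(f"series too short for DFA: {n} < 1024")
    if np.std(x) < 1e-14:
        raise ValueError("constant series: DFA undefined (degenerate)")
    if windows is None:
        windows = np.unique(np.floor(np.logspace(np.log10(8), np.log10(n // 4), 12)).astype(int))
    windows = np.asarray(windows, dtype=int)
    if len(windows) < 4:
        raise ValueError("need at least 4 window sizes")
    prof = np.cumsum(x - np.mean(x))
    flucts = np.empty(len(windows), dtype=float)
    for k, w in enumerate(windows):
        n_seg = n // w
        segs = prof[: n_seg * w].reshape(n_seg, w)
        t = np.arange(w, dtype=float)
        # least-squares polynomial detrend per segment, vectorized
        V = np.vander(t, order + 1)
        coef, *_ = np.linalg.lstsq(V, segs.T, rcond=None)
        resid = segs.T - V @ coef
        flucts[k] = np.sqrt(np.mean(resid ** 2))
    slope = np.polyfit(np.log(windows), np.log(flucts), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Behavioural event rates
# ---------------------------------------------------------------------------

def jerk_event_times(angles, fs: float, accel_threshold: float,
                     max_event_s: float = 0.5, refractory_s: float = 0.3):
    """Times of jerky-movement events in joint-angle trajectories.

    An event is an interval where the angular acceleration magnitude of any
    joint crosses ``accel_threshold`` upward and falls back below it within
    ``max_event_s`` — a burst of high acceleration-deceleration.  Crossings
    of the same joint within ``refractory_s`` belong to one burst (a single
    movement jerk produces several acceleration lobes).  Events are detected
    per joint and pooled.
    """
    if accel_threshold <= 0:
        raise ValueError("accel_threshold must be positive")
    th = np.atleast_2d(np.asarray(angles, dtype=float))
    if th.shape[0] > th.shape[1]:
        th = th.T
    acc = np.gradient(np.gradient(th, axis=1), axis=1) * fs * fs
    events = []
    max_len = int(round(max_event_s * fs))
    for a in np.abs(acc):
        above = a > accel_threshold
        d = np.diff(above.astype(int))
        ups = np.nonzero(d == 1)[0] + 1
        downs = np.nonzero(d == -1)[0] + 1
        last = -np.inf
        for u in ups:
            nxt = downs[downs > u]
            if len(nxt) and nxt[0] - u <= max_len:
                t = u / fs
                if t - last >= refractory_s:
                    events.append(t)
                last = t
    return np.sort(np.asarray(events))


def jerk_event_rate(angles, fs: float, accel_threshold: float,
                    window_s: float | None = None, max_event_s: float = 0.5):
    """Jerk events per minute; a windowed time course if ``window_s`` given."""
    th = np.atleast_2d(np.asarray(angles, dtype=float))
    if th.shape[0] > th.shape[1]:
        th = th.T
    duration = th.shape[1] / fs
    ev = jerk_event_times(angles, fs, accel_threshold, max_event_s)
    if window_s is None:
        return 60.0 * len(ev) / duration
    edges = np.arange(0.0, duration + window_s, window_s)
    counts, _ = np.histogram(ev, bins=edges)
    t_centers = 0.5 * (edges[:-1] + edges[1:])
    return t_centers, counts * (60.0 / window_s)


def contact_event_times(trajectory, region_a: str, region_b: str,
                        refractory_s: float = 0.5, min_force: float = 0.0):
    """Onset times of touch events between two skin regions.

    A contact event is the onset of any taxel-taxel pseudo-contact between a
    taxel tagged ``region_a`` and one tagged ``region_b`` in the trajectory's
    self-contact record, debounced by a refractory time.  ``min_force``
    ignores grazing touches below the given pseudo-contact force, so only
    decisive touches count.
    """
    regions = np.asarray(trajectory.taxel_regions)
    vocab = set(regions.tolist())
    for r in (region_a, region_b):
        if r not in vocab:
            raise ValueError(f"unknown region tag {r!r}; known: {sorted(vocab)}")
    in_a = regions == region_a
    in_b = regions == region_b
    times = []
    prev_touch = False
    last_event = -np.inf
    for t, pairs in zip(trajectory.times, trajectory.self_contacts):
        pairs = np.asarray(pairs)
        touching = False
        if pairs.size:
            i = pairs[:, 0].astype(int)
            j = pairs[:, 1].astype(int)
            strong = pairs[:, 2] >= min_force
            touching = bool(np.any(((in_a[i] & in_b[j]) | (in_b[i] & in_a[j]))
                                   & strong))
        if touching and not prev_touch and (t - last_event) >= refractory_s:
            times.append(t)
            last_event = t
        prev_touch = touching
    return np.asarray(times)


def contact_event_rate(trajectory, region_a: str, region_b: str,
                       window_s: float | None = None, refractory_s: float = 0.5,
                       min_force: float = 0.0):
    """Region-to-region contacts per minute (optionally a windowed course)."""
    ev = contact_event_times(trajectory, region_a, region_b, refractory_s,
                             min_force)
    duration = float(trajectory.times[-1]) if len(trajectory.times) else 0.0
    if window_s is None:
        return 60.0 * len(ev) / max(duration, 1e-9)
    edges = np.arange(0.0, duration + window_s, window_s)
    counts, _ = np.histogram(ev, bins=edges)
    t_centers = 0.5 * (edges[:-1] + edges[1:])
    return t_centers, counts * (60.0 / window_s)


# ---------------------------------------------------------------------------
# Cortical response indices
# ---------------------------------------------------------------------------

@dataclass
class SegregationScore:
    """Body-map segregation: 1 - mean pairwise overlap of response maps."""

    value: float
    overlap: np.ndarray
    parts: list
    excluded_pairs: list


def segregation_index(response_maps: dict) -> SegregationScore:
    """How body-part-wise segregated a set of cortical response maps is.

    Maps are rectified to their positive part and compared by cosine
    similarity; the score is 1 minus the mean off-diagonal overlap, so
    orthogonal (perfectly segregated) maps score 1 and identical maps 0.
    All-zero maps are excluded pair-wise and reported.  Invariant to
    positive rescaling of any map.
    """
    parts = list(response_maps)
    if len(parts) < 2:
        raise ValueError("need at least 2 body-part response maps")
    vecs = [np.clip(np.asarray(response_maps[p], dtype=float).ravel(), 0.0, None)
            for p in parts]
    lens = {len(v) for v in vecs}
    if len(lens) != 1:
        raise ValueError("response maps must have equal length")
    norms = [np.linalg.norm(v) for v in vecs]
    n = len(parts)
    overlap = np.full((n, n), np.nan)
    np.fill_diagonal(overlap, 1.0)
    excluded, offdiag = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] < 1e-12 or norms[j] < 1e-12:
                excluded.append((parts[i], parts[j]))
                continue
            c = float(vecs[i] @ vecs[j] / (norms[i] * norms[j]))
            overlap[i, j] = overlap[j, i] = c
            offdiag.append(c)
    if not offdiag:
        raise ValueError("all response-map pairs degenerate (zero maps)")
    return SegregationScore(value=float(1.0 - np.mean(offdiag)), overlap=overlap,
                            parts=parts, excluded_pairs=excluded)


def multimodal_index(combined, unimodal: list) -> float:
    """Superadditivity of a combined-stimulus response.

    ``||r_combined|| / sum_k ||r_k||`` over the rectified response vectors;
    values above the additive baseline indicate multimodal integration.
    """
    c = np.clip(np.asarray(combined, dtype=float).ravel(), 0.0, None)
    denom = 0.0
    for u in unimodal:
        denom += float(np.linalg.norm(np.clip(np.asarray(u, dtype=float).ravel(), 0.0, None)))
    if denom < 1e-12:
        raise ValueError("all unimodal responses are zero; index undefined")
    return float(np.linalg.norm(c) / denom)


def onset_time(times, rates, baseline_window, k: float = 2.0, m: int = 3,
               floor: float = 0.0):
    """First time a windowed rate shows a sustained increase over baseline.

    Onset = first time the rate exceeds (baseline mean + max(k * baseline
    SD, floor)) for ``m`` consecutive samples; returns None when that never
    happens.  ``floor`` guards against a degenerate all-zero baseline, where
    any single event would otherwise count as an onset.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(rates, dtype=float)
    b0, b1 = baseline_window
    base = r[(t >= b0) & (t <= b1)]
    if len(base) < 2:
        raise ValueError("baseline window contains fewer than 2 samples")
    thr = base.mean() + max(k * max(base.std(ddof=1), 1e-12), floor)
    above = r > thr
    run = 0
    for i in range(len(r)):
        run = run + 1 if above[i] else 0
        if run >= m and t[i] > b1:
            return float(t[i - m + 1])
    return None
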