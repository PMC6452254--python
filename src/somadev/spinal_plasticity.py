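"""Hebbian learning of full tactile-to-motor spinal connections.

A coarse generic model of spinal learning: every cutaneous taxel projects to
every alpha motor neuron (adding directly to muscle activation) and to every
muscle's oscillator (adding to its drive).  Weights follow an Oja-style
normalized Hebbian rule, which keeps them bounded without hard saturation
dynamics, and are additionally clipped to [0, w_max].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpinalWeights", "hebbian_update", "spinal_drive",
           "RunningPercentileNormalizer"]


@dataclass
class SpinalWeights:
    """Tactile->motor connection matrices (taxels x muscles), in [0, w_max]."""

    W_alpha: np.ndarray
    W_osc: np.ndarray
    gain: float = 1.0
    w_max: float = 1.0

    @classmethod
    def zeros(cls, n_taxels: int, n_muscles: int, gain: float = 1.0,
              w_max: float = 1.0, init_sd: float = 0.0, seed: int | None = None):
        rng = np.random.default_rng(seed)
        wa = np.clip(init_sd * np.abs(rng.standard_normal((n_taxels, n_muscles))), 0, w_max)
        wo = np.clip(init_sd * np.abs(rng.standard_normal((n_taxels, n_muscles))), 0, w_max)
        return cls(W_alpha=wa, W_osc=wo, gain=gain, w_max=w_max)

    def __post_init__(self):
        if self.W_alpha.shape != self.W_osc.shape:
            raise ValueError("W_alpha and W_osc must have identical shapes")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")


def hebbian_update(weights: SpinalWeights, tactile, activations,
                   lr: float) -> SpinalWeights:
    """One Oja-style Hebbian step on both connection matrices (in place).

    ``dW_ij = lr * (pre_i * post_j - post_j**2 * W_ij)``: plain Hebbian
    coincidence growth with a multiplicative decay that bounds each column's
    norm at the Oja fixed point; entries are then clipped to [0, w_max].
    With all-zero tactile input the weights can only shrink or stay.
    """
    if lr <= 0:
        raise ValueError("lr must be positive")
    pre = np.asarray(tactile, dtype=float).ravel()
    post = np.asarray(activations, dtype=float).ravel()
    if pre.shape[0] != weights.W_alpha.shape[0] or post.shape[0] != weights.W_alpha.shape[1]:
        raise ValueError(
            f"shape mismatch: tactile {pre.shape}, activations {post.shape}, "
            f"weights {weights.W_alpha.shape}")
    outer = np.outer(pre, post)
    decay = post ** 2
    for W in (weights.W_alpha, weights.W_osc):
        W += lr * (outer - decay[None, :] * W)
        np.clip(W, 0.0, weights.w_max, out=W)
    return weights


def spinal_drive(weights: SpinalWeights, tactile) -> np.ndarray:
    """Learned per-muscle activation added by the tactile feedback loop.

    ``tanh(gain * tactile @ W_alpha)`` — the pre-squash drive is exactly
    linear in ``gain`` (tripling the gain triples it), and the squash keeps
    the contribution in [0, 1) for nonnegative inputs.
    """
    pre = np.asarray(tactile, dtype=float).ravel()
    if pre.shape[0] != weights.W_alpha.shape[0]:
        raise ValueError("tactile length does not match weight rows")
    return np.tanh(weights.gain * (pre @ weights.W_alpha))


class RunningPercentileNormalizer:
    """Scale-free tactile normalization by a running 95th-percentile force.

    Keeps an exponentially updated estimate of the 95th percentile of the
    pooled nonzero tactile forces and divides by it, clipping to [0, 1].
    """

    def __init__(self, q: float = 0.95, eta: float = 0.02, floor: float = 1e-6):
        self.q = q
        self.eta = eta
        self.floor = floor
        self.scale = None

    def update(self, tactile) -> np.ndarray:
        x = np.asarray(tactile, dtype=float).ravel()
        nz = x[x > 0]
        if nz.size:
            p = float(np.quantile(nz, self.q))
            self.scale = p if self.scale is None else \
                (1 - self.eta) * self.scale + self.eta * p
        s = self.scale if self.scale else self.floor
        return np.clip(x / max(s, self.floor), 0.0, 1.0)
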