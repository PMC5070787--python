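"""Gaussian spike-pairing ITDP on the ensemble-to-final connections.

Input-timing-dependent plasticity is heterosynaptic: the weight of a
proximal synapse (ensemble neuron k -> final neuron f) changes when spikes
on the proximal pathway pair in time with spikes on the distal pathway
(gating neuron f, whose topographic projection enables plasticity but
contributes nothing to the final neuron's membrane potential).  Each
(distal, proximal) spike pair contributes a Gaussian potentiation factor
g(dt) = exp(-dt^2 / 2 sigma^2); the biological -20 ms pairing peak is
absorbed into an assumed conduction delay so the curve peaks at dt = 0.

The update fires whenever either presynaptic pathway spikes:

    dw_fk = h_fk(t) c e^{-w_fk} - 1

with h_fk the pairing sum over pairs involving the triggering spike (so no
pair is double-counted), applied through the synapse's variance-tracking
learning rate.  With perfect coincidence (h = 1 per trigger) the weight
converges to log(c) — the same fixed point as the logical pulse rule's
co-firing branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sem import PlasticityState, variance_tracking_step

__all__ = ["ITDPParams", "ITDPLayer", "itdp_gauss", "pairing_sum"]


@dataclass
class ITDPParams:
    """sigma2: variance (s^2) of the Gaussian timing curve (default 1.5e-4,
    i.e. sd ~12 ms); c: weight-bound constant shared with the SEM circuits;
    pairing_window: how far back each pathway's spike buffer reaches.  The
    default window of 5 sigma keeps every pair with a contribution above
    e^{-12.5}."""

    sigma2: float = 1.5e-4
    c: float = float(np.exp(5.0))
    pairing_window: float | None = None
    mu: float = 0.01

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.pairing_window is None:
            self.pairing_window = 5.0 * float(np.sqrt(self.sigma2))


def itdp_gauss(delta_t, sigma2: float):
    """Symmetric Gaussian potentiation factor e^{-dt^2 / (2 sigma^2)},
    peaking at 1 for coincident spikes."""
    delta_t = np.asarray(delta_t, dtype=float)
    out = np.exp(-(delta_t**2) / (2.0 * sigma2))
    return float(out) if out.ndim == 0 else out


def pairing_sum(
    proximal_spikes, distal_spikes, params: ITDPParams
) -> float:
    """Sum of Gaussian factors over all (distal, proximal) spike pairs."""
    prox = np.asarray(proximal_spikes, dtype=float)
    dist = np.asarray(distal_spikes, dtype=float)
    if prox.size == 0 or dist.size == 0:
        return 0.0
    return float(itdp_gauss(dist[:, None] - prox[None, :], params.sigma2).sum())


class ITDPLayer:
    """All ITDP synapses from ``n_pre`` ensemble-layer neurons onto the
    ``n_final`` final-WTA neurons, with bounded per-neuron spike buffers.

    The distal pathway is topographic: gating neuron f pairs with final
    neuron f.  Incremental bookkeeping: at each trigger only the pairs
    involving the triggering spike enter h, so every (distal, proximal)
    pair contributes exactly once over a run.
    """

    def __init__(
        self,
        n_final: int,
        n_pre: int,
        params: ITDPParams,
        rng: np.random.Generator,
        plastic: bool = True,
    ) -> None:
        self.params = params
        self.n_final = n_final
        self.n_pre = n_pre
        self.weights = rng.uniform(-1.0, 0.0, size=(n_final, n_pre))
        self.state = PlasticityState.for_weights(self.weights, params.mu)
        self._prox: list[list[float]] = [[] for _ in range(n_pre)]
        self._dist: list[list[float]] = [[] for _ in range(n_final)]
        self.plastic = plastic

    def _trim(self, buf: list[float], t: float) -> None:
        horizon = t - self.params.pairing_window
        while buf and buf[0] < horizon:
            buf.pop(0)

    def _apply(self, f_idx, k_idx, h: np.ndarray) -> None:
        """Vectorised weight + learning-rate update on the selected entries."""
        w = self.weights[f_idx, k_idx]
        delta = h * self.params.c * np.exp(-w) - 1.0
        new_w = w + self.state.eta[f_idx, k_idx] * delta
        self.weights[f_idx, k_idx] = new_w
        mask = np.zeros_like(self.weights, dtype=bool)
        mask[f_idx, k_idx] = True
        variance_tracking_step(self.state, new_w.ravel(), self.params.mu, mask)

    def step(self, t: float, proximal_ids, distal_ids) -> None:
        """Process one timestep's spikes on both pathways.

        All spikes of the step are buffered first, then each triggering
        spike is paired against the full opposite-pathway buffer.  A
        same-step (coincident) pair is therefore visible to both of its
        triggers — persistent perfect coincidence gives h = 1 at every
        trigger and the log(c) fixed point — while a pair spanning two
        steps enters h exactly once, at its later spike's trigger.
        A trigger with an empty opposite buffer takes the depression
        branch (h = 0).
        """
        proximal_ids = list(proximal_ids)
        distal_ids = list(distal_ids)
        for k in proximal_ids:
            self._trim(self._prox[k], t)
            self._prox[k].append(t)
        for f in distal_ids:
            self._trim(self._dist[f], t)
            self._dist[f].append(t)
        if not self.plastic or not (proximal_ids or distal_ids):
            return
        for k in proximal_ids:
            h = np.empty(self.n_final)
            for f in range(self.n_final):
                self._trim(self._dist[f], t)
                h[f] = pairing_sum([t], self._dist[f], self.params)
            self._apply(np.arange(self.n_final), np.full(self.n_final, k), h)
        for f in distal_ids:
            h = np.empty(self.n_pre)
            for k in range(self.n_pre):
                self._trim(self._prox[k], t)
                h[k] = pairing_sum(self._prox[k], [t], self.params)
            self._apply(np.full(self.n_pre, f), np.arange(self.n_pre), h)

    # single-event conveniences (tests, interactive use)
    def on_proximal_spike(self, k: int, t: float) -> None:
        self.step(t, [k], [])

    def on_distal_spike(self, f: int, t: float) -> None:
        self.step(t, [], [f])

    def reset_buffers(self) -> None:
        self._prox = [[] for _ in range(self.n_pre)]
        self._dist = [[] for _ in range(self.n_final)]

    def to_frame(self):
        """Long-format (f, k, w) weight table."""
        import pandas as pd

        f, k = np.indices(self.weights.shape)
        return pd.DataFrame(
            {"f": f.ravel(), "k": k.ravel(), "w": self.weights.ravel()}
        )
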