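"""Spiking expectation-maximization (SEM) winner-take-all microcircuit.

A WTA circuit holds K output neurons firing as inhomogeneous Poisson
processes with rate r_k(t) = exp(u_k(t)), where the membrane potential

    u_k(t) = w_k0 + sum_i w_ki y_i(t) + I(t) + v(t)

sums weighted double-exponential EPSPs y_i from the input layer, a shared
global inhibition term I(t) and an optional Ornstein-Uhlenbeck perturbation
v(t) emulating background activity.  I(t) jumps to -A_inh whenever any
neuron of the circuit fires and relaxes back to the resting offset O_inh
with time constant tau_inh: the pulse enforces refractoriness and soft
competition, while the resting offset acts as the firing threshold, sized
to the typical weighted-evidence sum of the circuit's afferents.

STDP on the input weights (potentiation proportional to the presynaptic EPSP
at the moment of the postsynaptic spike, inversely exponential in the current
weight, constant depression) together with spike-triggered excitability
plasticity implements stochastic online expectation maximization: a circuit
spike is a sample from the posterior over K hidden causes, the excitabilities
converge to the log prior (sum_k e^{w_k0} = 1) and the weights to
log-likelihood ratios.  Every learnable variable carries its own
variance-tracking adaptive learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, log

import numpy as np

__all__ = [
    "SEMParams",
    "PlasticityState",
    "WTACircuit",
    "epsp_kernel",
    "epsp_value",
    "epsp_peak_time",
    "inhibition",
    "stdp_delta",
    "variance_tracking_step",
    "ou_step",
]

_U_CLAMP = 500.0  # cap on membrane potential before exponentiation


@dataclass
class SEMParams:
    """Common circuit parameters.

    Inhibition: pulse amplitude A_inh = 3000, resting offset O_inh = -550,
    decay tau_inh = 5 ms.  EPSP kernel: slow decay tau_s = 15 ms, fast rise
    tau_f = 1 ms, scale A_EPSP fixed so a single-spike EPSP peaks at 1.
    c = e^5 bounds the learned weights; mu = 0.01 is the global
    variance-tracking constant.  dt is the simulation step (s); firing
    probability per step is 1 - exp(-r dt) capped at p_cap to preserve
    Poisson semantics at high rates.
    """

    A_inh: float = 3000.0
    O_inh: float = -550.0
    tau_inh: float = 0.005
    tau_s: float = 0.015
    tau_f: float = 0.001
    c: float = float(np.exp(5.0))
    mu: float = 0.01
    dt: float = 0.001
    p_cap: float = 0.95
    # Ornstein-Uhlenbeck background noise: mean-reversion time (s) and
    # stationary standard deviation (membrane-potential units); amplitude 0
    # switches the perturbation off.
    ou_tau: float = 0.020
    ou_sigma: float = 0.5
    ou_enabled: bool = True

    def __post_init__(self) -> None:
        if not (self.tau_s > self.tau_f > 0):
            raise ValueError("require tau_s > tau_f > 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def A_EPSP(self) -> float:
        """Kernel scale making the single-spike EPSP peak equal 1."""
        ts, tf = self.tau_s, self.tau_f
        return (ts / (ts - tf)) * (ts / tf) ** (tf / (ts - tf))


def epsp_kernel(t: np.ndarray | float, params: SEMParams) -> np.ndarray | float:
    """Double-exponential EPSP of a single spike at time 0, evaluated at t>=0."""
    t = np.asarray(t, dtype=float)
    out = params.A_EPSP * (np.exp(-t / params.tau_s) - np.exp(-t / params.tau_f))
    out = np.where(t < 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def epsp_value(spike_times, t: float, params: SEMParams) -> float:
    """Summed EPSP at time t from a list of past spike times."""
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        return 0.0
    if np.any(spike_times > t):
        raise ValueError("spike times must not exceed the evaluation time")
    return float(np.sum(epsp_kernel(t - spike_times, params)))


def epsp_peak_time(params: SEMParams) -> float:
    """Closed-form argmax of the single-spike EPSP:
    t* = tau_s tau_f ln(tau_s/tau_f) / (tau_s - tau_f)."""
    ts, tf = params.tau_s, params.tau_f
    return ts * tf * log(ts / tf) / (ts - tf)


def inhibition(t: float, t_f: float, params: SEMParams) -> float:
    """Global inhibition I(t) = O_inh - (A_inh + O_inh) e^{(t_f - t)/tau_inh}
    after the most recent circuit spike at t_f; before any spike, the resting
    offset O_inh."""
    if not np.isfinite(t_f):
        return params.O_inh
    if t < t_f:
        raise ValueError("t must not precede the last circuit spike")
    return params.O_inh - (params.A_inh + params.O_inh) * exp(
        (t_f - t) / params.tau_inh
    )


@dataclass
class PlasticityState:
    """Per-variable running moments and adaptive learning rate.

    eta_new = mu (m2 - m1^2) / (1 + e^{-m1}), then the moments relax toward
    the current value and its square at rate eta.  Initialised with m1 = w0,
    m2 = w0^2 + 1 (unit initial variance) and eta = mu so learning starts
    at the global rate and anneals as the variable settles.
    """

    m1: np.ndarray
    m2: np.ndarray
    eta: np.ndarray

    @classmethod
    def for_weights(cls, w: np.ndarray, mu: float) -> "PlasticityState":
        w = np.asarray(w, dtype=float)
        return cls(m1=w.copy(), m2=w**2 + 1.0, eta=np.full_like(w, mu))


def variance_tracking_step(
    state: PlasticityState, new_w: np.ndarray, mu: float, mask=None
) -> None:
    """Update learning rate and moments in place for the (optionally masked)
    entries whose variable was just updated to ``new_w``.

    The running variance m2 - m1^2 can go slightly negative numerically; it
    is floored at 0 so eta stays non-negative.
    """
    if mask is None:
        m1, m2 = state.m1, state.m2
        var = np.maximum(m2 - m1**2, 0.0)
        eta = mu * var / (1.0 + np.exp(-m1))
        state.eta = eta
        state.m1 = m1 + eta * (new_w - m1)
        state.m2 = m2 + eta * (new_w**2 - m2)
    else:
        m1, m2 = state.m1[mask], state.m2[mask]
        var = np.maximum(m2 - m1**2, 0.0)
        eta = mu * var / (1.0 + np.exp(-m1))
        state.eta[mask] = eta
        state.m1[mask] = m1 + eta * (new_w - m1)
        state.m2[mask] = m2 + eta * (new_w**2 - m2)


def stdp_delta(w: np.ndarray, y: np.ndarray, c: float) -> np.ndarray:
    """STDP increment at a postsynaptic spike: y_i c e^{-w} - 1 (depression -1
    when the presynaptic EPSP is silent).  Fixed point: w* = log(c y)."""
    return np.asarray(y) * c * np.exp(-np.asarray(w)) - 1.0


def ou_step(v: float, dt: float, params: SEMParams, rng: np.random.Generator) -> float:
    """Exact one-step update of the Ornstein-Uhlenbeck perturbation with
    stationary mean 0 and stationary variance ou_sigma^2."""
    if not params.ou_enabled or params.ou_sigma == 0.0:
        return 0.0
    rho = exp(-dt / params.ou_tau)
    return rho * v + params.ou_sigma * np.sqrt(1.0 - rho * rho) * rng.standard_normal()


class WTACircuit:
    """One soft winner-take-all microcircuit with K output neurons.

    weights : (K, n_inputs) log-domain STDP weights on the afferents.
    excitability : (K,) per-neuron bias w_k0 (log prior over hidden causes).
    input_idx : indices of this circuit's afferents within the global input
        layer (feature selection), or None for a private input vector.
    """

    def __init__(
        self,
        n_neurons: int,
        n_inputs: int,
        params: SEMParams,
        rng: np.random.Generator,
        input_idx: np.ndarray | None = None,
        A_inh: float | None = None,
        O_inh: float | None = None,
        plastic: bool = True,
    ) -> None:
        if n_neurons < 2:
            raise ValueError("a WTA circuit needs at least two neurons")
        self.K = n_neurons
        self.params = params
        self.input_idx = None if input_idx is None else np.asarray(input_idx)
        # start near the potentiated bound log(c) so circuits fire from the
        # outset (STDP is post-spike triggered; a silent circuit never
        # learns) and depression carves the class structure downward
        self.weights = rng.uniform(4.5, 5.0, size=(n_neurons, n_inputs))
        self.excitability = rng.uniform(
            -log(n_neurons) - 0.5, -log(n_neurons) + 0.5, size=n_neurons
        )
        self.w_state = PlasticityState.for_weights(self.weights, params.mu)
        self.exc_state = PlasticityState.for_weights(self.excitability, params.mu)
        self.t_f = -np.inf  # last circuit spike
        self.v = 0.0  # OU noise state
        self.A_inh = params.A_inh if A_inh is None else A_inh
        self.O_inh = params.O_inh if O_inh is None else O_inh
        self.plastic = plastic
        self.overflow_count = 0

    # -- dynamics ----------------------------------------------------------
    def inhibition_at(self, t: float) -> float:
        if not np.isfinite(self.t_f):
            return self.O_inh
        return self.O_inh - (self.A_inh + self.O_inh) * exp(
            min((self.t_f - t) / self.params.tau_inh, 0.0)
        )

    def membrane(self, y: np.ndarray, t: float) -> np.ndarray:
        """u_k(t) for this circuit's (already feature-selected) input EPSPs.

        The inhibition term is additive: -A_inh right after a circuit spike,
        relaxing to the resting offset O_inh (a negative threshold).
        """
        return (
            self.excitability
            + self.weights @ y
            + self.inhibition_at(t)
            + self.v
        )

    def posterior(self, u: np.ndarray) -> np.ndarray:
        """Softmax posterior q_k over the source of an observed circuit spike."""
        u = u - u.max()
        e = np.exp(u)
        return e / e.sum()

    def step_fire(
        self, y: np.ndarray, t: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Advance noise, evaluate membranes and draw at most one spike.

        The circuit as a whole is an inhomogeneous Poisson process with rate
        R(t) = sum_k e^{u_k}: it emits a spike within dt with probability
        1 - exp(-R dt), capped at p_cap, and the spike originates from
        neuron k with the softmax posterior q_k = e^{u_k} / R.  Updates t_f
        when the circuit fires.  Returns a boolean spike vector.
        """
        p = self.params
        self.v = ou_step(self.v, p.dt, p, rng)
        u = self.membrane(y, t)
        over = u > _U_CLAMP
        if np.any(over):
            self.overflow_count += int(np.sum(over))
            u = np.minimum(u, _U_CLAMP)
        u_max = u.max()
        q = np.exp(u - u_max)
        total = q.sum()
        log_rate = u_max + np.log(total)
        if log_rate > 30.0:  # e^30 dt >> 1: certain up to the cap
            prob = p.p_cap
        else:
            prob = min(1.0 - np.exp(-np.exp(log_rate) * p.dt), p.p_cap)
        fired = np.zeros(self.K, dtype=bool)
        if rng.random() < prob:
            k = rng.choice(self.K, p=q / total)
            fired[k] = True
            self.t_f = t
        return fired

    # -- plasticity (all trigger-gated) ------------------------------------
    def stdp_update(self, fired: np.ndarray, y: np.ndarray) -> None:
        """Apply STDP on the afferents of every neuron that just fired, using
        that synapse's own adaptive learning rate."""
        if not self.plastic or not np.any(fired):
            return
        rows = np.flatnonzero(fired)
        delta = stdp_delta(self.weights[rows], y[None, :], self.params.c)
        self.weights[rows] += self.w_state.eta[rows] * delta
        mask = np.zeros_like(self.weights, dtype=bool)
        mask[rows] = True
        variance_tracking_step(
            self.w_state, self.weights[rows].ravel(), self.params.mu, mask
        )

    def excitability_update(self, fired: np.ndarray) -> None:
        """Circuit-spike-triggered excitability plasticity: if any neuron
        fired, every neuron k receives z_k e^{-w_k0} - 1 with z_k = 1 only
        for the neurons that fired."""
        if not self.plastic or not np.any(fired):
            return
        z = fired.astype(float)
        delta = z * np.exp(-self.excitability) - 1.0
        self.excitability += self.exc_state.eta * delta
        variance_tracking_step(self.exc_state, self.excitability, self.params.mu)

    # -- checkpointing ------------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "weights": self.weights.copy(),
            "excitability": self.excitability.copy(),
            "t_f": self.t_f,
            "v": self.v,
        }

    def save(self, path) -> None:
        np.savez_compressed(path, **self.state_dict())

    def restore(self, path) -> None:
        data = np.load(path)
        self.weights = data["weights"]
        self.excitability = data["excitability"]
        self.t_f = float(data["t_f"])
        self.v = float(data["v"])
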