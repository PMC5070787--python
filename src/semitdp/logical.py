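"""Discrete-time logical voter ensemble with pulse ITDP.

An ensemble of pre-trained stochastic classifiers ("voters") is combined by a
final voter whose afferent weights are learned by a pulse form of
input-timing-dependent plasticity (ITDP): a weight from ensemble neuron
``m_i^j`` to final neuron ``f_k`` is potentiated when ``m_i^j`` co-fires with
the gating neuron ``g_k`` in the same clock tick, depressed by a constant when
exactly one of them fires, and untouched otherwise.  Potentiation is
inversely exponential in the current weight, which bounds growth and makes the
equilibrium solvable in closed form.

This module provides both the stochastic simulation (learning and measuring
phases) and the closed-form solutions it converges to: the scalar equilibrium
weight, the full ensemble equilibrium weight tensor, and the expected
final-voter firing probabilities obtained by enumerating ensemble firing
states.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VoterTable",
    "LogicalParams",
    "EnsembleWeights",
    "state_index_table",
    "joint_event_probs",
    "logical_itdp_delta",
    "equilibrium_weight",
    "ensemble_equilibrium_weights",
    "state_probability",
    "expected_final_probability",
    "run_learning_phase",
    "run_measuring_phase",
]

#: weight assigned to synapses whose equilibrium diverges to -inf
#: (zero long-run co-firing mass); keeps downstream softmax well defined.
WEIGHT_FLOOR = -50.0

#: hard cap on the number of enumerable ensemble states N_S = N_C**N_E.
DEFAULT_STATE_CAP = 10**6


class IntractableEnumerationError(ValueError):
    """Raised when N_C**N_E exceeds the state-enumeration cap."""


@dataclass
class VoterTable:
    """Per-sample firing probabilities of one voter's output neurons.

    Rows index samples (M), columns index the voter's N_C output neurons.
    Every row is a probability vector: the voter fires exactly one neuron per
    tick, drawn from its row for the currently presented sample.
    """

    probs: np.ndarray
    labels: np.ndarray | None = None  # class id per sample, used for scheduling

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be a 2-D (samples x neurons) matrix")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("firing probabilities must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("every row of a voter table must sum to 1")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.probs.shape[0],):
                raise ValueError("labels must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.probs.shape[1]

    # -- round-trip through plain text -------------------------------------
    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        """Write as CSV with a header row of neuron indices (labels column
        first when present)."""
        import pandas as pd

        df = pd.DataFrame(self.probs, columns=[str(i) for i in range(self.n_neurons)])
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase) -> "VoterTable":
        import pandas as pd

        df = pd.read_csv(path)
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy(dtype=int)
        return cls(df.to_numpy(dtype=float), labels=labels)


@dataclass
class LogicalParams:
    """Parameters of the logical model.

    a : dimensionless shift constant of the potentiation branch; the weight
        equilibrium is log(a) plus a log-probability ratio, so a >= 1 keeps
        fully co-firing synapses at a positive weight (default e^5).
    eta : learning rate applied to each ITDP increment (default 1e-3).
    """

    a: float = float(np.exp(5.0))
    eta: float = 1e-3

    def __post_init__(self) -> None:
        if self.a < 1:
            raise ValueError("shift constant a must be >= 1")
        if self.eta <= 0:
            raise ValueError("learning rate eta must be positive")


@dataclass
class EnsembleWeights:
    """Log-domain weights w[k, i, j] from neuron i of voter j to final neuron k."""

    w: np.ndarray
    divergent: np.ndarray | None = None  # bool mask of depressed-to-floor entries

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 3:
            raise ValueError("weights must have shape (N_C, N_C, N_E)")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite (floor divergent entries)")

    @property
    def n_classes(self) -> int:
        return self.w.shape[0]

    @property
    def ensemble_size(self) -> int:
        return self.w.shape[2]

    def to_frame(self):
        """Long-format (k, i, j, w) table."""
        import pandas as pd

        k, i, j = np.indices(self.w.shape)
        return pd.DataFrame(
            {"k": k.ravel(), "i": i.ravel(), "j": j.ravel(), "w": self.w.ravel()}
        )


def state_index_table(n_classes: int, ensemble_size: int) -> np.ndarray:
    """R[q, j]: index of the neuron of voter j that fires in ensemble state q.

    State q (0-based) is read as an N_E-digit base-N_C number whose j-th digit
    is the firing neuron of voter j.  Shape (N_C**N_E, N_E).
    """
    n_states = n_classes**ensemble_size
    q = np.arange(n_states)
    digits = np.empty((n_states, ensemble_size), dtype=int)
    for j in range(ensemble_size):
        digits[:, j] = (q // n_classes**j) % n_classes
    return digits


def joint_event_probs(p_m: float, p_g: float) -> tuple[float, float, float]:
    """Probabilities of the three joint firing events of two independent
    Bernoulli neurons: (both fire, exactly one fires, neither fires)."""
    p_m = float(p_m)
    p_g = float(p_g)
    if not (0.0 <= p_m <= 1.0 and 0.0 <= p_g <= 1.0):
        raise ValueError("firing probabilities must lie in [0, 1]")
    p_both = p_m * p_g
    p_one = p_m + p_g - 2.0 * p_both
    p_neither = 1.0 - p_m - p_g + p_both
    return p_both, p_one, p_neither


def logical_itdp_delta(w, fired_m, fired_g, a: float):
    """Pulse-ITDP weight change: a*e^{-w} - 1 on co-firing, -1 when exactly
    one presynaptic pathway fires, 0 otherwise.  Vectorised over w/fired_*."""
    if np.any(np.asarray(a) < 1):
        raise ValueError("shift constant a must be >= 1")
    w = np.asarray(w, dtype=float)
    fired_m = np.asarray(fired_m, dtype=bool)
    fired_g = np.asarray(fired_g, dtype=bool)
    both = fired_m & fired_g
    one = fired_m ^ fired_g
    delta = np.where(both, a * np.exp(-w) - 1.0, np.where(one, -1.0, 0.0))
    if delta.ndim == 0:
        return float(delta)
    return delta


def equilibrium_weight(p_m: float, p_g: float, a: float) -> float:
    """Closed-form equilibrium of the pulse-ITDP weight for constant
    presynaptic firing probabilities:

        w* = log(a) + log[ p_m p_g / (p_m + p_g - p_m p_g) ]

    For p_m*p_g == 0 the equilibrium diverges to -inf (pure depression); the
    configurable floor ``WEIGHT_FLOOR`` is returned instead.
    """
    p_both, p_one, _ = joint_event_probs(p_m, p_g)
    if p_both == 0.0:
        return WEIGHT_FLOOR
    return float(np.log(a) + np.log(p_both / (p_both + p_one)))


def ensemble_equilibrium_weights(
    voters: list[VoterTable],
    gate: VoterTable,
    a: float,
    weight_floor: float = WEIGHT_FLOOR,
) -> EnsembleWeights:
    """Equilibrium ITDP weight tensor for the full ensemble.

    w[k, i, j] = log(a) - log( S_sum / S_prod - 1 ) with
    S_sum  = sum_l [ p(m_i^j|x_l) + p(g_k|x_l) ],
    S_prod = sum_l [ p(m_i^j|x_l) * p(g_k|x_l) ];
    the uniform sample probability 1/M cancels.  Entries with zero pooled
    co-firing mass are depressed without bound and are clipped to
    ``weight_floor`` (flagged in ``divergent``).
    """
    m = gate.n_samples
    n_c = gate.n_neurons
    if any(v.n_samples != m for v in voters):
        raise ValueError("all voter tables must share the number of samples")
    n_e = len(voters)
    p_m = np.stack([v.probs for v in voters], axis=-1)  # (M, N_C, N_E)
    p_g = gate.probs  # (M, N_C)
    s_prod = np.einsum("lk,lij->kij", p_g, p_m)  # sum_l p_m p_g
    s_sum = p_m.sum(axis=0)[None, :, :] + p_g.sum(axis=0)[:, None, None]
    divergent = s_prod <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.log(a) - np.log(s_sum / np.where(divergent, 1.0, s_prod) - 1.0)
    w = np.where(divergent, weight_floor, w)
    # near-divergent entries can still underflow past the floor
    w = np.maximum(w, weight_floor)
    assert w.shape == (n_c, n_c, n_e)
    return EnsembleWeights(w, divergent=divergent)


def state_probability(
    sample_idx: int, voters: list[VoterTable], r_table: np.ndarray | None = None
) -> np.ndarray:
    """p(s_q | x_l) for every ensemble state q: the product over voters of the
    probability that voter j fires its state-q neuron.  Sums to 1 over q."""
    n_c = voters[0].n_neurons
    n_e = len(voters)
    if r_table is None:
        r_table = state_index_table(n_c, n_e)
    p = np.ones(r_table.shape[0])
    for j, v in enumerate(voters):
        p = p * v.probs[sample_idx, r_table[:, j]]
    return p


def _softmax(u: np.ndarray, axis: int = -1) -> np.ndarray:
    u = u - u.max(axis=axis, keepdims=True)
    e = np.exp(u)
    return e / e.sum(axis=axis, keepdims=True)


def _state_potentials(weights: EnsembleWeights, r_table: np.ndarray) -> np.ndarray:
    """u[q, k] = sum_j w[k, R(q,j), j]."""
    n_e = r_table.shape[1]
    # w[k, R(q,j), j] -> (N_S, N_E, N_C) then sum over voters
    per_voter = weights.w[:, r_table.T, np.arange(n_e)[:, None]]  # (N_C, N_E, N_S)
    return per_voter.sum(axis=1).T


def expected_final_probability(
    class_c: int,
    voters: list[VoterTable],
    gate_weights: EnsembleWeights,
    labels: np.ndarray,
    state_cap: int = DEFAULT_STATE_CAP,
) -> np.ndarray:
    """Expected firing probability of each final neuron under presentation of
    class ``class_c``, by exact enumeration of all N_C**N_E ensemble states:

        E[p(f_k | c)] = (1/M_c) sum_{l in c} sum_q p(s_q|x_l) softmax_k u_k(q)

    with u_k(q) the weighted instantaneous spike sum in state q.
    """
    n_c = voters[0].n_neurons
    n_e = len(voters)
    n_states = n_c**n_e
    if n_states > state_cap:
        raise IntractableEnumerationError(
            f"N_C**N_E = {n_states} exceeds the enumeration cap {state_cap}; "
            "reduce the ensemble size or estimate by simulation"
        )
    labels = np.asarray(labels)
    sample_ids = np.flatnonzero(labels == class_c)
    if sample_ids.size == 0:
        raise ValueError(f"no samples with class {class_c}")
    r_table = state_index_table(n_c, n_e)
    soft = _softmax(_state_potentials(gate_weights, r_table), axis=1)  # (N_S, N_C)
    out = np.zeros(n_c)
    for l in sample_ids:
        p_state = state_probability(l, voters, r_table)
        out += p_state @ soft
    return out / sample_ids.size


def _presentation_order(t: int, labels: np.ndarray, n_classes: int) -> int:
    """Sample presented at 1-based step t: classes round-robin, samples within
    a class cycling in order."""
    c = (t - 1) % n_classes
    members = np.flatnonzero(labels == c)
    n = ((t - 1) // n_classes) % members.size
    return int(members[n])


def run_learning_phase(
    voters: list[VoterTable],
    gate: VoterTable,
    params: LogicalParams,
    steps: int,
    rng_seed: int | np.random.Generator = 0,
    w_init: np.ndarray | None = None,
    record_every: int = 0,
) -> tuple[EnsembleWeights, np.ndarray | None]:
    """Stochastic simulation of ITDP learning.

    Per step: present the scheduled sample; every voter and the gate fire one
    neuron drawn from their row probabilities; every weight w[k,i,j] receives
    eta * logical_itdp_delta based on the co-firing of m_i^j and g_k.

    Weights start at log(a)/2 unless ``w_init`` is given.  If ``record_every``
    > 0, returns a trajectory array of shape (n_snapshots, N_C, N_C, N_E).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n_c = gate.n_neurons
    n_e = len(voters)
    labels = gate.labels
    if labels is None:
        raise ValueError("gate table must carry sample labels for scheduling")
    w = (
        np.full((n_c, n_c, n_e), np.log(params.a) / 2.0)
        if w_init is None
        else np.array(w_init, dtype=float)
    )
    # deterministic presentation schedule, then pre-drawn firings per voter
    # (independent substream per voter derived from the master seed)
    sample_seq = np.array(
        [_presentation_order(t, labels, n_c) for t in range(1, steps + 1)]
    )
    voter_seeds = rng.integers(0, 2**31, n_e + 1)

    def _draw_firings(probs: np.ndarray, seed: int) -> np.ndarray:
        sub = np.random.default_rng(seed)
        cdf = np.cumsum(probs[sample_seq], axis=1)
        u = sub.random(steps)
        return np.minimum((u[:, None] > cdf).sum(axis=1), n_c - 1)

    m_idx = np.stack(
        [_draw_firings(v.probs, voter_seeds[j]) for j, v in enumerate(voters)], axis=1
    )  # (steps, N_E)
    g_idx = _draw_firings(gate.probs, voter_seeds[n_e])  # (steps,)

    eye = np.eye(n_c, dtype=bool)
    traj = [] if record_every else None
    for t in range(steps):
        fired_m = eye[m_idx[t]].T  # (N_C, N_E)
        fired_g = eye[g_idx[t]]  # (N_C,)
        both = fired_g[:, None, None] & fired_m[None, :, :]
        one = fired_g[:, None, None] ^ fired_m[None, :, :]
        delta = np.where(both, params.a * np.exp(-w) - 1.0, np.where(one, -1.0, 0.0))
        w += params.eta * delta
        if record_every and (t + 1) % record_every == 0:
            traj.append(w.copy())
    trajectory = np.stack(traj) if traj else None
    return EnsembleWeights(w), trajectory


def run_measuring_phase(
    voters: list[VoterTable],
    gate_weights: EnsembleWeights,
    class_c: int,
    duration: int,
    labels: np.ndarray,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Frozen-weight measuring phase for one class.

    Each step the voters fire one neuron each; the final neuron is drawn from
    the softmax of the weighted instantaneous spike sum (unit-impulse EPSP
    kernel).  Returns (empirical firing frequencies over final neurons,
    per-step analytic probability vectors) so the empirical counts can be
    compared with the closed-form expectation.
    """
    rng = np.random.default_rng(rng_seed)
    n_c = gate_weights.n_classes
    n_e = gate_weights.ensemble_size
    labels = np.asarray(labels)
    members = np.flatnonzero(labels == class_c)
    counts = np.zeros(n_c)
    step_probs = np.empty((duration, n_c))
    w = gate_weights.w
    for t in range(duration):
        l = int(members[t % members.size])
        fired = [rng.choice(n_c, p=v.probs[l]) for v in voters]
        u = w[:, fired, np.arange(n_e)].sum(axis=1)
        p = _softmax(u)
        step_probs[t] = p
        counts[rng.choice(n_c, p=p)] += 1
    return counts / duration, step_probs
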