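"""Performance and diversity measures for spiking classifiers.

Normalized conditional entropy (NCE) scores how exclusively each output
neuron fires for one input class, without requiring any fixed mapping between
neuron indices and class labels:

    NCE = H(C | F) / H(C, F)

over the joint distribution of presented class C and firing neuron F.  For
N_C-class problems NCE lies in [0, 0.5]: 0 means perfectly class-exclusive
firing, 0.5 means chance (uniform independent firing).

Ensemble diversity is the entropy (base N_C) of the soft vote proportions of
the ensemble members relative to the gating reference, averaged over data:
0 when all members always agree with the instructed class, 1 when votes are
uniform over classes on every datum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NCE_UNDEFINED",
    "WindowPolicy",
    "nce",
    "windowed_nce",
    "joint_counts",
    "diversity",
    "assign_classes",
    "error_rate",
]

#: sentinel returned when the joint distribution is degenerate (H(C,F) = 0)
#: or a requested window contains no spikes; plots then show burn-in gaps
#: honestly instead of a spurious 0.
NCE_UNDEFINED = float("nan")


@dataclass
class WindowPolicy:
    """Moving-window policy for time-resolved NCE.

    The window is [T_p, t] with a dynamically growing lower bound

        T_p = t * (1 - d / (4 D)),   d = t while t < 2D, else d = 2D,

    where D is the duration of one full round of data presentation (seconds).
    Early in a run the window covers a shrinking fraction of history, which
    burns out the immature initial output faster; from t = 2D onward the
    window is simply the latest half of the run.
    """

    round_duration: float = 224.0

    def lower_bound(self, t: float) -> float:
        d = min(t, 2.0 * self.round_duration)
        t_p = t * (1.0 - d / (4.0 * self.round_duration))
        return max(t_p, 0.0)


def nce(joint) -> float:
    """Normalized conditional entropy H(C|F)/H(C,F) of a joint class-by-neuron
    count (or probability) table.  0 log 0 is taken as 0; a degenerate table
    with a single occupied cell has H(C,F) = 0 and returns ``NCE_UNDEFINED``.
    """
    p = np.asarray(joint, dtype=float)
    if np.any(p < 0):
        raise ValueError("joint counts must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("joint table must have positive total mass")
    p = p / total
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    h_joint = -np.sum(p * log_p)
    if h_joint == 0.0:
        return NCE_UNDEFINED
    col = p.sum(axis=0, keepdims=True)  # marginal over firing neurons
    with np.errstate(divide="ignore", invalid="ignore"):
        log_cond = np.where(p > 0, np.log(np.where(p > 0, p, 1.0) / col), 0.0)
    h_cond = -np.sum(p * log_cond)
    return float(h_cond / h_joint)


def joint_counts(
    times: np.ndarray,
    neurons: np.ndarray,
    classes: np.ndarray,
    n_classes: int,
    t_lo: float = -np.inf,
    t_hi: float = np.inf,
) -> np.ndarray:
    """Accumulate spike counts into a (class, neuron) table over [t_lo, t_hi]."""
    times = np.asarray(times, dtype=float)
    neurons = np.asarray(neurons, dtype=int)
    classes = np.asarray(classes, dtype=int)
    sel = (times >= t_lo) & (times <= t_hi) & (classes >= 0)
    table = np.zeros((n_classes, n_classes))
    np.add.at(table, (classes[sel], neurons[sel]), 1.0)
    return table


def windowed_nce(
    times: np.ndarray,
    neurons: np.ndarray,
    classes: np.ndarray,
    n_classes: int,
    t: float,
    policy: WindowPolicy,
) -> float:
    """NCE of the spikes inside the policy's window [T_p(t), t]."""
    if t <= 0:
        raise ValueError("t must be positive")
    t_p = policy.lower_bound(t)
    table = joint_counts(times, neurons, classes, n_classes, t_p, t)
    if table.sum() == 0:
        return NCE_UNDEFINED
    return nce(table)


def assign_classes(joint: np.ndarray) -> np.ndarray:
    """Map each neuron (column) to the class (row) it fired most for; neurons
    that never fired get -1 (no class)."""
    joint = np.asarray(joint, dtype=float)
    assignment = np.argmax(joint, axis=0)
    assignment[joint.sum(axis=0) == 0] = -1
    return assignment


def diversity(
    member_counts: np.ndarray,
    class_of_neuron: np.ndarray,
    n_classes: int,
) -> float:
    """Entropy-based ensemble diversity.

    member_counts : array (M, N_E, N_C) of per-datum spike counts of every
        ensemble member's output neurons.
    class_of_neuron : array (N_E, N_C) mapping each member's neuron index to
        the class it represents (resolved by maximal co-firing with the
        gating reference; -1 for unassigned neurons, whose spikes are
        ignored).

    Div = (1/M) sum_l sum_k -P_k^l log_{N_C} P_k^l, with P_k^l the soft
    proportion of members voting class k on datum l.
    """
    member_counts = np.asarray(member_counts, dtype=float)
    m, n_e, n_c = member_counts.shape
    class_of_neuron = np.asarray(class_of_neuron, dtype=int)
    # per-member soft vote over classes: route neuron counts to their classes
    votes = np.zeros((m, n_e, n_classes))
    for j in range(n_e):
        for i in range(n_c):
            k = class_of_neuron[j, i]
            if k >= 0:
                votes[:, j, k] += member_counts[:, j, i]
    member_totals = votes.sum(axis=2, keepdims=True)
    used = 0
    div = 0.0
    for l in range(m):
        tot = member_totals[l, :, 0]
        if np.all(tot == 0):
            continue  # datum with zero ensemble spikes: skipped
        frac = np.divide(
            votes[l], tot[:, None], out=np.zeros_like(votes[l]), where=tot[:, None] > 0
        )
        p_k = frac.mean(axis=0)
        nz = p_k > 0
        div += -np.sum(p_k[nz] * np.log(p_k[nz]) / np.log(n_classes))
        used += 1
    if used == 0:
        raise ValueError("no datum with ensemble spikes")
    return float(div / used)


def error_rate(
    train_joint: np.ndarray,
    test_winners: np.ndarray,
    test_classes: np.ndarray,
) -> float:
    """Test classification error from train-phase class assignment.

    Each final neuron is assigned to the class it fired most for during
    training; a test presentation is an error when its winning neuron is
    assigned to a different class (or to none).  Winners of -1 (no spikes in
    the presentation) also count as errors.
    """
    assignment = assign_classes(train_joint)
    test_winners = np.asarray(test_winners, dtype=int)
    test_classes = np.asarray(test_classes, dtype=int)
    if test_winners.shape != test_classes.shape:
        raise ValueError("winners and classes must align")
    predicted = np.where(test_winners >= 0, assignment[test_winners], -1)
    return float(np.mean(predicted != test_classes))
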