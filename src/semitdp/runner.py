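"""Full spiking ensemble architecture: input layer -> SEM ensemble + gating
-> ITDP-combined final WTA (optionally a parallel STDP-combined final WTA).

The ensemble layer holds N_E SEM circuits on distinct feature subsets plus a
gating circuit (a learned SEM on the full feature set, a supervised
label-driven spike source, or an automatically promoted ensemble member).
Ensemble spikes reach the final WTA through ITDP synapses whose plasticity
is enabled by the gating circuit's topographic distal projections; the
distal spikes themselves contribute nothing to the final membrane
potential.  A parallel STDP final WTA can be attached for rule comparison:
it receives the same ensemble spike streams plus the gating output as an
ordinary extra member, learned by ordinary STDP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inputs import (
    BinaryImageSet,
    FeatureAssignment,
    PresentationSchedule,
    population_encode_eligible,
    select_normal_gaussian,
    select_random,
    select_stretched_gaussian,
)
from .itdp import ITDPLayer, ITDPParams
from .metrics import WindowPolicy, joint_counts, windowed_nce
from .sem import SEMParams, WTACircuit

__all__ = [
    "SpikeRecord",
    "TopologyConfig",
    "EnsembleNetwork",
    "inhibition_shift",
    "build",
]

#: supervised gating protocol: three spikes per presentation, 15 ms apart,
#: the first 5 ms after presentation onset.
SUPERVISED_SPIKE_OFFSETS = (0.005, 0.020, 0.035)


def inhibition_shift(n_members: int) -> float:
    """Final-WTA inhibition shift I_s = 560 - 4 N_E: the final circuit has
    far fewer afferents than the ensemble circuits, so its inhibition is
    relaxed (A_inh - I_s, O_inh + I_s) to match output intensity."""
    return 560.0 - 4.0 * n_members


@dataclass
class SpikeRecord:
    """Timestamped firing events plus the presentation timeline.

    circuit ids: 0..N_E-1 ensemble members, "gating", "final", "final_stdp".
    """

    times: list = field(default_factory=list)
    circuits: list = field(default_factory=list)
    neurons: list = field(default_factory=list)
    # presentation windows: onset, offset, class, sample index
    pres_t0: list = field(default_factory=list)
    pres_t1: list = field(default_factory=list)
    pres_class: list = field(default_factory=list)
    pres_sample: list = field(default_factory=list)

    def add(self, t: float, circuit, neuron: int) -> None:
        if self.times and t < self.times[-1]:
            raise ValueError("spike times must be non-decreasing")
        self.times.append(t)
        self.circuits.append(circuit)
        self.neurons.append(neuron)

    def spikes_of(self, circuit) -> tuple[np.ndarray, np.ndarray]:
        sel = [i for i, c in enumerate(self.circuits) if c == circuit]
        return (
            np.asarray([self.times[i] for i in sel]),
            np.asarray([self.neurons[i] for i in sel], dtype=int),
        )

    def class_at(self, times: np.ndarray) -> np.ndarray:
        """Class presented at each spike time (-1 during rest periods)."""
        t0 = np.asarray(self.pres_t0)
        t1 = np.asarray(self.pres_t1)
        cls = np.asarray(self.pres_class, dtype=int)
        idx = np.searchsorted(t0, times, side="right") - 1
        idx = np.clip(idx, 0, len(t0) - 1)
        inside = (times >= t0[idx]) & (times < t1[idx])
        return np.where(inside, cls[idx], -1)

    def joint(self, circuit, n_classes: int, t_lo=-np.inf, t_hi=np.inf) -> np.ndarray:
        times, neurons = self.spikes_of(circuit)
        classes = self.class_at(times) if times.size else np.empty(0, dtype=int)
        return joint_counts(times, neurons, classes, n_classes, t_lo, t_hi)

    def nce_at(self, circuit, n_classes: int, t: float, policy: WindowPolicy) -> float:
        times, neurons = self.spikes_of(circuit)
        classes = self.class_at(times) if times.size else np.empty(0, dtype=int)
        return windowed_nce(times, neurons, classes, n_classes, t, policy)

    def presentation_counts(self, circuit, n_classes: int) -> np.ndarray:
        """Spike counts per presentation window: shape (n_presentations, K)."""
        times, neurons = self.spikes_of(circuit)
        t0 = np.asarray(self.pres_t0)
        t1 = np.asarray(self.pres_t1)
        out = np.zeros((t0.size, n_classes))
        if times.size:
            idx = np.searchsorted(t0, times, side="right") - 1
            ok = (idx >= 0) & (times < t1[np.clip(idx, 0, None)])
            np.add.at(out, (idx[ok], neurons[ok]), 1.0)
        return out

    def presentation_winners(self, circuit, n_classes: int) -> np.ndarray:
        """Winning neuron per presentation: most spikes in the window; ties
        broken by earliest final spike, then lowest index; -1 when silent."""
        times, neurons = self.spikes_of(circuit)
        t0 = np.asarray(self.pres_t0)
        t1 = np.asarray(self.pres_t1)
        counts = np.zeros((t0.size, n_classes))
        last = np.full((t0.size, n_classes), -np.inf)
        if times.size:
            idx = np.searchsorted(t0, times, side="right") - 1
            ok = (idx >= 0) & (times < t1[np.clip(idx, 0, None)])
            np.add.at(counts, (idx[ok], neurons[ok]), 1.0)
            np.maximum.at(last, (idx[ok], neurons[ok]), times[ok])
        winners = np.full(t0.size, -1, dtype=int)
        for p in range(t0.size):
            c = counts[p]
            if c.max() == 0:
                continue
            top = np.flatnonzero(c == c.max())
            if top.size == 1:
                winners[p] = top[0]
            else:
                # earliest last-spike time among tied neurons, then lowest idx
                winners[p] = top[np.argmin(last[p, top])]
        return winners

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "circuit": self.circuits, "neuron": self.neurons}
        )


@dataclass
class TopologyConfig:
    """Sizes, scheme and gating variant of one experiment."""

    n_classes: int = 4
    n_members: int = 5
    feature_scheme: str = "random"  # random | normal_gaussian | stretched_gaussian
    gating_mode: str = "unsupervised"  # unsupervised | supervised | auto
    stdp_parallel: bool = False
    sem: SEMParams = field(default_factory=SEMParams)
    itdp: ITDPParams = field(default_factory=ITDPParams)
    schedule: PresentationSchedule = field(default_factory=PresentationSchedule)
    auto_check_interval: int = 50  # presentations between gating-rank checks


_SELECTORS = {
    "random": select_random,
    "normal_gaussian": select_normal_gaussian,
    "stretched_gaussian": select_stretched_gaussian,
}


class EnsembleNetwork:
    """The wired system: ensemble SEM circuits, gating, ITDP final layer and
    (optionally) a parallel STDP final layer."""

    def __init__(
        self,
        dataset: BinaryImageSet,
        config: TopologyConfig,
        seed: int | np.random.Generator = 0,
    ) -> None:
        self.config = config
        self.rng = np.random.default_rng(seed)
        self.dataset = dataset
        k = config.n_classes
        n_e = config.n_members
        if config.feature_scheme not in _SELECTORS:
            raise ValueError(f"unknown feature scheme {config.feature_scheme!r}")
        self.features: FeatureAssignment = _SELECTORS[config.feature_scheme](
            dataset, n_e, self.rng
        )
        shape = dataset.active_mask.shape
        self.n_pixels_total = shape[0] * shape[1]
        # per-circuit afferent input-neuron ids within the global 2-per-pixel
        # neuron space
        def neuron_ids(pixels: np.ndarray) -> np.ndarray:
            return np.sort(np.concatenate([2 * pixels, 2 * pixels + 1]))

        self.members = [
            WTACircuit(
                k,
                2 * sub.size,
                config.sem,
                self.rng,
                input_idx=neuron_ids(sub),
            )
            for sub in self.features.member_pixels
        ]
        self.gating_circuit = None
        if config.gating_mode in ("unsupervised", "auto"):
            gp = self.features.gating_pixels
            self.gating_circuit = WTACircuit(
                k, 2 * gp.size, config.sem, self.rng, input_idx=neuron_ids(gp)
            )
        elif config.gating_mode != "supervised":
            raise ValueError(f"unknown gating mode {config.gating_mode!r}")
        # final ITDP-combined WTA: afferents are the N_E * K ensemble neurons;
        # inhibition relaxed by I_s because it has few afferents
        i_s = inhibition_shift(n_e)
        self.final = WTACircuit(
            k,
            n_e * k,
            config.sem,
            self.rng,
            A_inh=config.sem.A_inh - i_s,
            O_inh=config.sem.O_inh + i_s,
        )
        self.itdp = ITDPLayer(k, n_e * k, config.itdp, self.rng)
        # the final WTA's membrane weights ARE the ITDP weights (one array)
        self.final.weights = self.itdp.weights
        self.final_stdp = None
        if config.stdp_parallel:
            i_s2 = inhibition_shift(n_e + 1)
            self.final_stdp = WTACircuit(
                k,
                (n_e + 1) * k,
                config.sem,
                self.rng,
                A_inh=config.sem.A_inh - i_s2,
                O_inh=config.sem.O_inh + i_s2,
            )
        # which circuit plays the gating role: -1 = dedicated gating circuit
        # (or the supervised spike source); >= 0 = promoted ensemble member
        self.gating_role = -1
        # cumulative presentations and the auto-selection horizon (one round)
        self._pres_seen = 0
        self._auto_window_end: int | None = None
        self.window_policy = WindowPolicy(
            round_duration=config.schedule.cycle  # rescaled per-train below
        )
        self._verify_counts()

    # -- construction checks ----------------------------------------------
    def _verify_counts(self) -> None:
        cfg = self.config
        k = cfg.n_classes
        n_active_super = self.dataset.n_active
        n_i = 2 * n_active_super  # input neurons over active pixels
        got_stdp = sum(c.weights.size for c in self.members)
        if self.gating_circuit is not None:
            got_stdp += self.gating_circuit.weights.size
        n_circuits = cfg.n_members + (1 if self.gating_circuit is not None else 0)
        expected = k * n_i * n_circuits / 4
        if got_stdp != expected:
            raise RuntimeError(
                f"STDP synapse count {got_stdp} != K N_I (N_E+1)/4 = {expected}"
            )
        if self.itdp.weights.size != k * k * cfg.n_members:
            raise RuntimeError("ITDP synapse count != K^2 N_E")

    @property
    def stdp_synapse_count(self) -> int:
        n = sum(c.weights.size for c in self.members)
        if self.gating_circuit is not None:
            n += self.gating_circuit.weights.size
        return n

    @property
    def itdp_synapse_count(self) -> int:
        return self.itdp.weights.size

    # -- plasticity switches ------------------------------------------------
    def set_plastic(self, on: bool) -> None:
        for c in self.members:
            c.plastic = on
        if self.gating_circuit is not None:
            self.gating_circuit.plastic = on
        self.final.plastic = on
        if self.final_stdp is not None:
            self.final_stdp.plastic = on
        self.itdp.plastic = on

    def weight_hash(self) -> int:
        import hashlib

        h = hashlib.sha256()
        for c in self.members + [self.final]:
            h.update(c.weights.tobytes())
            h.update(c.excitability.tobytes())
        if self.gating_circuit is not None:
            h.update(self.gating_circuit.weights.tobytes())
        h.update(self.itdp.weights.tobytes())
        if self.final_stdp is not None:
            h.update(self.final_stdp.weights.tobytes())
        return int.from_bytes(h.digest()[:8], "big")

    # -- simulation ---------------------------------------------------------
    def _presentation_order(self, labels: np.ndarray, rounds: int) -> list[int]:
        """Round-robin over classes; samples cycle within each class."""
        k = self.config.n_classes
        per_class = [np.flatnonzero(labels == c) for c in range(k)]
        if any(p.size == 0 for p in per_class):
            raise ValueError("every class needs at least one sample")
        n_per_round = sum(p.size for p in per_class)
        order = []
        for t in range(rounds * n_per_round):
            c = t % k
            n = (t // k) % per_class[c].size
            order.append(int(per_class[c][n]))
        return order

    def run(
        self,
        dataset: BinaryImageSet,
        rounds: int,
        rng: np.random.Generator | int | None = None,
        learn: bool = True,
        t_start: float | None = None,
        record: SpikeRecord | None = None,
    ) -> SpikeRecord:
        """Present the dataset for ``rounds`` full passes.

        With learn=True all plasticities (STDP, excitability, ITDP) are
        active; with learn=False every weight is frozen (test phase).
        Simulated time continues across calls unless ``t_start`` overrides
        it (it must not move backwards past pending inhibition).  Returns
        the spike record (appended to ``record`` when given, so train and
        test phases can share a timeline).
        """
        cfg = self.config
        rng = self.rng if rng is None else np.random.default_rng(rng)
        self.set_plastic(learn)
        record = SpikeRecord() if record is None else record
        p = cfg.sem
        sched = cfg.schedule
        dt = p.dt
        n_present = int(round(sched.T_present / dt))
        n_rest = int(round(sched.T_rest / dt))
        p_in = 1.0 - np.exp(-sched.input_rate * dt)
        rho_s = np.exp(-dt / p.tau_s)
        rho_f = np.exp(-dt / p.tau_f)
        a_epsp = p.A_EPSP
        k = cfg.n_classes
        n_e = cfg.n_members
        order = self._presentation_order(dataset.labels, max(rounds, 1))
        n_round = len(order) // max(rounds, 1)
        if rounds < 1:
            return record
        round_dur = n_round * sched.cycle
        if cfg.gating_mode == "auto" and self._auto_window_end is None:
            self._auto_window_end = n_round
        self.window_policy = WindowPolicy(round_duration=round_dur)
        sup_steps = sorted(int(round(o / dt)) for o in SUPERVISED_SPIKE_OFFSETS)

        n_neurons_in = 2 * self.n_pixels_total
        es_in = np.zeros(n_neurons_in)
        ef_in = np.zeros(n_neurons_in)
        es_ens = np.zeros(n_e * k)
        ef_ens = np.zeros(n_e * k)
        # gating EPSP traces feed only the parallel STDP final layer
        self._es_gate = np.zeros(k)
        self._ef_gate = np.zeros(k)
        active_ids = self.dataset.active_pixel_ids()

        t = getattr(self, "_t_now", 0.0) if t_start is None else t_start
        n_pres_done = 0
        for pres_i, sample in enumerate(order):
            image = dataset.images[sample]
            label = int(dataset.labels[sample])
            elig = population_encode_eligible(image, active_ids)
            record.pres_t0.append(t)
            record.pres_t1.append(t + sched.T_present)
            record.pres_class.append(label)
            record.pres_sample.append(sample)
            for step in range(n_present + n_rest):
                t += dt
                presenting = step < n_present
                # EPSP trace decay
                es_in *= rho_s
                ef_in *= rho_f
                es_ens *= rho_s
                ef_ens *= rho_f
                self._es_gate *= rho_s
                self._ef_gate *= rho_f
                if presenting:
                    spiked = elig[rng.random(elig.size) < p_in]
                    es_in[spiked] += 1.0
                    ef_in[spiked] += 1.0
                y_in = a_epsp * (es_in - ef_in)
                self._step_prox = []
                self._step_dist = []
                # ensemble layer
                for j, circ in enumerate(self.members):
                    y_sel = y_in[circ.input_idx]
                    fired = circ.step_fire(y_sel, t, rng)
                    if np.any(fired):
                        if learn:
                            circ.stdp_update(fired, y_sel)
                            circ.excitability_update(fired)
                        for idx in np.flatnonzero(fired):
                            record.add(t, j, int(idx))
                            g_idx = j * k + idx
                            es_ens[g_idx] += 1.0
                            ef_ens[g_idx] += 1.0
                            self._step_prox.append(int(g_idx))
                            if self.gating_role == j:
                                # promoted member gates; its spike is already
                                # recorded under its own circuit id
                                self._distal_spike(int(idx), t, record, False)
                # gating layer
                if cfg.gating_mode == "supervised":
                    if presenting and step in sup_steps:
                        self._distal_spike(label, t, record, True)
                elif self.gating_circuit is not None:
                    # the dedicated gating circuit always runs and learns,
                    # but it only drives ITDP while it holds the gating role
                    gc = self.gating_circuit
                    y_sel = y_in[gc.input_idx]
                    fired = gc.step_fire(y_sel, t, rng)
                    if np.any(fired):
                        if learn:
                            gc.stdp_update(fired, y_sel)
                            gc.excitability_update(fired)
                        for idx in np.flatnonzero(fired):
                            if self.gating_role == -1:
                                self._distal_spike(int(idx), t, record, True)
                            else:
                                record.add(t, "gating", int(idx))
                # ITDP: all of this step's proximal and distal spikes are
                # buffered together, then each trigger pairs against the
                # full opposite-pathway buffer
                if self._step_prox or self._step_dist:
                    self.itdp.step(t, self._step_prox, self._step_dist)
                # final ITDP WTA (membrane weights are the ITDP weights;
                # distal gating spikes contribute nothing here)
                y_ens = a_epsp * (es_ens - ef_ens)
                fired = self.final.step_fire(y_ens, t, rng)
                if np.any(fired):
                    if learn:
                        self.final.excitability_update(fired)
                    for idx in np.flatnonzero(fired):
                        record.add(t, "final", int(idx))
                # parallel STDP final WTA: same ensemble inputs plus the
                # gating output as an ordinary extra member
                if self.final_stdp is not None:
                    y_gate = a_epsp * (self._es_gate - self._ef_gate)
                    y_all = np.concatenate([y_ens, y_gate])
                    fired = self.final_stdp.step_fire(y_all, t, rng)
                    if np.any(fired):
                        if learn:
                            self.final_stdp.stdp_update(fired, y_all)
                            self.final_stdp.excitability_update(fired)
                        for idx in np.flatnonzero(fired):
                            record.add(t, "final_stdp", int(idx))
            n_pres_done += 1
            self._pres_seen += 1
            # automatic gating selection: active only while the first round
            # of presentations (over the network's lifetime) is running
            if (
                cfg.gating_mode == "auto"
                and learn
                and self._pres_seen <= self._auto_window_end
                and n_pres_done % cfg.auto_check_interval == 0
            ):
                self._auto_select(record, t)
        self._t_now = t
        return record

    def _distal_spike(
        self, neuron: int, t: float, record: SpikeRecord, record_as_gating: bool
    ) -> None:
        """A gating-role spike: fed to ITDP (distal pathway, no membrane
        contribution to the final WTA) and to the gating EPSP trace used by
        the parallel STDP final layer (where it is an ordinary input)."""
        if record_as_gating:
            record.add(t, "gating", neuron)
        self._step_dist.append(neuron)
        self._es_gate[neuron] += 1.0
        self._ef_gate[neuron] += 1.0

    def _auto_select(self, record: SpikeRecord, t: float) -> None:
        """Promote the best-ranked circuit (by running windowed NCE) to the
        gating role."""
        k = self.config.n_classes
        scores = {}
        current = "gating" if self.gating_role == -1 else self.gating_role
        for cid in list(range(self.config.n_members)) + ["gating"]:
            val = record.nce_at(cid, k, t, self.window_policy)
            if np.isfinite(val):
                scores[cid] = val
        if not scores or current not in scores:
            return
        best = min(scores, key=scores.get)
        if best != current and scores[best] < scores[current]:
            self.gating_role = -1 if best == "gating" else int(best)

    # convenience wrappers ---------------------------------------------------
    def train(
        self,
        dataset: BinaryImageSet | None = None,
        rounds: int = 2,
        rng=None,
        record: SpikeRecord | None = None,
    ) -> SpikeRecord:
        return self.run(
            dataset or self.dataset, rounds, rng=rng, learn=True, record=record
        )

    def test(
        self,
        dataset: BinaryImageSet,
        rounds: int = 1,
        rng=None,
        t_start: float | None = None,
        record: SpikeRecord | None = None,
    ) -> SpikeRecord:
        return self.run(
            dataset, rounds, rng=rng, learn=False, t_start=t_start, record=record
        )


def build(
    dataset: BinaryImageSet, config: TopologyConfig, seed=0
) -> EnsembleNetwork:
    """Construct and verify the wired system."""
    return EnsembleNetwork(dataset, config, seed)


def member_class_assignment(
    record: SpikeRecord, n_classes: int, n_members: int
) -> np.ndarray:
    """Resolve which class each ensemble neuron represents, by maximal
    co-firing with the gating reference: counts of each neuron's spikes in
    presentations whose gating winner was class k; each neuron is assigned
    the k it co-fired with most (-1 if it never fired)."""
    gate_counts = record.presentation_counts("gating", n_classes)
    instructed = np.where(
        gate_counts.sum(axis=1) > 0, np.argmax(gate_counts, axis=1), -1
    )
    assignment = np.full((n_members, n_classes), -1, dtype=int)
    for j in range(n_members):
        counts = record.presentation_counts(j, n_classes)  # (P, K)
        co = np.zeros((n_classes, n_classes))  # [instructed k, neuron i]
        ok = instructed >= 0
        np.add.at(co, (instructed[ok],), counts[ok])
        fired = co.sum(axis=0) > 0
        assignment[j, fired] = np.argmax(co, axis=0)[fired]
    return assignment


def ensemble_diversity(
    record: SpikeRecord, n_classes: int, n_members: int
) -> float:
    """Entropy-based diversity of the ensemble's soft votes over one dataset
    pass, with neuron classes resolved against the gating reference."""
    from .metrics import diversity

    assignment = member_class_assignment(record, n_classes, n_members)
    member_counts = np.stack(
        [record.presentation_counts(j, n_classes) for j in range(n_members)],
        axis=1,
    )  # (P, N_E, K)
    return diversity(member_counts, assignment, n_classes)
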