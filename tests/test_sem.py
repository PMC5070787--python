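"""SEM microcircuit: EPSP kernel, inhibition, firing, plasticities, noise."""

import numpy as np
import pytest

from semitdp.sem import (
    PlasticityState,
    SEMParams,
    WTACircuit,
    epsp_kernel,
    epsp_peak_time,
    epsp_value,
    inhibition,
    ou_step,
    stdp_delta,
    variance_tracking_step,
)

P = SEMParams(ou_enabled=False)


class TestEPSP:
    def test_no_spikes_is_zero(self):
        assert epsp_value([], 0.05, P) == 0.0

    def test_single_spike_peak_is_one(self):
        t = np.arange(0, 0.1, 1e-6)
        assert epsp_kernel(t, P).max() == pytest.approx(1.0, abs=1e-6)

    def test_peak_time_matches_grid_search(self):
        """Dense numeric grid search against the closed-form argmax
        tau_s tau_f ln(tau_s/tau_f)/(tau_s - tau_f) ~ 2.9 ms."""
        t = np.arange(0, 0.05, 1e-7)
        grid_peak = t[np.argmax(epsp_kernel(t, P))]
        assert epsp_peak_time(P) == pytest.approx(grid_peak, abs=1e-6)
        assert epsp_peak_time(P) == pytest.approx(0.0029, abs=1e-4)

    def test_superposition_of_spikes(self):
        times = [0.0, 0.004, 0.011]
        t = 0.02
        total = epsp_value(times, t, P)
        assert total == pytest.approx(sum(epsp_value([s], t, P) for s in times))

    def test_decays_to_zero(self):
        assert epsp_value([0.0], 1.0, P) == pytest.approx(0.0, abs=1e-12)


class TestInhibition:
    def test_at_spike_time_equals_minus_amplitude(self):
        assert inhibition(1.0, 1.0, P) == pytest.approx(-P.A_inh)

    def test_relaxes_to_resting_offset(self):
        assert inhibition(10.0, 1.0, P) == pytest.approx(P.O_inh)

    def test_one_time_constant(self):
        got = inhibition(1.0 + P.tau_inh, 1.0, P)
        assert got == pytest.approx(-550 - 2450 / np.e)
        assert got == pytest.approx(-1451.3, abs=0.05)

    def test_before_any_spike_resting(self):
        assert inhibition(0.5, -np.inf, P) == P.O_inh


class TestFiring:
    def _circuit(self, n_inputs=20, seed=0, **kw):
        rng = np.random.default_rng(seed)
        kw.setdefault("A_inh", 300.0)
        kw.setdefault("O_inh", -40.0)
        return WTACircuit(4, n_inputs, P, rng, **kw), rng

    def test_posterior_sums_to_one_and_uniform_when_equal(self):
        circ, _ = self._circuit()
        q = circ.posterior(np.full(4, 3.0))
        assert q.sum() == pytest.approx(1.0)
        assert q == pytest.approx(np.full(4, 0.25))

    def test_at_most_one_spike_per_step(self):
        circ, rng = self._circuit()
        y = np.full(20, 0.7)
        for step in range(200):
            fired = circ.step_fire(y, 0.001 * (step + 1), rng)
            assert fired.sum() <= 1

    def test_suppressed_just_after_spike(self):
        """The -A_inh pulse silences the circuit immediately after a spike."""
        circ, rng = self._circuit()
        y = np.full(20, 0.7)
        t = 0.0
        while True:
            t += P.dt
            if circ.step_fire(y, t, rng).any():
                break
            assert t < 1.0, "circuit never fired"
        # immediately after: effectively zero firing probability
        fired_next = [circ.step_fire(y, t + P.dt, rng).any() for _ in range(50)]
        assert not any(fired_next)

    def test_bursts_of_a_few_spikes_per_presentation(self):
        """With full-scale afferent drive (347 pixels -> 694 input neurons,
        one eligible neuron per pixel at ~0.71 mean EPSP) and the default
        inhibition, the recovery from the -A_inh pulse paces a regular burst
        of roughly 3-4 spikes per 40 ms presentation."""
        rng = np.random.default_rng(4)
        n = 694
        circ = WTACircuit(4, n, SEMParams(ou_enabled=False), rng)
        circ.plastic = False
        y = np.zeros(n)
        y[::2] = 0.71  # one neuron of each ON/OFF pair active
        t, counts = 0.0, []
        for pres in range(30):
            c = 0
            for step in range(40):
                t += P.dt
                c += int(circ.step_fire(y, t, rng).any())
            counts.append(c)
        mean_burst = np.mean(counts)
        assert 2.0 <= mean_burst <= 6.0


class TestSTDP:
    def test_silent_presynapse_depresses(self):
        assert stdp_delta(0.3, 0.0, P.c) == pytest.approx(-1.0)

    @pytest.mark.parametrize("y", [1.0, 0.5, 0.2])
    def test_clamped_activation_fixed_point(self, y):
        """Iterating the update with variance-tracking rates converges to
        w* = log(c y) (y = 1 gives log c = 5)."""
        w = np.array([0.0])
        state = PlasticityState.for_weights(w, P.mu)
        for _ in range(4000):
            w = w + state.eta * stdp_delta(w, y, P.c)
            variance_tracking_step(state, w, P.mu)
        assert w[0] == pytest.approx(np.log(P.c * y), abs=0.1)

    def test_update_only_on_postsynaptic_spike(self):
        rng = np.random.default_rng(0)
        circ = WTACircuit(4, 10, P, rng)
        before = circ.weights.copy()
        circ.stdp_update(np.zeros(4, dtype=bool), np.ones(10))
        assert (circ.weights == before).all()

    def test_update_touches_only_fired_rows(self):
        rng = np.random.default_rng(0)
        circ = WTACircuit(4, 10, P, rng)
        before = circ.weights.copy()
        fired = np.array([True, False, False, False])
        circ.stdp_update(fired, np.ones(10))
        assert not np.allclose(circ.weights[0], before[0])
        assert (circ.weights[1:] == before[1:]).all()


class TestExcitability:
    def test_equal_firing_converges_to_log_half(self):
        """Two neurons firing alternately settle near w0 = log(1/2) and the
        prior constraint sum e^{w0} = 1."""
        rng = np.random.default_rng(0)
        circ = WTACircuit(2, 4, P, rng)
        for i in range(6000):
            fired = np.array([i % 2 == 0, i % 2 == 1])
            circ.excitability_update(fired)
        assert circ.excitability == pytest.approx(np.log(0.5) * np.ones(2), abs=0.1)
        assert np.exp(circ.excitability).sum() == pytest.approx(1.0, abs=0.05)

    def test_never_firing_neuron_decreases_monotonically(self):
        rng = np.random.default_rng(0)
        circ = WTACircuit(3, 4, P, rng)
        fired = np.array([True, False, False])
        prev = circ.excitability[2]
        for _ in range(100):
            circ.excitability_update(fired)
            assert circ.excitability[2] < prev
            prev = circ.excitability[2]

    def test_no_circuit_spike_no_update(self):
        rng = np.random.default_rng(0)
        circ = WTACircuit(3, 4, P, rng)
        before = circ.excitability.copy()
        circ.excitability_update(np.zeros(3, dtype=bool))
        assert (circ.excitability == before).all()


class TestVarianceTracking:
    def test_constant_variable_anneals_to_zero_rate(self):
        w = np.array([2.0])
        state = PlasticityState.for_weights(w, 0.01)
        for _ in range(5000):
            variance_tracking_step(state, w, 0.01)
        assert state.eta[0] < 1e-3  # annealed from ~mu toward 0
        assert state.m1[0] == pytest.approx(2.0, abs=0.05)

    def test_large_mean_logistic_factor_saturates(self):
        state = PlasticityState(
            m1=np.array([50.0]), m2=np.array([50.0**2 + 4.0]), eta=np.array([0.01])
        )
        variance_tracking_step(state, np.array([50.0]), 0.01)
        # eta was recomputed as mu * var / (1 + e^{-m1}) ~ mu * var
        assert state.eta[0] == pytest.approx(0.01 * 4.0, rel=1e-6)

    def test_tracks_sample_variance_of_oscillation(self):
        """For a +-1 oscillating variable the tracked variance approaches the
        running sample variance (~1)."""
        state = PlasticityState.for_weights(np.array([0.0]), 0.01)
        for i in range(20000):
            w = np.array([1.0 if i % 2 == 0 else -1.0])
            variance_tracking_step(state, w, 0.01)
        var = state.m2[0] - state.m1[0] ** 2
        assert var == pytest.approx(1.0, abs=0.2)

    def test_negative_variance_floored(self):
        state = PlasticityState(
            m1=np.array([1.0]), m2=np.array([0.5]), eta=np.array([0.01])
        )
        variance_tracking_step(state, np.array([1.0]), 0.01)
        assert state.eta[0] >= 0.0


class TestOUNoise:
    def test_disabled_noise_is_identically_zero(self):
        params = SEMParams(ou_enabled=False)
        rng = np.random.default_rng(0)
        assert ou_step(1.3, params.dt, params, rng) == 0.0

    def test_stationary_moments_match_closed_form(self):
        params = SEMParams(ou_enabled=True, ou_sigma=0.5, ou_tau=0.02)
        rng = np.random.default_rng(1)
        v, samples = 0.0, []
        for _ in range(200_000):
            v = ou_step(v, params.dt, params, rng)
            samples.append(v)
        samples = np.asarray(samples[2000:])
        assert samples.mean() == pytest.approx(0.0, abs=0.02)
        assert samples.var() == pytest.approx(0.25, rel=0.1)


class TestCheckpoint:
    def test_state_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        circ = WTACircuit(4, 10, P, rng)
        path = tmp_path / "circuit.npz"
        circ.save(path)
        other = WTACircuit(4, 10, P, np.random.default_rng(99))
        other.restore(path)
        assert (other.weights == circ.weights).all()
        assert (other.excitability == circ.excitability).all()
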