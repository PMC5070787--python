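"""Logical voter-ensemble model: closed forms vs brute-force oracles and the
stochastic simulation."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semitdp import logical as L
from semitdp.synth import VoterFixtureSpec, make_voters

A = float(np.exp(5.0))


class TestJointEvents:
    @pytest.mark.parametrize(
        "p_m,p_g,expected",
        [
            (0.3, 0.6, (0.18, 0.54, 0.28)),
            (1.0, 1.0, (1.0, 0.0, 0.0)),
            (0.0, 0.7, (0.0, 0.7, 0.3)),
        ],
    )
    def test_values(self, p_m, p_g, expected):
        assert L.joint_event_probs(p_m, p_g) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(derandomize=True)
    def test_three_branches_sum_to_one(self, p_m, p_g):
        assert sum(L.joint_event_probs(p_m, p_g)) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            L.joint_event_probs(1.2, 0.5)


class TestPulseRule:
    def test_cofire_at_log_a_is_zero(self):
        assert L.logical_itdp_delta(np.log(7.0), True, True, 7.0) == pytest.approx(0.0)

    def test_single_fire_depresses_by_one(self):
        for w in (-3.0, 0.0, 4.0):
            assert L.logical_itdp_delta(w, True, False, A) == -1.0
            assert L.logical_itdp_delta(w, False, True, A) == -1.0

    def test_silence_leaves_weight(self):
        assert L.logical_itdp_delta(2.0, False, False, A) == 0.0

    @given(st.floats(-10, 10), st.floats(0.01, 1), st.floats(0.01, 1))
    @settings(derandomize=True)
    def test_expected_change_vanishes_at_equilibrium(self, w0, p_m, p_g):
        """E[dw] evaluated at the closed-form weight is 0 for any p_m p_g > 0."""
        w_star = L.equilibrium_weight(p_m, p_g, A)
        p_both, p_one, _ = L.joint_event_probs(p_m, p_g)
        e_dw = (A * np.exp(-w_star) - 1.0) * p_both - p_one
        assert e_dw == pytest.approx(0.0, abs=1e-9)


class TestEquilibriumWeight:
    def test_certain_cofiring(self):
        assert L.equilibrium_weight(1, 1, A) == pytest.approx(5.0)

    def test_a_equal_one_shift(self):
        assert L.equilibrium_weight(0.5, 0.5, 1.0) == pytest.approx(-np.log(3))

    def test_half_half(self):
        assert L.equilibrium_weight(0.5, 0.5, A) == pytest.approx(5 - np.log(3))

    def test_stochastic_iteration_oracle(self):
        """Long-run mean of the iterated pulse rule matches the closed form."""
        rng = np.random.default_rng(42)
        eta, p_m, p_g = 0.001, 0.5, 0.5
        w = 2.5
        n_burn, n_keep = 200_000, 800_000
        fires = rng.random((n_burn + n_keep, 2)) < (p_m, p_g)
        acc, count = 0.0, 0
        for i, (fm, fg) in enumerate(fires):
            if fm and fg:
                w += eta * (A * np.exp(-w) - 1.0)
            elif fm or fg:
                w -= eta
            if i >= n_burn:
                acc += w
                count += 1
        assert acc / count == pytest.approx(L.equilibrium_weight(p_m, p_g, A), abs=0.05)

    def test_zero_cofiring_floors(self):
        assert L.equilibrium_weight(0.0, 0.5, A) == L.WEIGHT_FLOOR


class TestEnsembleEquilibrium:
    def test_single_sample_all_ones(self):
        t = L.VoterTable(np.ones((1, 1)))
        g = L.VoterTable(np.ones((1, 1)))
        w = L.ensemble_equilibrium_weights([t], g, A)
        assert w.w == pytest.approx(np.log(A))

    def test_two_sample_hand_evaluation(self):
        """p(m) = (1, 0), p(g) = (1, 0) over two samples: co-firing only on
        sample 1 gives S_sum/S_prod - 1 = 1, hence w = log a."""
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        voters = [L.VoterTable(probs)]
        gate = L.VoterTable(probs)
        w = L.ensemble_equilibrium_weights(voters, gate, A)
        assert w.w[0, 0, 0] == pytest.approx(np.log(A))

    def test_matches_pooled_scalar_oracle(self, voter_fixture):
        """Entrywise equality with the scalar equilibrium applied to pooled
        statistics (brute-force summation oracle)."""
        voters, gate = voter_fixture
        w = L.ensemble_equilibrium_weights(voters, gate, A)
        n_c = gate.n_neurons
        for k in range(n_c):
            for i in range(n_c):
                for j in range(len(voters)):
                    pm = voters[j].probs[:, i]
                    pg = gate.probs[:, k]
                    s_prod = pm @ pg
                    s_sum = pm.sum() + pg.sum()
                    oracle = np.log(A) + np.log(s_prod / (s_sum - s_prod))
                    assert w.w[k, i, j] == pytest.approx(oracle)

    def test_divergent_entry_flagged_and_floored(self):
        voters = [L.VoterTable(np.array([[1.0, 0.0]]))]
        gate = L.VoterTable(np.array([[0.0, 1.0]]))
        w = L.ensemble_equilibrium_weights(voters, gate, A)
        assert not w.divergent[1, 0, 0]  # m_0 (p=1) co-fires with g_1 (p=1)
        assert w.divergent[0, 0, 0]  # g_0 never fires at all
        assert w.w[0, 0, 0] == L.WEIGHT_FLOOR


class TestStateEnumeration:
    def test_base_expansion_indexing(self):
        """For 4 voters' states read as quaternary digits, state 25 = '121'
        has the middle voter firing its third neuron (0-based index 2)."""
        r = L.state_index_table(4, 3)
        assert r[25, 1] == 2
        assert r.shape == (64, 3)
        # bijection: every digit string appears exactly once
        assert len({tuple(row) for row in r}) == 64

    def test_single_voter_returns_rows(self, voter_fixture):
        voters, _ = voter_fixture
        p = L.state_probability(3, voters[:1])
        assert p == pytest.approx(voters[0].probs[3])

    def test_uniform_voters_give_symmetric_states(self):
        t = L.VoterTable(np.full((2, 3), 1 / 3))
        p = L.state_probability(0, [t, t])
        assert p == pytest.approx(np.full(9, 1 / 9))

    def test_state_probabilities_sum_to_one(self, voter_fixture):
        voters, _ = voter_fixture
        for l in range(voters[0].n_samples):
            assert L.state_probability(l, voters).sum() == pytest.approx(1.0)


class TestExpectedFinalProbability:
    def test_equal_weights_give_uniform(self, voter_fixture):
        voters, gate = voter_fixture
        w = L.EnsembleWeights(np.ones((4, 4, 3)))
        for c in range(4):
            p = L.expected_final_probability(c, voters, w, gate.labels)
            assert p == pytest.approx(np.full(4, 0.25))

    def test_two_state_enumeration_oracle(self):
        """N_E=1, N_C=2: brute-force enumeration over both states."""
        probs = np.array([[0.8, 0.2], [0.3, 0.7]])
        labels = np.array([0, 1])
        voters = [L.VoterTable(probs, labels=labels)]
        w = L.EnsembleWeights(np.array([[[2.0], [-1.0]], [[-1.0], [2.0]]]))
        got = L.expected_final_probability(0, voters, w, labels)
        # state q: the single voter fires neuron q; u_k = w[k, q, 0]
        expected = np.zeros(2)
        for q in range(2):
            u = w.w[:, q, 0]
            soft = np.exp(u - u.max())
            soft /= soft.sum()
            expected += probs[0, q] * soft
        assert got == pytest.approx(expected)

    def test_normalised_over_final_neurons(self, voter_fixture):
        voters, gate = voter_fixture
        w = L.ensemble_equilibrium_weights(voters, gate, A)
        for c in range(4):
            p = L.expected_final_probability(c, voters, w, gate.labels)
            assert p.sum() == pytest.approx(1.0)

    def test_enumeration_cap(self, voter_fixture):
        voters, gate = voter_fixture
        w = L.ensemble_equilibrium_weights(voters, gate, A)
        with pytest.raises(L.IntractableEnumerationError):
            L.expected_final_probability(0, voters, w, gate.labels, state_cap=10)


class TestLearningPhase:
    def test_zero_rate_leaves_weights(self, voter_fixture):
        voters, gate = voter_fixture
        params = L.LogicalParams(eta=1e-300)
        w, _ = L.run_learning_phase(voters, gate, params, steps=500, rng_seed=1)
        assert w.w == pytest.approx(np.full_like(w.w, np.log(params.a) / 2), abs=1e-12)

    def test_round_robin_class_counts(self, voter_fixture):
        """After T = N_C * K steps every class was presented K times."""
        _, gate = voter_fixture
        n_c = gate.n_neurons
        counts = np.zeros(n_c)
        for t in range(1, 4 * n_c + 1):
            l = L._presentation_order(t, gate.labels, n_c)
            counts[gate.labels[l]] += 1
        assert counts == pytest.approx(np.full(n_c, 4.0))

    def test_trajectory_recording(self, voter_fixture):
        voters, gate = voter_fixture
        w, traj = L.run_learning_phase(
            voters, gate, L.LogicalParams(), steps=100, rng_seed=0, record_every=50
        )
        assert traj.shape == (2, 4, 4, 3)
        assert traj[-1] == pytest.approx(w.w)


class TestMeasuringPhase:
    def test_deterministic_voters_fire_gated_class(self):
        probs = np.eye(2)
        labels = np.array([0, 1])
        voters = [L.VoterTable(probs, labels=labels)]
        w = L.EnsembleWeights(np.array([[[30.0], [-30.0]], [[-30.0], [30.0]]]))
        freq, steps = L.run_measuring_phase(voters, w, 0, 200, labels, rng_seed=0)
        assert freq[0] == 1.0
        assert steps[:, 0] == pytest.approx(np.ones(200))

    def test_frequencies_match_enumeration_within_3se(self, voter_fixture):
        voters, gate = voter_fixture
        w = L.ensemble_equilibrium_weights(voters, gate, A)
        t_m = 3000
        for c in range(2):
            analytic = L.expected_final_probability(c, voters, w, gate.labels)
            freq, _ = L.run_measuring_phase(
                voters, w, c, t_m, gate.labels, rng_seed=c
            )
            se = np.sqrt(analytic * (1 - analytic) / t_m)
            assert np.all(np.abs(freq - analytic) <= 3 * se + 1e-9)


class TestVoterTableIO:
    def test_csv_round_trip(self, voter_fixture):
        voters, _ = voter_fixture
        buf = io.StringIO()
        voters[0].to_csv(buf)
        buf.seek(0)
        back = L.VoterTable.from_csv(buf)
        assert back.probs == pytest.approx(voters[0].probs)
        assert (back.labels == voters[0].labels).all()

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            L.VoterTable(np.array([[0.5, 0.4]]))
        with pytest.raises(ValueError):
            L.VoterTable(np.array([[1.5, -0.5]]))
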