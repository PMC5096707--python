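"""Linear-system simulators, ground-truth rank structure, controls, spikes."""

import numpy as np
import pytest

import prefmode as pm
from prefmode import (
    DegenerateDataError,
    InvalidInputError,
    LDSConfig,
    PopulationTensor,
)


class TestDynamicsMatrix:
    def test_orthogonal_with_unit_eigenvalues(self):
        a = pm.make_dynamics_matrix(20, seed=1)
        assert np.linalg.norm(a.T @ a - np.eye(20)) < 1e-10
        moduli = np.abs(np.linalg.eigvals(a))
        np.testing.assert_allclose(moduli, 1.0, atol=1e-10)

    def test_eigenvalue_angles_bounded(self):
        max_angle = 0.2
        a = pm.make_dynamics_matrix(10, max_rotation_angle=max_angle, seed=2)
        angles = np.abs(np.angle(np.linalg.eigvals(a)))
        assert np.all(angles <= max_angle + 1e-12)

    def test_odd_dimension_gets_unit_eigenvalue(self):
        a = pm.make_dynamics_matrix(7, seed=3)
        eigs = np.linalg.eigvals(a)
        assert np.any(np.abs(eigs - 1.0) < 1e-10)

    def test_small_angle_limit_trajectories_constant(self):
        a = pm.make_dynamics_matrix(6, max_rotation_angle=1e-9, seed=4)
        x = np.ones(6) / np.sqrt(6)
        traj = [x]
        for _ in range(50):
            traj.append(a @ traj[-1])
        assert np.max(np.abs(traj[-1] - traj[0])) < 1e-6

    def test_nonpositive_angle_rejected(self):
        with pytest.raises(InvalidInputError):
            pm.make_dynamics_matrix(4, max_rotation_angle=0.0)


class TestInputs:
    def test_channel_spans_limited_sinusoid_space(self):
        # each channel lives in the 2·n_sinusoids-dim sin/cos span
        u = pm.make_inputs(2, 10, 60, n_sinusoids=3, seed=5)
        for m in range(2):
            assert np.linalg.matrix_rank(u[m]) <= 6

    def test_deterministic_per_seed(self):
        u1 = pm.make_inputs(3, 4, 50, seed=6)
        u2 = pm.make_inputs(3, 4, 50, seed=6)
        np.testing.assert_array_equal(u1, u2)
        u3 = pm.make_inputs(3, 4, 50, seed=7)
        assert not np.array_equal(u1, u3)

    def test_condition_unfolding_rank_grows_then_saturates(self):
        # unconstrained-inputs premise: rank of the condition-mode unfolding
        # of U grows with the timespan until it saturates at C
        cfg = LDSConfig(a=0.0, b=1.0, n_conditions=15, n_timepoints=60, seed=8)
        tensor, truth = pm.simulate_lds(cfg)
        u_tensor = PopulationTensor.from_values(truth.inputs)
        ranks = [
            pm.numerical_rank(pm.unfold(u_tensor.window(0, ti - 1), "condition").values)
            for ti in (1, 11, 51)
        ]
        assert ranks[0] < ranks[1] <= ranks[2]
        assert ranks[2] == 15


class TestSimulateLds:
    def test_pure_dynamics_matches_matrix_power_oracle(self):
        cfg = LDSConfig(a=1.0, b=0.0, n_timepoints=80, seed=9)
        tensor, truth = pm.simulate_lds(cfg)
        expected = np.linalg.matrix_power(truth.A, 79) @ truth.initial_states
        np.testing.assert_allclose(
            tensor.values[:, :, -1], expected, rtol=1e-8, atol=1e-10
        )

    def test_pure_tuning_is_static_readout(self):
        cfg = LDSConfig(a=0.0, b=1.0, n_timepoints=40, seed=10)
        tensor, truth = pm.simulate_lds(cfg)
        np.testing.assert_allclose(
            tensor.values, np.einsum("nm,mct->nct", truth.B, truth.inputs), atol=1e-12
        )

    def test_presets_cover_canonical_strengths(self):
        settings = {name: (cfg.a, cfg.b) for name, cfg in
                    ((n, pm.preset_config(n)) for n in pm.PRESETS)}
        assert settings == {
            "fig8a": (0.0, 1.0),
            "fig8b": (0.98, 0.05),
            "fig8c": (0.99, 0.03),
            "fig8d": (1.0, 0.0),
        }

    def test_zero_strengths_rejected(self):
        with pytest.raises(DegenerateDataError):
            LDSConfig(a=0.0, b=0.0)

    def test_low_rank_preconditions_enforced(self):
        with pytest.raises(InvalidInputError):
            LDSConfig(a=0.0, b=1.0, n_inputs=20)  # tuning needs N > M
        with pytest.raises(InvalidInputError):
            LDSConfig(a=1.0, b=0.0, init_state_rank=20)  # dynamics needs r < N

    def test_b_has_orthonormal_columns(self):
        _, truth = pm.simulate_lds(LDSConfig(a=0.0, b=1.0, n_timepoints=30, seed=11))
        gram = truth.B.T @ truth.B
        np.testing.assert_allclose(gram, np.eye(truth.B.shape[1]), atol=1e-10)

    def test_initial_states_span_configured_rank(self):
        _, truth = pm.simulate_lds(LDSConfig(a=1.0, b=0.0, init_state_rank=6, seed=12))
        assert np.linalg.matrix_rank(truth.initial_states) == 6


class TestRankPremises:
    def test_tuning_neuron_rank_bounded_condition_rank_grows(self):
        cfg = LDSConfig(a=0.0, b=1.0, n_timepoints=150, seed=13)
        tensor, _ = pm.simulate_lds(cfg)
        r1, r2 = [], []
        for ti in (1, 11, 51, 150):
            sub = tensor.window(0, ti - 1)
            r1.append(pm.numerical_rank(pm.unfold(sub, "neuron").values))
            r2.append(pm.numerical_rank(pm.unfold(sub, "condition").values))
        assert max(r1) <= cfg.n_inputs  # bounded by M at every timespan
        assert r2[0] < r2[-1] == cfg.n_conditions  # grows, saturates at C

    def test_dynamics_condition_rank_stable_neuron_rank_grows(self):
        cfg = LDSConfig(a=1.0, b=0.0, n_timepoints=150, seed=13)
        tensor, _ = pm.simulate_lds(cfg)
        r1, r2 = [], []
        for ti in (1, 11, 51, 150):
            sub = tensor.window(0, ti - 1)
            r1.append(pm.numerical_rank(pm.unfold(sub, "neuron").values))
            r2.append(pm.numerical_rank(pm.unfold(sub, "condition").values))
        assert set(r2) == {cfg.init_state_rank}  # equals rank(X(1)) always
        assert r1[0] == cfg.init_state_rank and r1[-1] == cfg.n_neurons

    def test_time_varying_dynamics_keeps_condition_rank_stable(self):
        cfg = LDSConfig(a=1.0, b=0.0, time_varying=True, n_timepoints=100, seed=14)
        tensor, truth = pm.simulate_lds(cfg)
        assert truth.A is None and len(truth.A_sequence) == 99
        ranks = [
            pm.numerical_rank(pm.unfold(tensor.window(0, ti - 1), "condition").values)
            for ti in (1, 31, 100)
        ]
        assert set(ranks) == {cfg.init_state_rank}


class TestObservation:
    def test_full_observation_is_identity(self):
        tensor, _ = pm.simulate_lds(LDSConfig(a=1.0, b=0.0, n_timepoints=50, seed=15))
        out = pm.apply_observation(tensor, tensor.n_neurons)
        np.testing.assert_array_equal(out.values, tensor.values)

    def test_partial_observation_bounds_neuron_rank(self):
        tensor, _ = pm.simulate_lds(LDSConfig(a=1.0, b=0.0, n_timepoints=150, seed=15))
        out = pm.apply_observation(tensor, 3)
        assert pm.numerical_rank(pm.unfold(out, "neuron").values) <= 3

    def test_zero_observed_dims_rejected(self, random_tensor):
        with pytest.raises(InvalidInputError):
            pm.apply_observation(random_tensor, 0)


class TestControlDataset:
    def test_collapsed_mode_rank_bounded(self):
        tensor, _ = pm.simulate_lds(LDSConfig(a=0.0, b=1.0, n_timepoints=100, seed=16))
        ctrl = pm.make_control_dataset(tensor, "condition", 18, 6, seed=1)
        assert pm.numerical_rank(pm.unfold(ctrl, "condition").values) <= 6

    def test_refit_equals_orthogonal_projection(self, rng):
        tensor = PopulationTensor.from_values(rng.standard_normal((6, 6, 8)))
        ctrl = pm.make_control_dataset(tensor, "neuron", 4, 2, seed=2)
        # least-squares refit residual == projection residual: the collapsed
        # data must be the projection of each row of the unfolding, i.e.
        # projecting again changes nothing and residual ⟂ collapsed span
        unf = pm.unfold(tensor, "neuron").values
        unf_ctrl = pm.unfold(ctrl, "neuron").values
        resid = unf - unf_ctrl
        assert np.abs(resid @ unf_ctrl.T).max() < 1e-10

    def test_indivisible_partition_rejected(self, random_tensor):
        with pytest.raises(InvalidInputError):
            pm.make_control_dataset(random_tensor, "neuron", 4, 3, seed=0)

    def test_condition_collapse_flips_tuning_verdict(self):
        tensor, _ = pm.simulate_lds(LDSConfig(a=0.0, b=1.0, n_timepoints=150, seed=17))
        assert pm.mode_preference(tensor, pm.select_k(tensor)).preferred == "neuron"
        ctrl = pm.make_control_dataset(tensor, "condition", 18, 6, seed=3)
        assert pm.mode_preference(ctrl, pm.select_k(ctrl)).preferred == "condition"


class TestSubsampleConditions:
    def test_full_subsample_is_identity(self, random_tensor):
        out = pm.subsample_conditions(random_tensor, random_tensor.n_conditions, seed=0)
        np.testing.assert_array_equal(out.values, random_tensor.values)
        assert out.condition_ids == random_tensor.condition_ids

    def test_ids_are_distinct_subset(self, rng):
        tensor = PopulationTensor.from_values(rng.standard_normal((4, 10, 6)))
        out = pm.subsample_conditions(tensor, 5, seed=1)
        assert len(set(out.condition_ids)) == 5
        assert set(out.condition_ids) <= set(tensor.condition_ids)

    def test_dynamics_verdict_robust_to_condition_count(self):
        base, _ = pm.simulate_lds(
            LDSConfig(a=1.0, b=0.0, n_conditions=72, n_timepoints=150, seed=18)
        )
        for n in (10, 20, 30):
            for seed in range(3):
                sub = pm.subsample_conditions(base, n, seed=seed)
                verdict = pm.mode_preference(sub, pm.select_k(sub))
                assert verdict.preferred == "condition"

    def test_out_of_range_rejected(self, random_tensor):
        with pytest.raises(InvalidInputError):
            pm.subsample_conditions(random_tensor, 0)


class TestSimulateSpikes:
    def test_zero_rate_emits_no_spikes(self):
        rates = PopulationTensor.from_values(
            np.zeros((2, 2, 11)), time_ms=np.arange(11) * 10.0
        )
        spikes = pm.simulate_spikes(rates, 5, seed=0)
        assert all(
            ev.size == 0
            for per_n in spikes.spike_times
            for per_c in per_n
            for ev in per_c
        )

    def test_constant_rate_mean_count(self):
        rates = PopulationTensor.from_values(
            np.full((1, 1, 101), 50.0), time_ms=np.arange(101) * 10.0
        )
        spikes = pm.simulate_spikes(rates, 1000, seed=1)
        counts = [len(ev) for ev in spikes.spike_times[0][0]]
        assert np.mean(counts) == pytest.approx(50.0, abs=3 * np.sqrt(50.0 / 1000))

    def test_deterministic_per_seed(self):
        rates = PopulationTensor.from_values(
            np.full((1, 1, 21), 20.0), time_ms=np.arange(21) * 10.0
        )
        s1 = pm.simulate_spikes(rates, 3, seed=7)
        s2 = pm.simulate_spikes(rates, 3, seed=7)
        for r in range(3):
            np.testing.assert_array_equal(
                s1.spike_times[0][0][r], s2.spike_times[0][0][r]
            )

    def test_negative_rates_rejected(self, random_tensor):
        with pytest.raises(InvalidInputError):
            pm.simulate_spikes(random_tensor, 1, seed=0)
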