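import numpy as np
import pytest

from orthospace.generator import (
    GeneratorParams,
    Timeline,
    emit_rates,
    emit_spikes,
    gate_signal,
    make_loading,
    make_scenario,
    make_targets,
    simulate_latents,
)


class TestTargets:
    def test_eight_radial_targets_at_130mm(self):
        t = make_targets(8, 130.0)
        assert t.shape == (2, 8)
        np.testing.assert_allclose(np.linalg.norm(t, axis=0), 130.0)
        angles = np.arctan2(t[1], t[0])
        np.testing.assert_allclose(np.diff(angles[:5]), np.pi / 4, atol=1e-12)
        # balanced: radial targets sum to zero
        np.testing.assert_allclose(t.sum(axis=1), 0.0, atol=1e-9)

    def test_single_target_on_positive_axis(self):
        np.testing.assert_allclose(make_targets(1, 130.0), [[130.0], [0.0]])

    def test_four_targets_are_axis_points(self):
        t = make_targets(4, 130.0)
        np.testing.assert_allclose(
            t, [[130, 0, -130, 0], [0, 130, 0, -130]], atol=1e-12
        )

    def test_zero_conditions_rejected(self):
        with pytest.raises(ValueError):
            make_targets(0)


class TestLatentDynamics:
    def test_gate_closed_state_converges_to_input_fixed_point(self):
        # keep the gate at zero by pushing its onset beyond the simulation
        tl = Timeline(go_cue_ms=10_000.0, move_onset_ms=10_000.0, end_ms=3000.0)
        params = GeneratorParams(seed=0, targets=make_targets(3))
        lat = simulate_latents(params, tl)
        fixed = -np.linalg.inv(params.J_prep) @ params.targets
        np.testing.assert_allclose(lat.x_prep[:, :, -1], fixed, rtol=1e-3)
        assert np.all(lat.x_move == 0.0)

    def test_zero_input_keeps_all_latents_at_zero(self):
        params = GeneratorParams(seed=0, targets=np.zeros((2, 4)))
        lat = simulate_latents(params)
        assert np.all(lat.x == 0.0)

    def test_movement_latents_silent_before_go_cue(self, gen_latents):
        t = gen_latents.time_ms
        pre_go = t < gen_latents.timeline.go_cue_ms
        peak_prep = np.abs(gen_latents.x_prep).max()
        assert np.abs(gen_latents.x_move[:, :, pre_go]).max() <= 1e-6 * peak_prep

    def test_movement_state_is_linear_image_of_pre_go_state(self, gen_params):
        """The system is linear with condition-independent gates, so the
        post-go movement state at any time is one fixed linear map of the
        pre-go preparatory state, across all conditions."""
        lat = simulate_latents(gen_params)
        t = lat.time_ms
        x0 = lat.x_prep[:, :, t == 500.0][:, :, 0]
        scale = np.abs(lat.x_move).max()
        for probe in (700.0, 800.0, 900.0):
            xm = lat.x_move[:, :, t == probe][:, :, 0]
            w = xm @ np.linalg.pinv(x0)
            np.testing.assert_allclose(w @ x0 / scale, xm / scale, atol=1e-3)

    def test_movement_trajectory_rotates_with_near_constant_radius(self, gen_latents):
        """Late in the trial the oscillator traces an ellipse: the radius of
        the (rescaled) movement trajectory stays nearly constant while the
        phase advances steadily."""
        t = gen_latents.time_ms
        late = t >= 800.0
        xy = gen_latents.x_move[:, 0, late]
        radius = np.hypot(xy[0], xy[1])
        assert radius.std() / radius.mean() < 0.05
        phase = np.unwrap(np.arctan2(xy[1], xy[0]))
        steps = np.diff(phase)
        assert np.all(np.abs(steps) > 0.1)  # ~0.157 rad per 10 ms at 2.5 Hz
        assert np.all(np.sign(steps) == np.sign(steps[0]))

    def test_preparatory_spread_decays_after_input_gated_off(self, gen_latents):
        t = gen_latents.time_ms
        post = t >= 700.0
        spread = gen_latents.x_prep[:, :, post].std(axis=1).sum(axis=0)
        assert np.all(np.diff(spread) < 0)

    def test_gate_is_monotone_in_unit_interval_and_zero_before_go(self, gen_params):
        tl = Timeline()
        t = np.arange(0.0, 950.0, 1.0)
        g = gate_signal(t, gen_params, tl)
        assert np.all((g >= 0) & (g <= 1))
        assert np.all(np.diff(g) >= 0)
        assert np.all(g[t < tl.go_cue_ms] == 0.0)
        assert g[t == 640.0] > 0.999

    def test_divergent_integration_raises(self):
        params = GeneratorParams(seed=0, J_move=np.array([[0.0, 5.0], [-5.0, 0.0]]))
        with pytest.raises(FloatingPointError, match="dt"):
            simulate_latents(params, Timeline(end_ms=5000.0))

    def test_unstable_j_prep_rejected(self):
        with pytest.raises(ValueError, match="leaky"):
            GeneratorParams(seed=0, J_prep=np.eye(2) / 100)


class TestRateEmission:
    def test_identity_loading_returns_latents(self, gen_latents):
        params = GeneratorParams(seed=0, n_neurons=4)
        resp = emit_rates(gen_latents, params, loading=np.eye(4))
        np.testing.assert_array_equal(resp.rates, gen_latents.x)

    def test_seeded_loading_is_reproducible(self, gen_latents):
        params = GeneratorParams(seed=42)
        a = emit_rates(gen_latents, params)
        b = emit_rates(gen_latents, params)
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_rate_variance_scales_with_squared_loading_sd(self, gen_latents):
        v = []
        for sd in (50.0, 25.0):
            accum = 0.0
            for seed in range(8):
                params = GeneratorParams(seed=seed, loading_sd=sd)
                accum += emit_rates(gen_latents, params).rates.var()
            v.append(accum / 8)
        assert v[0] / v[1] == pytest.approx(4.0, rel=0.15)

    def test_shape_mismatch_rejected(self, gen_latents):
        params = GeneratorParams(seed=0)
        with pytest.raises(ValueError, match="columns"):
            emit_rates(gen_latents, params, loading=np.ones((10, 3)))


class TestSpikeEmission:
    def constant_response(self, rate):
        from orthospace.population import PopulationResponse

        return PopulationResponse(
            rates=np.full((1, 1, 101), rate),
            time_ms=np.arange(101) * 10.0,
            events={"target_onset_ms": 0, "go_cue_ms": 0, "move_onset_ms": 0},
        )

    def test_zero_rate_emits_no_spikes(self):
        trains = emit_spikes(self.constant_response(0.0), n_trials=5, seed=0)
        assert all(len(t) == 0 for t in trains.trials[(0, 0)])

    def test_poisson_mean_count_within_sem(self):
        trains = emit_spikes(self.constant_response(100.0), n_trials=1000, seed=1)
        counts = np.array([len(t) for t in trains.trials[(0, 0)]])
        sem = np.sqrt(100.0 / 1000)
        assert abs(counts.mean() - 100.0) < 3 * sem

    def test_doubling_rate_doubles_counts(self):
        c1 = np.mean([len(t) for t in
                      emit_spikes(self.constant_response(40.0), 500, seed=2).trials[(0, 0)]])
        c2 = np.mean([len(t) for t in
                      emit_spikes(self.constant_response(80.0), 500, seed=3).trials[(0, 0)]])
        assert c2 / c1 == pytest.approx(2.0, rel=0.1)

    def test_negative_rates_rejected(self, gen_response):
        with pytest.raises(ValueError, match="non-negative"):
            emit_spikes(gen_response, n_trials=1, seed=0)


class TestScenarios:
    def test_overlapping_epochs_share_top2_eigenspace(self, scenario_fixture):
        from orthospace.alignment import epoch_pcs
        from orthospace.population import (
            MOVEMENT_EPOCH, PREPARATORY_EPOCH, extract_epoch, preprocess,
        )

        resp, truth = scenario_fixture["overlapping"]
        pre = preprocess(resp)
        prep = extract_epoch(pre, PREPARATORY_EPOCH)
        move = extract_epoch(pre, MOVEMENT_EPOCH)
        qp = epoch_pcs(prep.covariance, 2).vectors
        qm = epoch_pcs(move.covariance, 2).vectors
        cos = np.linalg.svd(qp.T @ qm, compute_uv=False)
        angles = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert angles.max() < 1e-4

    def test_orthogonal_linked_planted_planes_are_orthogonal(self, scenario_fixture):
        _, truth = scenario_fixture["orthogonal_linked"]
        overlap = truth["Q_prep"].T @ truth["Q_move"]
        assert np.abs(overlap).max() < 1e-10

    def test_independent_scrambles_condition_order(self):
        """Across random draws the movement-epoch condition assignment is a
        (usually non-trivial) permutation of the linked scenario's."""
        nontrivial = 0
        for seed in range(12):
            _, truth = make_scenario("independent", GeneratorParams(seed=seed))
            perm = truth["condition_permutation"]
            nontrivial += not np.array_equal(perm, np.arange(perm.size))
        assert nontrivial >= 10

    def test_unknown_scenario_rejected(self, gen_params):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_scenario("sideways", gen_params)

    def test_raw_gaussian_loading_when_orthogonalize_off(self):
        params = GeneratorParams(seed=5)
        _, truth = make_scenario("orthogonal_linked", params, orthogonalize=False)
        # planes nearly but not exactly orthogonal
        loading = make_loading(params, np.random.default_rng(params.seed))
        q = np.linalg.qr(loading[:, :2])[0]
        overlap = np.abs(q.T @ loading[:, 2:]).max()
        col_norm = np.linalg.norm(loading[:, 2:], axis=0).min()
        assert 0 < overlap < 0.3 * col_norm
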