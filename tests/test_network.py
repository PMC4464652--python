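"""Network core: dynamics, clamping, early stopping, error, BPTT."""

import dataclasses

import numpy as np
import pytest
from scipy.special import logit

import overshadow as ov
from overshadow.network import NonFiniteStateError

from conftest import make_micro_weights


def run_free_trial(weights, phases, params=None):
    spec = ov.TrialSpec(task="visual_recognition", phases=phases)
    return ov.run_trial(spec, weights, params or weights.params, rng=None)


class TestConnectivity:
    def test_constant_units_disconnected_varying_connected(self, stimulus_set):
        mask = ov.derive_connectivity(stimulus_set)
        # background pixels are white in all 64 images -> disconnected
        always_white = np.flatnonzero(stimulus_set.images.max(axis=0) == 0)
        assert not mask.visual[always_white].any()
        varying = np.flatnonzero(np.ptp(stimulus_set.images, axis=0) > 0)
        assert mask.visual[varying].all()

    def test_all_six_verbal_units_connected(self, stimulus_set):
        mask = ov.derive_connectivity(stimulus_set)
        assert mask.verbal.all() and mask.verbal.size == 6

    def test_two_item_set_differing_in_one_pixel(self, stimulus_set):
        sub = ov.subset_stimulus_set(stimulus_set, [0, 1])
        img = sub.images.copy()
        img[1] = img[0]
        flip = 17
        img[1, flip] = 1 - img[0, flip]
        sub.images = img
        sub.retinotopic = img.astype(float)
        mask = ov.derive_connectivity(sub)
        assert np.flatnonzero(mask.visual).tolist() == [flip]
        assert np.flatnonzero(mask.retinotopic).tolist() == [flip]


class TestInitialization:
    def test_same_seed_reproduces_weights(self, stimulus_set):
        mask = ov.derive_connectivity(stimulus_set)
        params = ov.NetworkParams()
        w1 = ov.init_network(params, mask, 9)
        w2 = ov.init_network(params, mask, 9)
        assert np.array_equal(w1.W_ph, w2.W_ph)
        assert np.array_equal(w1.b_p, w2.b_p)

    def test_zero_range_gives_zero_weights(self, stimulus_set):
        mask = ov.derive_connectivity(stimulus_set)
        params = ov.NetworkParams(init_weight_range=0.0)
        w = ov.init_network(params, mask, 0)
        assert not w.W_ph.any() and not w.W_hp.any()

    def test_weights_allocated_only_for_connected_units(self, stimulus_set):
        mask = ov.derive_connectivity(stimulus_set)
        w = ov.init_network(ov.NetworkParams(), mask, 0)
        assert w.W_ph.shape[0] == mask.n_connected
        assert w.W_hp.shape == (20, mask.n_connected)

    def test_checkpoint_round_trip_bit_exact(self, stimulus_set, tmp_path):
        mask = ov.derive_connectivity(stimulus_set)
        w = ov.init_network(ov.NetworkParams(), mask, 4)
        w.save(tmp_path / "ckpt.npz")
        back = ov.WeightSet.load(tmp_path / "ckpt.npz")
        assert np.array_equal(back.W_ph, w.W_ph)
        assert np.array_equal(back.W_hp, w.W_hp)
        assert np.array_equal(back.b_h, w.b_h)
        assert back.params == w.params


class TestDynamics:
    def test_net_input_single_step_moves_one_tenth_toward_input(self):
        # hidden receives a constant summed input of 1 from a clamped unit
        w = make_micro_weights(n_h=1)
        w.W_ph[0, 0] = 1.0
        clamp = ov.ClampSpec("retinotopic", "hard", np.array([1.0, 0.0]))
        traj = run_free_trial(w, [ov.Phase(1, clamps=[clamp])])
        assert traj.s_h[1, 0] == pytest.approx(0.1, abs=1e-12)

    def test_net_input_converges_geometrically_with_ratio_09(self):
        w = make_micro_weights(n_h=1)
        w.W_ph[0, 0] = 1.0
        clamp = ov.ClampSpec("retinotopic", "hard", np.array([1.0, 0.0]))
        traj = run_free_trial(w, [ov.Phase(10, clamps=[clamp])])
        assert traj.s_h[10, 0] == pytest.approx(1.0 - 0.9**10, abs=1e-12)
        # geometric approach: the residual shrinks by 0.9 each cycle
        resid = 1.0 - traj.s_h[1:, 0]
        assert np.allclose(resid[1:] / resid[:-1], 0.9)

    def test_soft_clamp_is_a_convex_combination(self):
        # verbal unit resting at activation 0.2 pulled halfway to external 1.0
        w = make_micro_weights()
        w.b_p[w.slices["verbal"]][0] = logit(0.2)
        state = (
            np.full(w.n_p, 0.0),
            np.zeros(w.n_h),
            np.full(w.n_p, 0.5),
            np.full(w.n_h, 0.5),
        )
        state[0][w.slices["verbal"].start] = logit(0.2)
        clamp = ov.ClampSpec(
            "verbal", "soft", np.array([1.0, 0.0]), unit_mask=np.array([True, False])
        )
        s_p, s_h, a_p, a_h = ov.step_activations(state, w, [clamp], w.params)
        assert a_p[w.slices["verbal"].start] == pytest.approx(0.2 + 0.5 * 0.8, abs=1e-12)

    def test_unclamped_activations_strictly_inside_unit_interval(self, micro_gradient):
        traj = ov.run_trial(micro_gradient.trial, micro_gradient.weights, micro_gradient.params)
        free = traj.dadz_p[1:] == 1.0
        vals = traj.a_p[1:][free]
        assert np.all(vals > 0) and np.all(vals < 1)

    def test_hard_clamped_layer_matches_external_input_every_cycle(self, stimulus_set):
        mask = ov.derive_connectivity(stimulus_set)
        w = ov.init_network(ov.NetworkParams(), mask, 0)
        ext = stimulus_set.retinotopic[3]
        clamp = ov.ClampSpec("retinotopic", "hard", ext)
        traj = run_free_trial(w, [ov.Phase(10, clamps=[clamp])])
        packed = ext[mask.retinotopic]
        for t in range(0, 11):
            assert np.array_equal(traj.a_p[t, w.slices["retinotopic"]], packed)

    def test_non_finite_state_reports_cycle(self):
        w = make_micro_weights(n_h=1)
        w.W_ph[:, 0] = 1e308  # summed input overflows to inf
        clamp = ov.ClampSpec("retinotopic", "hard", np.array([1.0, 0.0]))
        with np.errstate(over="ignore"), pytest.raises(NonFiniteStateError) as exc:
            run_free_trial(w, [ov.Phase(10, clamps=[clamp])])
        assert exc.value.cycle == 1


class TestTrialStructure:
    def test_no_target_runs_all_ten_cycles(self):
        w = make_micro_weights()
        traj = run_free_trial(w, [ov.Phase(10)])
        assert traj.stop_cycle == 10

    def test_outputs_within_half_of_target_stop_the_phase_early(self):
        # zero weights hold outputs at 0.5; a 0.6 target is inside the 0.5
        # band, so the phase ends at the earliest cycle the stop test runs
        w = make_micro_weights()
        phase = ov.Phase(10, target_layer="visual", target=np.array([0.6, 0.4]))
        traj = run_free_trial(w, [phase])
        assert traj.stop_cycle == w.params.early_stop_min_cycle

    def test_stop_test_waits_for_input_to_reach_the_output_layer(self):
        # external input needs two cycles (input -> hidden -> output); the
        # stop test never fires before the configured floor
        w = make_micro_weights(early_stop_min_cycle=5)
        phase = ov.Phase(10, target_layer="visual", target=np.array([0.6, 0.4]))
        traj = run_free_trial(w, [phase])
        assert traj.stop_cycle == 5

    def test_binary_targets_not_reached_do_not_stop(self):
        w = make_micro_weights()
        phase = ov.Phase(10, target_layer="visual", target=np.array([1.0, 0.0]))
        traj = run_free_trial(w, [phase])
        assert traj.stop_cycle == 10

    def test_two_phase_trial_carries_state_across_the_boundary(self, stimulus_set):
        mask = ov.derive_connectivity(stimulus_set)
        w = ov.init_network(ov.NetworkParams(), mask, 1)
        verbal = np.zeros(6)
        verbal[[0, 2, 4]] = 1.0
        p1 = ov.Phase(10, clamps=[ov.ClampSpec("verbal", "soft", verbal, unit_mask=verbal > 0)], early_stop=False)
        p2 = ov.Phase(10, clamps=[ov.ClampSpec("retinotopic", "hard", stimulus_set.retinotopic[0])], early_stop=False)
        traj = ov.run_trial(ov.TrialSpec("recognition_after_verbalization", [p1, p2]), w)
        assert traj.phase_stop == [10, 20]
        assert traj.a_p.shape[0] == 21
        # no reset: hidden net input is continuous across the boundary
        assert np.any(traj.s_h[10] != 0)
        step = np.abs(np.diff(traj.s_h, axis=0))
        assert step[10].max() <= np.abs(traj.s_h).max()  # bounded move, not a reset

    def test_clamp_and_phase_validation(self):
        with pytest.raises(ValueError):
            ov.ClampSpec("hidden", "hard", np.zeros(3))
        with pytest.raises(ValueError):
            ov.ClampSpec("verbal", "medium", np.zeros(6))
        with pytest.raises(ValueError):
            ov.Phase(5, target_layer="visual", target=None)


class TestError:
    def test_perfect_output_has_zero_error_and_gradient(self):
        err, grad = ov.compute_error(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        assert err == pytest.approx(0.0, abs=1e-5)
        assert np.all(grad == 0)

    def test_zero_error_radius_suppresses_near_target_gradients(self):
        err, grad = ov.compute_error(np.array([0.95]), np.array([1.0]), zero_error_radius=0.1)
        assert grad[0] == 0.0
        assert err > 0

    def test_cross_entropy_value_at_half(self):
        err, grad = ov.compute_error(np.array([0.5]), np.array([1.0]))
        assert err == pytest.approx(np.log(2), rel=1e-9)
        assert grad[0] == pytest.approx(-0.5)


class TestBptt:
    @pytest.mark.parametrize("schedule", ["final_cycle", "every_cycle"])
    def test_gradients_match_central_finite_differences(self, schedule):
        inst = ov.make_micro_instance("gradient_check", 3)
        params = dataclasses.replace(inst.params, error_schedule=schedule)
        w = inst.weights
        trial = inst.trial

        def loss():
            traj = ov.run_trial(trial, w, params)
            total = 0.0
            for p_i, ph in enumerate(trial.phases):
                sl = w.slices[ph.target_layer]
                tgt = np.asarray(ph.target)[w.mask.mask_for(ph.target_layer)]
                cyc = (
                    [traj.phase_stop[p_i]]
                    if schedule == "final_cycle"
                    else np.flatnonzero(traj.phase_of_cycle == p_i)
                )
                for t in cyc:
                    a = np.clip(traj.a_p[t, sl], params.eps, 1 - params.eps)
                    total += float(-np.sum(tgt * np.log(a) + (1 - tgt) * np.log(1 - a)))
            return total

        traj = ov.run_trial(trial, w, params)
        grads = ov.bptt_gradients(traj, w, params)[:4]
        h = 1e-5
        for g, arr in zip(grads, (w.W_ph, w.W_hp, w.b_h, w.b_p)):
            for idx in np.ndindex(arr.shape):
                orig = arr[idx]
                arr[idx] = orig + h
                lp = loss()
                arr[idx] = orig - h
                lm = loss()
                arr[idx] = orig
                fd = (lp - lm) / (2 * h)
                # the 1e-3 floor covers finite-difference roundoff near zero
                rel = abs(fd - g[idx]) / max(abs(fd), abs(g[idx]), 1e-3)
                assert rel <= 1e-6

    def test_zero_gradient_leaves_only_the_decay_term(self):
        w = make_micro_weights()
        w.W_ph += 0.2
        before = w.W_ph.copy()
        # no target phase -> zero error gradient everywhere
        traj = run_free_trial(w, [ov.Phase(3)])
        ov.apply_bptt_update(traj, w)
        expected = before - w.params.weight_decay * before
        assert np.allclose(w.W_ph, expected, atol=1e-15)

    def test_update_is_independent_of_previous_updates_with_zero_momentum(self, micro_gradient):
        inst = micro_gradient
        w1 = inst.weights.copy()
        w2 = inst.weights.copy()
        # w2 takes a detour trial first; with momentum 0 the second update
        # from identical weights would still match w1's, so instead verify
        # directly: same weights + same trial -> same update, no history kept
        traj1 = ov.run_trial(inst.trial, w1, inst.params)
        ov.apply_bptt_update(traj1, w1, inst.params)
        traj2 = ov.run_trial(inst.trial, w2, inst.params)
        ov.apply_bptt_update(traj2, w2, inst.params)
        assert np.array_equal(w1.W_ph, w2.W_ph)
        assert w1._velocity is None
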