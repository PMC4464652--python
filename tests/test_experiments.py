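"""Verbalization conditions, paired statistics, and the single-trial lineup."""

import numpy as np
import pytest
from scipy import stats

import overshadow as ov
from overshadow.experiments import CONDITIONS, validate_selection


def result_with(accs):
    accs = np.asarray(accs, dtype=float)
    return ov.ConditionResult(
        name="x", hit_rates=accs, cr_rates=accs, accuracies=accs, distributions=[]
    )


class TestVerbalSelection:
    @pytest.fixture
    def verbal(self):
        v = np.zeros(6, dtype=np.uint8)
        v[[0, 3, 4]] = 1  # drooping eyes, button nose, thick lips
        return v

    def test_consistent_selects_the_items_own_labels(self, verbal):
        units = ov.selected_verbal_units(verbal, "consistent")
        assert sorted(units) == [0, 3, 4]

    def test_inconsistent_flips_within_each_pair(self, verbal):
        units = ov.selected_verbal_units(verbal, "inconsistent")
        assert sorted(units) == [1, 2, 5]

    def test_graded_extremes_match_the_named_rules(self, verbal):
        rng = np.random.default_rng(0)
        assert sorted(ov.selected_verbal_units(verbal, 3, rng)) == [0, 3, 4]
        assert sorted(ov.selected_verbal_units(verbal, 0, rng)) == [1, 2, 5]

    def test_graded_k_selects_exactly_k_correct_features(self, verbal):
        rng = np.random.default_rng(1)
        for k in (1, 2):
            for _ in range(10):
                units = ov.selected_verbal_units(verbal, k, rng)
                n_correct = len(set(units) & {0, 3, 4})
                assert n_correct == k
                validate_selection(units)

    def test_two_units_in_one_pair_rejected(self):
        with pytest.raises(ValueError):
            validate_selection(np.array([0, 1, 4]))

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            ov.ConditionSpec("bad", "sometimes", "none")


class TestConditionTrials:
    def test_control_is_a_single_recognition_phase(self, stimulus_set):
        params = ov.NetworkParams()
        trial = ov.condition_trial(0, None, False, stimulus_set, params)
        assert len(trial.phases) == 1
        assert trial.phases[0].clamps[0].layer == "retinotopic"

    @pytest.mark.parametrize("maintain", [True, False])
    def test_verbal_clamp_maintained_or_removed_at_recognition(self, stimulus_set, maintain):
        params = ov.NetworkParams()
        units = np.array([0, 2, 4])
        trial = ov.condition_trial(0, units, maintain, stimulus_set, params)
        assert len(trial.phases) == 2
        p1, p2 = trial.phases
        assert [c.layer for c in p1.clamps] == ["verbal"]
        layers = [c.layer for c in p2.clamps]
        assert "retinotopic" in layers
        assert ("verbal" in layers) == maintain
        assert not p1.early_stop and not p2.early_stop


class TestPairedT:
    def test_matches_closed_form_oracle(self):
        control = result_with([0.65, 0.60, 0.70, 0.65, 0.65])
        cond = result_with([0.50, 0.50, 0.50, 0.50, 0.50])
        diffs = control.accuracies - cond.accuracies
        t_oracle = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(diffs.size))
        t, df, p = ov.paired_t_vs_control(cond, control)
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert df == 4
        assert p == pytest.approx(2 * stats.t.sf(abs(t_oracle), 4), abs=1e-12)

    def test_identical_accuracies_give_t_zero_p_one(self):
        a = result_with([0.6, 0.7, 0.65])
        t, df, p = ov.paired_t_vs_control(a, result_with([0.6, 0.7, 0.65]))
        assert t == 0.0 and p == 1.0 and df == 2

    def test_constant_nonzero_difference_reports_signed_infinity(self):
        control = result_with([0.6, 0.7, 0.65, 0.6, 0.7])
        cond = result_with([0.5, 0.6, 0.55, 0.5, 0.6])
        t, df, p = ov.paired_t_vs_control(cond, control)
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            ov.paired_t_vs_control(result_with([0.5]), result_with([0.5, 0.6]))


class TestLineup:
    def test_disjoint_distributions_always_pick_the_target(self):
        canned = ov.make_micro_instance("overlap_distributions", 0, overlap=0.0)
        res = ov.single_trial_lineup(canned.old, canned.new, n_distractors=7, repetitions=500, seed=1)
        assert res.proportion_correct == 1.0

    def test_exchangeable_samples_approach_one_over_n_plus_one(self):
        """With old and new item polarities drawn from one distribution, the
        target wins the 8-alternative lineup with probability 1/8.

        A single finite item pool biases the proportion toward its own
        realized order statistics (the item-differences effect), so the
        exchangeability prediction is checked across fresh pools, 100k
        lineup trials in total.
        """
        rng = np.random.default_rng(12)
        n_pools, reps_per_pool = 500, 200
        means = []
        for k in range(n_pools):
            pool = rng.normal(0.8, 0.05, size=64)
            res = ov.single_trial_lineup(
                pool[:32], pool[32:], n_distractors=7, repetitions=reps_per_pool, seed=1000 + k
            )
            means.append(res.proportion_correct)
        means = np.array(means)
        est = means.mean()
        se = means.std(ddof=1) / np.sqrt(n_pools)
        assert abs(est - 1.0 / 8.0) <= 2 * se

    def test_too_many_distractors_rejected(self):
        with pytest.raises(ValueError):
            ov.single_trial_lineup(np.ones(3), np.zeros(3), n_distractors=4, repetitions=10, seed=0)

    def test_ties_count_as_failures(self):
        res = ov.single_trial_lineup(
            np.full(4, 0.5), np.full(4, 0.5), n_distractors=2, repetitions=200, seed=3
        )
        assert res.proportion_correct == 0.0
        assert res.n_ties == 200


@pytest.fixture(scope="module")
def resting_model(stimulus_set):
    # zero weights: every layer rests at 0.5, polarity identically 0
    params = ov.NetworkParams(init_weight_range=0.0)
    mask = ov.derive_connectivity(stimulus_set)
    return ov.init_network(params, mask, 0)


class TestRunCondition:
    def test_distribution_covers_all_items_with_the_old_new_split(
        self, resting_model, stimulus_set
    ):
        from overshadow.experiments import CONDITIONS, measure_condition

        dist = measure_condition(resting_model, stimulus_set, CONDITIONS["similar"], 0)
        assert len(dist.samples) == 64
        assert dist.old_values.size == 32 and dist.new_values.size == 32
        # a resting network is maximally uncertain about every face
        assert np.allclose(dist.old_values, 0.0, atol=1e-9)

    def test_rerun_is_deterministic(self, resting_model, stimulus_set):
        spec = ov.ConditionSpec("graded_k1", 1, 1, maintain=True)
        a = ov.measure_condition(resting_model, stimulus_set, spec, 0, seed=3)
        b = ov.measure_condition(resting_model, stimulus_set, spec, 0, seed=3)
        assert [s.mean_polarity for s in a.samples] == [s.mean_polarity for s in b.samples]

    def test_one_sample_t_against_chance(self):
        res = result_with([0.6, 0.7, 0.65, 0.6, 0.7])
        t, df, p = ov.one_sample_t_vs_chance(res)
        a = np.array([0.6, 0.7, 0.65, 0.6, 0.7])
        t_oracle = (a.mean() - 0.5) / (a.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert df == 4


class TestGradedEquivalences:
    def test_k3_and_k0_reproduce_similar_and_irrelevant_unit_choices(self, stimulus_set):
        """k=3 correct equals the consistent (similar) clamp; k=0 equals the
        within-pair-opposite (irrelevant/dissimilar-new) clamp."""
        rng = np.random.default_rng(0)
        for i in (0, 13, 40):
            v = stimulus_set.verbal[i]
            assert sorted(ov.selected_verbal_units(v, 3, rng)) == sorted(
                ov.selected_verbal_units(v, "consistent")
            )
            assert sorted(ov.selected_verbal_units(v, 0, rng)) == sorted(
                ov.selected_verbal_units(v, "inconsistent")
            )

    def test_named_conditions_are_configured_as_specified(self):
        assert CONDITIONS["similar"].maintain is True
        assert CONDITIONS["similar"].old_rule == "consistent" == CONDITIONS["similar"].new_rule
        assert CONDITIONS["dissimilar"].new_rule == "inconsistent"
        assert CONDITIONS["dissimilar"].maintain is True
        assert CONDITIONS["irrelevant"].maintain is False
        assert CONDITIONS["irrelevant"].old_rule == "inconsistent"
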