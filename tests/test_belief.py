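import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_dg
from socialrl.belief import (
    NB,
    XI,
    ModelSpecSocial,
    SocialBeliefParams,
    belief_update,
    bin_to_rating,
    binomial_power_prior,
    blunt_for_emission,
    build_policy_map,
    get_social_spec,
    initial_joint_belief,
    rating_to_bin,
    reset_beliefs_dg,
    reset_beliefs_dg_two_eta,
    simulate_social_agent,
    social_loglik,
    social_model_space,
)
from socialrl.tasks import DGEnvironment

SWEEP_BASE = dict(p_hi0=0.5, u_hi0=2.0, p_si0=0.5, u_si0=2.0, u_pi=2.0,
                w0=-1.0, w_hi=0.1, w_si=0.3, eta_dg=0.5)


def enum_prior(p, u, nb=9):
    """Brute-force enumeration of the powered binomial pmf."""
    terms = [comb(nb - 1, k) * p**k * (1 - p) ** (nb - 1 - k) for k in range(nb)]
    powered = [t**u for t in terms]
    total = sum(powered)
    return np.array([t / total for t in powered])


class TestBinomialPowerPrior:
    def test_unit_exponent_symmetric_binomial(self):
        expected = np.array([1, 8, 28, 56, 70, 56, 28, 8, 1]) / 256
        np.testing.assert_allclose(
            binomial_power_prior(0.5, 1.0), expected, atol=1e-14
        )

    def test_zero_exponent_uniform(self):
        np.testing.assert_allclose(binomial_power_prior(0.3, 0.0), np.full(9, 1 / 9))

    def test_squared_pmf_matches_enumeration(self):
        np.testing.assert_allclose(
            binomial_power_prior(0.7, 2.0), enum_prior(0.7, 2.0), atol=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p=st.floats(0.01, 0.99), u=st.floats(0.0, 10.0))
    def test_always_a_distribution(self, p, u):
        out = binomial_power_prior(p, u)
        assert np.all(out >= 0)
        assert out.sum() == pytest.approx(1.0, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_power_prior(1.2, 1.0)
        with pytest.raises(ValueError):
            binomial_power_prior(0.5, 1.0, nb=1)


class TestJointPrior:
    def test_flat_prior_case(self):
        params = SocialBeliefParams(p_hi0=0.5, u_hi0=0.0, p_si0=0.5, u_si0=0.0,
                                    u_pi=1.0, w0=0.0, w_hi=0.0, w_si=0.0)
        np.testing.assert_allclose(initial_joint_belief(params), np.full((9, 9), 1 / 81))

    def test_marginal_recovers_each_prior(self):
        params = SocialBeliefParams(p_hi0=0.3, u_hi0=2.0, p_si0=0.7, u_si0=0.5,
                                    u_pi=1.0, w0=0.0, w_hi=0.0, w_si=0.0)
        joint = initial_joint_belief(params)
        np.testing.assert_allclose(
            joint.sum(axis=1), binomial_power_prior(0.3, 2.0), atol=1e-12
        )
        np.testing.assert_allclose(
            joint.sum(axis=0), binomial_power_prior(0.7, 0.5), atol=1e-12
        )

    def test_sweep_base_configuration_is_outer_product(self):
        params = SocialBeliefParams(**SWEEP_BASE)
        joint = initial_joint_belief(params)
        np.testing.assert_allclose(
            joint, np.outer(enum_prior(0.5, 2.0), enum_prior(0.5, 2.0)), atol=1e-12
        )


class TestPolicyMap:
    def test_zero_weights_give_half_everywhere(self):
        np.testing.assert_allclose(build_policy_map(0.0, 0.0, 0.0), 0.5)

    def test_centre_bin_equals_intercept_sigmoid(self):
        pmap = build_policy_map(-1.0, 0.1, 0.1)
        assert pmap[4, 4] == pytest.approx(1 / (1 + math.exp(1.0)))

    def test_full_map_matches_elementwise_sigmoid(self):
        w0, whi, wsi = -1.0, 0.1, 0.3
        pmap = build_policy_map(w0, whi, wsi)
        for hi in range(1, 10):
            for si in range(1, 10):
                z = w0 + whi * (hi - 5) + wsi * (si - 5)
                assert pmap[hi - 1, si - 1] == pytest.approx(
                    1 / (1 + math.exp(-z)), rel=1e-12
                )


class TestBeliefUpdate:
    def test_uninformative_likelihood_leaves_prior(self):
        prior = np.full((9, 9), 1 / 81)
        np.testing.assert_allclose(
            belief_update(prior, 0.0, np.full((9, 9), 0.5)), prior
        )

    def test_unfair_return_raises_harmful_intent_mean(self):
        params = SocialBeliefParams(**SWEEP_BASE)
        prior = initial_joint_belief(params)
        pmap = build_policy_map(-1.0, 0.5, 0.0)
        post = belief_update(prior, 0.0, pmap)
        bins = np.arange(1, 10)
        assert post.sum(axis=1) @ bins > prior.sum(axis=1) @ bins

    def test_five_observation_sequence_matches_batch_enumeration(self):
        params = SocialBeliefParams(**SWEEP_BASE)
        prior = initial_joint_belief(params)
        pmap = build_policy_map(-1.0, 0.2, 0.3)
        returns = [0.0, 0.5, 0.0, 0.0, 0.5]
        belief = prior
        for r in returns:
            belief = belief_update(belief, r, pmap)
        # brute force: per-cell product of likelihoods times prior
        brute = np.empty((9, 9))
        for i in range(9):
            for j in range(9):
                like = 1.0
                for r in returns:
                    like *= pmap[i, j] if r == 0.0 else 1 - pmap[i, j]
                brute[i, j] = like * prior[i, j]
        brute /= brute.sum()
        np.testing.assert_allclose(belief, brute, atol=1e-12)


class TestEmissionAndReset:
    def test_identity_blunting(self):
        params = SocialBeliefParams(**SWEEP_BASE)
        b = initial_joint_belief(params)
        np.testing.assert_allclose(blunt_for_emission(b, 1.0, xi=0.0), b)

    def test_extreme_uncertainty_flattens(self):
        params = SocialBeliefParams(**SWEEP_BASE)
        b = initial_joint_belief(params)
        out = blunt_for_emission(b, 1e6, xi=0.0)
        assert np.all(np.abs(out - 1 / 81) < 1e-4)

    def test_lapse_floor_on_point_mass(self):
        b = np.full((9, 9), 1e-300)
        b[0, 0] = 1.0
        out = blunt_for_emission(b, 1.0, xi=XI)
        assert out.min() >= XI / (1 + 81 * XI) - 1e-15

    def test_reset_endpoints_and_midpoint(self):
        params = SocialBeliefParams(**SWEEP_BASE)
        p0 = initial_joint_belief(params)
        p1 = belief_update(p0, 0.0, build_policy_map(-1.0, 0.3, 0.3))
        np.testing.assert_allclose(reset_beliefs_dg(p0, p1, 0.0), p0)
        np.testing.assert_allclose(reset_beliefs_dg(p0, p1, 1.0), p1)
        np.testing.assert_allclose(
            reset_beliefs_dg(p0, p1, 0.5), 0.5 * p0 + 0.5 * p1
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(eta=st.floats(0, 1))
    def test_reset_output_is_distribution_without_renormalising(self, eta):
        params = SocialBeliefParams(**SWEEP_BASE)
        p0 = initial_joint_belief(params)
        p1 = belief_update(p0, 0.0, build_policy_map(-1.0, 0.3, 0.3))
        mixed = reset_beliefs_dg(p0, p1, eta)
        assert mixed.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(mixed >= 0)

    def test_two_eta_reset_mixes_marginals_separately(self):
        params = SocialBeliefParams(**SWEEP_BASE)
        p0 = initial_joint_belief(params)
        p1 = belief_update(p0, 0.0, build_policy_map(-1.0, 0.3, 0.3))
        out = reset_beliefs_dg_two_eta(p0, p1, eta_hi=0.2, eta_si=0.9)
        np.testing.assert_allclose(
            out.sum(axis=1), 0.8 * p0.sum(axis=1) + 0.2 * p1.sum(axis=1), atol=1e-12
        )
        np.testing.assert_allclose(
            out.sum(axis=0), 0.1 * p0.sum(axis=0) + 0.9 * p1.sum(axis=0), atol=1e-12
        )


class TestRatingBins:
    @pytest.mark.parametrize("rating,expected", [(0, 1), (100, 9), (50, 5)])
    def test_boundaries_and_midpoint(self, rating, expected):
        assert rating_to_bin(rating) == expected

    def test_bin_centre_of_middle_bin(self):
        assert bin_to_rating(5) == pytest.approx(50.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(rating=st.floats(0, 100))
    def test_round_trip_stays_in_own_bin(self, rating):
        b = rating_to_bin(rating)
        assert rating_to_bin(bin_to_rating(b)) == b

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rating_to_bin(-1)


class TestSocialLoglik:
    def test_flat_model_closed_form(self, random_dg_data):
        params = SocialBeliefParams(p_hi0=0.5, u_hi0=0.0, p_si0=0.5, u_si0=0.0,
                                    u_pi=1.0, w0=0.0, w_hi=0.0, w_si=0.0)
        ll = social_loglik(random_dg_data, params, xi=0.0)
        assert ll == pytest.approx(20 * math.log(1 / 81))

    def test_single_trial_matches_single_step_oracle(self):
        params = SocialBeliefParams(**SWEEP_BASE)
        data = make_dg([0.0], [70.0], [30.0])
        prior = initial_joint_belief(params)
        pmap = build_policy_map(-1.0, 0.1, 0.3)
        post = pmap * prior
        post /= post.sum()
        emit = post ** (1 / 2.0) + XI
        emit /= emit.sum()
        expected = math.log(emit[rating_to_bin(70) - 1, rating_to_bin(30) - 1])
        assert social_loglik(data, params) == pytest.approx(expected, abs=1e-12)

    def test_matches_independent_recursion_oracle(self, random_dg_data):
        params = SocialBeliefParams(**SWEEP_BASE)
        # straight-line reimplementation
        belief = np.outer(enum_prior(0.5, 2.0), enum_prior(0.5, 2.0))
        prior0 = belief.copy()
        total = 0.0
        for rec in random_dg_data:
            if rec.trial == 11:
                belief = 0.5 * prior0 + 0.5 * belief
            like = np.empty((9, 9))
            for i in range(9):
                for j in range(9):
                    z = -1.0 + 0.1 * (i + 1 - 5) + 0.3 * (j + 1 - 5)
                    p_unfair = 1 / (1 + math.exp(-z))
                    like[i, j] = p_unfair if rec.partner_return == 0 else 1 - p_unfair
            belief = like * belief
            belief /= belief.sum()
            emit = belief ** 0.5 + 0.02 / 81
            emit /= emit.sum()
            hi_b = min(9, int(rec.hi_rating * 9 / 100) + 1)
            si_b = min(9, int(rec.si_rating * 9 / 100) + 1)
            total += math.log(emit[hi_b - 1, si_b - 1])
        assert social_loglik(random_dg_data, params) == pytest.approx(total, abs=1e-8)

    def test_grids_stay_normalised_through_recursion(self):
        params = SocialBeliefParams(**SWEEP_BASE)
        belief = initial_joint_belief(params)
        pmap = build_policy_map(params.w0, params.w_hi, params.w_si)
        for r in [0.0, 0.5] * 10:
            belief = belief_update(belief, r, pmap)
            assert belief.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(belief >= 0)
            emit = blunt_for_emission(belief, params.u_pi)
            assert emit.sum() == pytest.approx(1.0, abs=1e-10)


class TestSimulation:
    def test_symmetric_agent_mean_rating_near_fifty(self):
        params = SocialBeliefParams(p_hi0=0.5, u_hi0=2.0, p_si0=0.5, u_si0=2.0,
                                    u_pi=2.0, w0=0.0, w_hi=0.0, w_si=0.0)
        env = DGEnvironment(condition="initially_unfair")
        ratings = [
            r.hi_rating
            for seed in range(300)
            for r in simulate_social_agent(env, params, seed)
        ]
        assert np.mean(ratings) == pytest.approx(50.0, abs=2.0)

    def test_degenerate_prior_emits_its_mode(self):
        params = SocialBeliefParams(p_hi0=0.9, u_hi0=200.0, p_si0=0.1, u_si0=200.0,
                                    u_pi=1.0, w0=0.0, w_hi=0.0, w_si=0.0)
        env = DGEnvironment()
        recs = simulate_social_agent(env, params, 3, xi=0.0)
        mode_hi = np.argmax(binomial_power_prior(0.9, 200.0)) + 1
        mode_si = np.argmax(binomial_power_prior(0.1, 200.0)) + 1
        assert all(rating_to_bin(r.hi_rating) == mode_hi for r in recs)
        assert all(rating_to_bin(r.si_rating) == mode_si for r in recs)

    def test_same_seed_identical_records(self):
        params = SocialBeliefParams(**SWEEP_BASE)
        env = DGEnvironment()
        assert simulate_social_agent(env, params, 9) == simulate_social_agent(env, params, 9)


class TestTrajectoryExport:
    def test_long_format_trajectory_is_trialwise_normalised(self, random_dg_data):
        from socialrl.belief import belief_trajectory

        params = SocialBeliefParams(**SWEEP_BASE)
        table = belief_trajectory(random_dg_data, params, participant_id="p1")
        assert list(table.columns) == ["participant_id", "trial", "hi_bin",
                                       "si_bin", "prob"]
        assert len(table) == 20 * 81
        sums = table.groupby("trial")["prob"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)
        # the first trial's grid equals one blunted Bayes step from the prior
        first = table[table.trial == 1].pivot(index="hi_bin", columns="si_bin",
                                              values="prob").to_numpy()
        prior = initial_joint_belief(params)
        pmap = build_policy_map(-1.0, 0.1, 0.3)
        expected = blunt_for_emission(
            belief_update(prior, random_dg_data[0].partner_return, pmap), 2.0
        )
        np.testing.assert_allclose(first, expected, atol=1e-12)


class TestModelSpace:
    def test_registry_contents(self):
        space = social_model_space()
        assert len(space) == 6
        winning = get_social_spec("bb_free_1eta")
        assert set(winning.free) == {
            "p_hi0", "u_hi0", "p_si0", "u_si0", "u_pi", "w0", "w_hi", "w_si", "eta_dg"
        }
        fixed = get_social_spec("bb_fixed_0eta")
        assert fixed.n_free == 5

    def test_two_eta_spec_builds_marginal_resets(self):
        spec = get_social_spec("bb_free_2eta")
        params = spec.build_params(
            {**{k: v for k, v in SWEEP_BASE.items() if k != "eta_dg"},
             "eta_hi": 0.3, "eta_si": 0.7}
        )
        assert params.eta_dg is None
        assert params.eta_hi == 0.3 and params.eta_si == 0.7

    def test_mixing_joint_and_marginal_etas_rejected(self):
        with pytest.raises(ValueError):
            SocialBeliefParams(**{**SWEEP_BASE, "eta_hi": 0.5})
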