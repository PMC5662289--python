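import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obsirl.agent_sim import softmax_pair_prob
from obsirl.observer_models import (
    ORDERINGS,
    ImitationParams,
    InverseRLParams,
    ObserverParamError,
    RankLearnerParams,
    imitation_invert,
    imitation_update,
    init_beliefs,
    irl_expected_values,
    irl_kl_signal,
    irl_update,
    make_context,
    make_observer,
    observer_simulate,
    rank_belief_policy,
    rank_belief_update,
)

EPS_SPREAD = (0.9, 0.5, 0.1)


def irl_params(eps=EPS_SPREAD, beta=5.0, decay=None):
    return InverseRLParams(eps=eps, beta=beta, decay=decay)


class TestIrlUpdate:
    def test_multiplicative_renormalized_arithmetic(self):
        new = irl_update(init_beliefs(), 0, 1, irl_params())
        np.testing.assert_allclose(new[0], [0.6, 1 / 3, 1 / 15])
        # unchosen row gets the flipped vector
        np.testing.assert_allclose(new[1], [1 / 15, 1 / 3, 0.6])

    def test_unoffered_row_untouched(self):
        before = irl_update(init_beliefs(), 0, 1, irl_params())
        after = irl_update(before, 0, 1, irl_params())
        np.testing.assert_array_equal(before[2], after[2])

    @pytest.mark.parametrize("k", [0.1, 0.5, 0.9])
    def test_uniform_eps_is_identity(self, k):
        new = irl_update(init_beliefs(), 1, 2, irl_params(eps=(k, k, k)))
        np.testing.assert_allclose(new, init_beliefs())

    def test_invalid_eps_rejected(self):
        with pytest.raises(ObserverParamError):
            irl_params(eps=(0.0, 0.5, 0.5))
        with pytest.raises(ObserverParamError):
            irl_params(eps=(0.5, 1.0, 0.5))

    def test_same_machine_rejected(self):
        with pytest.raises(ObserverParamError):
            irl_update(init_beliefs(), 1, 1, irl_params())

    @settings(max_examples=100, deadline=None)
    @given(
        eps=st.tuples(*[st.floats(min_value=0.01, max_value=0.99)] * 3),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_simplex_conserved_under_random_updates(self, eps, seed):
        rng = np.random.default_rng(seed)
        beliefs = init_beliefs()
        params = irl_params(eps=eps)
        for _ in range(50):
            c, u = rng.choice(3, size=2, replace=False)
            beliefs = irl_update(beliefs, int(c), int(u), params)
        np.testing.assert_allclose(beliefs.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(beliefs >= 0)


class TestIrlValues:
    def test_uniform_beliefs_mean_value(self):
        np.testing.assert_allclose(irl_expected_values(init_beliefs(), (3, 2, 1)), 2.0)

    def test_degenerate_belief(self):
        b = init_beliefs()
        b[0] = [1, 0, 0]
        assert irl_expected_values(b, (3, 2, 1))[0] == pytest.approx(3.0)

    def test_dissimilar_dot_product(self):
        b = init_beliefs()
        b[0] = [0.6, 1 / 3, 1 / 15]
        v = irl_expected_values(b, (1, 2, 3))[0]
        assert v == pytest.approx(0.6 * 1 + (1 / 3) * 2 + (1 / 15) * 3)
        assert v == pytest.approx(1.4667, abs=1e-4)


class TestKlSignal:
    def test_identity_is_zero(self):
        assert irl_kl_signal(np.full(3, 1 / 3), np.full(3, 1 / 3)) == 0.0

    def test_direct_evaluation(self):
        post = np.array([0.6, 1 / 3, 1 / 15])
        expected = sum(p * np.log(p / (1 / 3)) for p in post)
        assert irl_kl_signal(np.full(3, 1 / 3), post) == pytest.approx(expected)
        assert expected == pytest.approx(0.245376, abs=1e-6)

    def test_asymmetry(self):
        u = np.full(3, 1 / 3)
        post = np.array([0.6, 1 / 3, 1 / 15])
        forward = irl_kl_signal(u, post)
        backward = irl_kl_signal(post, u)
        assert forward != pytest.approx(backward)

    def test_zero_prior_mass_rejected(self):
        with pytest.raises(ObserverParamError):
            irl_kl_signal(np.array([1.0, 0.0, 0.0]), np.array([0.5, 0.5, 0.0]))


class TestImitation:
    def test_chosen_update(self):
        p = ImitationParams(eta=0.5, theta=0.0, beta=5.0)
        new = imitation_update(np.full(3, 0.5), 0, p)
        assert new[0] == pytest.approx(0.75)
        np.testing.assert_array_equal(new[1:], [0.5, 0.5])

    def test_counterfactual_decay(self):
        p = ImitationParams(eta=0.5, theta=0.0, beta=5.0, eta_unchosen=0.5)
        new = imitation_update(np.full(3, 0.5), 0, p, counterfactual=True, unchosen=1)
        assert new[1] == pytest.approx(0.25)

    def test_eta_zero_no_learning(self):
        p = ImitationParams(eta=0.0, theta=0.0, beta=5.0)
        np.testing.assert_array_equal(imitation_update(np.full(3, 0.5), 2, p), np.full(3, 0.5))

    def test_counterfactual_requires_rate(self):
        p = ImitationParams(eta=0.5, theta=0.0, beta=5.0)
        with pytest.raises(ObserverParamError):
            imitation_update(np.full(3, 0.5), 0, p, counterfactual=True, unchosen=1)

    @pytest.mark.parametrize(
        "theta,v,expected",
        [(0.0, 0.8, 0.8), (1.0, 0.8, 0.2), (0.5, 0.13, 0.5), (0.5, 0.99, 0.5)],
    )
    def test_inversion_fixed_points(self, theta, v, expected):
        assert imitation_invert(v, theta) == pytest.approx(expected)

    def test_inversion_bounds(self):
        with pytest.raises(ObserverParamError):
            imitation_invert(1.2, 0.5)


class TestRankLearner:
    def test_one_observation_shifts_mass(self):
        belief = np.full(6, 1 / 6)
        post = rank_belief_update(belief, 0, 1, kappa=1.0)
        favoring = [k for k, pi in enumerate(ORDERINGS) if pi.index(0) < pi.index(1)]
        assert post[favoring].sum() > 0.5

    def test_tiny_kappa_flat_likelihood(self):
        belief = np.full(6, 1 / 6)
        post = rank_belief_update(belief, 0, 1, kappa=1e-9)
        np.testing.assert_allclose(post, belief, atol=1e-6)

    def test_brute_force_bayes_oracle(self):
        # independent enumeration of the posterior over all 6 orderings
        belief = np.full(6, 1 / 6)
        post = rank_belief_update(belief, 2, 0, kappa=1.0)
        scores = {pi: [3 - pi.index(m) for m in range(3)] for pi in ORDERINGS}
        like = np.array(
            [1 / (1 + np.exp(-(scores[pi][2] - scores[pi][0]))) for pi in ORDERINGS]
        )
        expected = (like / 6) / (like / 6).sum()
        np.testing.assert_allclose(post, expected)

    def test_uniform_policy_is_half(self):
        assert rank_belief_policy(np.full(6, 1 / 6), (0, 2), beta=8.0) == pytest.approx(0.5)

    def test_concentrated_belief_and_flip(self):
        belief = np.zeros(6)
        belief[ORDERINGS.index((0, 1, 2))] = 1.0
        assert rank_belief_policy(belief, (0, 2), beta=5.0) > 0.99
        assert rank_belief_policy(belief, (0, 2), beta=5.0, flip=-1) < 0.01

    def test_mixed_belief_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        belief = rng.dirichlet(np.ones(6))
        scores = np.array([[3 - pi.index(m) for m in range(3)] for pi in ORDERINGS])
        exp_scores = belief @ scores
        expected = softmax_pair_prob(exp_scores[1], exp_scores[2], 4.0)
        assert rank_belief_policy(belief, (1, 2), beta=4.0) == pytest.approx(expected)


class TestObserverSimulate:
    def test_uniform_eps_forces_chance_policy(self, agent_log):
        ctx = make_context("similar")
        rng = np.random.default_rng(0)
        obs = make_observer("inverse_rl", irl_params(eps=(0.3, 0.3, 0.3)), ctx)
        for rec in agent_log.trials_of("agent"):
            i, j = ctx.machines.index(rec.pair[0]), ctx.machines.index(rec.pair[1])
            c = ctx.machines.index(rec.chosen)
            obs.observe(c, j if c == i else i)
            np.testing.assert_allclose(obs.beliefs, init_beliefs(), atol=1e-12)
        assert obs.self_choice_prob((0, 2)) == pytest.approx(0.5)

    def test_pure_imitation_limit_copies_agent(self):
        # theta = 0 and near-deterministic beta: the observer replicates the
        # machine the agent consistently chose in each pair
        from conftest import make_log
        from obsirl.task_core import TrialRecord

        recs = []
        idx = 1
        for _ in range(10):
            for chosen, pair in (("A", ("A", "B")), ("A", ("A", "C")), ("B", ("B", "C"))):
                recs.append(TrialRecord(idx, "agent", pair, "agent", chosen, 1))
                idx += 1
        for pair in (("A", "B"), ("A", "C"), ("B", "C")):
            recs.append(TrialRecord(idx, "self", pair, "self", None, None))
            recs[-1].chosen = pair[0]  # placeholder; regenerated below
            idx += 1
        agent_log = make_log(recs)
        ctx = make_context("similar")
        params = ImitationParams(eta=0.2, theta=0.0, beta=22.0)
        log, _ = observer_simulate("imitation", params, agent_log, ctx, np.random.default_rng(0))
        picks = {r.pair: r.chosen for r in log.trials_of("self")}
        assert picks[("A", "B")] == "A"
        assert picks[("A", "C")] == "A"
        assert picks[("B", "C")] == "B"

    def test_seeded_reproducibility(self, agent_log):
        ctx = make_context("dissimilar")
        out = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            log, sig = observer_simulate("inverse_rl", irl_params(), agent_log, ctx, rng)
            out.append((log.to_frame(), sig))
        assert out[0][0].equals(out[1][0])
        assert out[0][1].equals(out[1][1])

    def test_unknown_model_rejected(self, agent_log):
        with pytest.raises(ObserverParamError):
            observer_simulate("psychic", None, agent_log, make_context("similar"),
                              np.random.default_rng(0))

    def test_agent_space_values_condition_invariant(self, agent_log):
        """The agent-referential value trajectory depends only on the agent
        log, not on whether the observer is in the similar or dissimilar
        condition (only the self-value mapping differs)."""
        sigs = {}
        for condition in ("similar", "dissimilar"):
            ctx = make_context(condition)
            rng = np.random.default_rng(5)
            _, sig = observer_simulate("inverse_rl", irl_params(), agent_log, ctx, rng)
            sigs[condition] = sig
        a = sigs["similar"][sigs["similar"].kind == "agent"]
        b = sigs["dissimilar"][sigs["dissimilar"].kind == "agent"]
        np.testing.assert_allclose(a.value_agent_chosen.values, b.value_agent_chosen.values)
        np.testing.assert_allclose(a.kl_update.values, b.kl_update.values)

    def test_kl_positive_iff_row_changed(self, agent_log):
        ctx = make_context("similar")
        rng = np.random.default_rng(0)
        _, sig = observer_simulate("inverse_rl", irl_params(), agent_log, ctx, rng)
        kl = sig[sig.kind == "agent"].kl_update
        assert (kl >= 0).all()
        assert (kl > 0).mean() > 0.9  # informative eps almost always moves the row

    def test_decay_window_limits_memory(self, agent_log):
        """With a 1-trial window, beliefs reflect only the latest observation."""
        ctx = make_context("similar")
        obs = make_observer("inverse_rl", irl_params(decay=1), ctx)
        obs.observe(0, 1)
        obs.observe(2, 1)
        expected = irl_update(init_beliefs(), 2, 1, irl_params())
        np.testing.assert_allclose(obs.beliefs, expected)
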