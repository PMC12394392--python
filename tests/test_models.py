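"""Unit and property tests for the cognitive-model simulators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lasenet as ln
from lasenet import models as cm
from lasenet.baselines import weber_belief_trajectory
from lasenet.datasets import default_prior, sample_parameters
from lasenet.errors import InvalidInputError, InvalidParameterError

from conftest import make_session


# --------------------------------------------------------------------------
# elementary update rules
# --------------------------------------------------------------------------

@pytest.mark.parametrize("q,r,alpha,expected_q,expected_rpe", [
    (0.5, 1, 0.1, 0.55, 0.5),
    (0.3, 0, 0.0, 0.3, -0.3),
    (0.0, 1, 1.0, 1.0, 1.0),
])
def test_qvalue_update_delta_rule(q, r, alpha, expected_q, expected_rpe):
    updated, rpe = ln.qvalue_update(q, r, alpha)
    assert updated == pytest.approx(expected_q)
    assert rpe == pytest.approx(expected_rpe)


def test_qvalue_update_rejects_bad_learning_rate():
    with pytest.raises(InvalidParameterError):
        ln.qvalue_update(0.5, 1, 1.5)
    with pytest.raises(InvalidParameterError):
        ln.qvalue_update(0.5, 1, -0.1)


def test_softmax_policy_closed_forms():
    assert ln.softmax_policy([0.7, 0.2], 0.0) == pytest.approx([0.5, 0.5])
    # logistic of beta * (Q1 - Q2)
    p = ln.softmax_policy([0.6, 0.4], 1.0)
    assert p == pytest.approx([0.5498, 0.4502], abs=1e-4)
    p = ln.softmax_policy([1.0, 0.0, 0.0], 200.0)
    assert p[0] == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(InvalidInputError):
        ln.softmax_policy([], 1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    values=st.lists(st.floats(-5, 5), min_size=2, max_size=6),
    beta=st.floats(0, 10),
    shift=st.floats(-3, 3),
)
def test_softmax_policy_is_a_shift_invariant_distribution(values, beta, shift):
    p = ln.softmax_policy(values, beta)
    assert np.all(p > 0)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    p2 = ln.softmax_policy(np.asarray(values) + shift, beta)
    assert np.allclose(p, p2, atol=1e-9)


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

def test_parameter_counts_match_model_table():
    expected = {"4prl": 4, "metarl": 9, "hrl": 2, "weber": 3, "glmhmm": 21}
    for model_id, n in expected.items():
        assert len(cm.get_spec(model_id).param_names) == n


def test_parameters_validated_against_bounds():
    with pytest.raises(InvalidParameterError):
        ln.ModelParameters("4prl", {"alpha_pos": 1.5, "alpha_neg": 0.1,
                                    "beta": 1.0, "kappa": 0.0})
    with pytest.raises(InvalidParameterError):
        ln.ModelParameters("4prl", {"alpha_pos": 0.5})


def test_glmhmm_transition_rows_must_sum_to_one(rng):
    params = sample_parameters(default_prior("glmhmm"), 1, rng)[0]
    bad = dict(params.values)
    bad["a00"] = min(1.0, bad["a00"] + 0.2)
    with pytest.raises(InvalidParameterError):
        ln.ModelParameters("glmhmm", bad)


# --------------------------------------------------------------------------
# simulator contracts
# --------------------------------------------------------------------------

EXPECTED_SHAPES = {
    # model: (stimulus_dim, n_actions, cont_channels, n_states)
    "4prl": (0, 2, 1, None),
    "metarl": (0, 2, 1, 2),
    "hrl": (3, 2, 1, 3),
    "weber": (7, 4, 1, 24),
    "glmhmm": (1, 2, 0, 3),
}


@pytest.mark.parametrize("model_id", ln.MODEL_IDS)
def test_simulator_output_contract(model_id):
    stim_dim, n_actions, C, M = EXPECTED_SHAPES[model_id]
    _, session, latents = make_session(model_id, n_trials=50, seed=1)
    T = 50
    assert session.stimuli.shape == (T, stim_dim)
    assert session.actions.shape == (T,)
    assert session.rewards.shape == (T,)
    assert set(np.unique(session.rewards)) <= {0, 1}
    assert session.actions.min() >= 0 and session.actions.max() < n_actions
    assert latents.continuous.shape == (T, C)
    if M is None:
        assert latents.discrete is None
    else:
        assert latents.discrete.shape == (T,)
        assert latents.state_space_size == M
        assert latents.discrete.min() >= 0 and latents.discrete.max() < M


@pytest.mark.parametrize("model_id", ln.MODEL_IDS)
def test_simulators_reproducible_under_seed(model_id):
    _, s1, z1 = make_session(model_id, n_trials=40, seed=9)
    _, s2, z2 = make_session(model_id, n_trials=40, seed=9)
    assert np.array_equal(s1.stimuli, s2.stimuli)
    assert np.array_equal(s1.actions, s2.actions)
    assert np.array_equal(s1.rewards, s2.rewards)
    assert np.array_equal(z1.continuous, z2.continuous)
    if z1.discrete is not None:
        assert np.array_equal(z1.discrete, z2.discrete)


@pytest.mark.parametrize("model_id", ["4prl", "metarl", "hrl"])
def test_q_trajectories_stay_in_unit_interval(model_id):
    for seed in range(5):
        _, _, latents = make_session(model_id, n_trials=300, seed=seed)
        assert latents.continuous.min() >= 0.0
        assert latents.continuous.max() <= 1.0


def test_4prl_no_learning_keeps_q_at_initialization(rng):
    params = ln.ModelParameters("4prl", {"alpha_pos": 0.0, "alpha_neg": 0.0,
                                         "beta": 3.0, "kappa": 0.2})
    _, latents = ln.simulate_4prl(params, ln.default_task("4prl", 100), rng)
    assert np.all(latents.continuous == 0.5)


def test_4prl_uniform_policy_choice_frequency(rng):
    params = ln.ModelParameters("4prl", {"alpha_pos": 0.3, "alpha_neg": 0.3,
                                         "beta": 0.0, "kappa": 0.0})
    session, _ = ln.simulate_4prl(params, ln.default_task("4prl", 720), rng)
    freq = session.actions.mean()
    sd = 0.5 / np.sqrt(720)
    assert abs(freq - 0.5) < 3 * sd


def test_metarl_absorbing_engaged_state(rng):
    values = dict(alpha_pos=0.3, alpha_neg=0.2, beta=3.0, kappa=0.0,
                  forget=0.1, bias=0.5, p_stay_engaged=1.0,
                  p_stay_random=0.5, p_engaged0=1.0)
    _, latents = ln.simulate_metarl(ln.ModelParameters("metarl", values),
                                    ln.default_task("metarl", 200), rng)
    assert np.all(latents.discrete == 0)


def test_metarl_state_occupancy_matches_stationary_distribution(rng):
    pe, pr = 0.95, 0.85
    values = dict(alpha_pos=0.3, alpha_neg=0.2, beta=2.0, kappa=0.0,
                  forget=0.1, bias=0.6, p_stay_engaged=pe,
                  p_stay_random=pr, p_engaged0=0.5)
    task = cm.TaskConfig("metarl", n_trials=10_000)
    _, latents = ln.simulate_metarl(ln.ModelParameters("metarl", values),
                                    task, rng)
    # stationary distribution of the 2-state chain
    pi_engaged = (1 - pr) / ((1 - pe) + (1 - pr))
    occ = np.mean(latents.discrete == 0)
    # conservative SD bound accounting for chain autocorrelation
    rho = pe + pr - 1
    n_eff = 10_000 * (1 - rho) / (1 + rho)
    sd = np.sqrt(pi_engaged * (1 - pi_engaged) / n_eff)
    assert abs(occ - pi_engaged) < 3 * sd


def test_hrl_emitted_side_matches_chosen_arrow():
    _, session, latents = make_session("hrl", n_trials=200, seed=4)
    dirs = session.stimuli.astype(int)
    chosen = latents.discrete
    assert np.all(session.actions == dirs[np.arange(200), chosen])


def test_hrl_continuous_latent_is_chosen_arrow_pre_update_q():
    params = ln.ModelParameters("hrl", {"alpha": 0.5, "beta": 2.0})
    rng = np.random.default_rng(0)
    session, latents = ln.simulate_hrl(params, ln.default_task("hrl", 100), rng)
    # replay: only the chosen arrow's value updates by the delta rule
    Q = np.full(3, 0.5)
    for t in range(100):
        k = latents.discrete[t]
        assert latents.continuous[t, 0] == pytest.approx(Q[k])
        Q[k] += 0.5 * (session.rewards[t] - Q[k])


def test_weber_noise_free_simulation_matches_exact_bayes_replay():
    params = ln.ModelParameters(
        "weber", {"mu": 0.0, "lam": 0.0, "select_beta": 5.0})
    rng = np.random.default_rng(21)
    session, latents = ln.simulate_weber(params,
                                         ln.default_task("weber", 120), rng)
    beliefs, d = weber_belief_trajectory(session)
    assert np.allclose(d, latents.continuous[:, 0], atol=1e-12)
    assert np.allclose(beliefs.sum(axis=1), 1.0, atol=1e-12)
    assert beliefs.min() >= 0


def test_weber_belief_update_concentrates_on_true_mapping():
    # hand-built consistent observation sequence: repeatedly observing the
    # true mapping's rewarded actions must concentrate the posterior on it
    true_idx = 7
    mapping = cm.WEBER_MAPPINGS[true_idx]
    belief = np.full(24, 1.0 / 24.0)
    h = 0.03
    for rep in range(4):
        for s in range(3):
            belief = cm.weber_predict(
                cm.weber_condition(belief, s, mapping[s], 1), h)
    # independent oracle: direct enumeration of the same Bayes recursion
    oracle = np.full(24, 1.0 / 24.0)
    for rep in range(4):
        for s in range(3):
            like = np.array([1.0 if m[s] == mapping[s] else 0.0
                             for m in cm.WEBER_MAPPINGS])
            oracle = oracle * like
            oracle /= oracle.sum()
            oracle = (1 - h) * oracle + h / 24.0
    assert np.allclose(belief, oracle, atol=1e-12)
    assert belief.argmax() == true_idx
    assert belief[true_idx] > 0.8


def test_weber_stimulus_one_hot_uses_three_slots():
    _, session, _ = make_session("weber", n_trials=300, seed=6)
    assert np.all(session.stimuli.sum(axis=1) == 1.0)
    assert (session.stimuli.any(axis=0)).sum() == 3


def test_glmhmm_identity_transition_freezes_state(rng):
    params = sample_parameters(default_prior("glmhmm"), 1, rng)[0]
    values = dict(params.values)
    for i in range(3):
        for j in range(3):
            values[f"a{i}{j}"] = 1.0 if i == j else 0.0
    _, latents = ln.simulate_glmhmm(ln.ModelParameters("glmhmm", values),
                                    ln.default_task("glmhmm", 150), rng)
    assert len(np.unique(latents.discrete)) == 1


def test_glmhmm_zero_weights_give_unbiased_choices(rng):
    params = sample_parameters(default_prior("glmhmm"), 1, rng)[0]
    values = {k: (0.0 if k.startswith("w") else v)
              for k, v in params.values.items()}
    session, _ = ln.simulate_glmhmm(ln.ModelParameters("glmhmm", values),
                                    ln.default_task("glmhmm", 720), rng)
    sd = 0.5 / np.sqrt(720)
    assert abs(session.actions.mean() - 0.5) < 3 * sd


def test_glmhmm_empirical_transitions_match_generator(rng):
    params = sample_parameters(default_prior("glmhmm"), 1, rng)[0]
    A = params.transition_matrix()
    task = cm.TaskConfig("glmhmm", n_trials=20_000)
    _, latents = ln.simulate_glmhmm(params, task, rng)
    z = latents.discrete
    for i in range(3):
        from_i = z[:-1] == i
        n_i = from_i.sum()
        for j in range(3):
            emp = np.mean(z[1:][from_i] == j)
            sd = np.sqrt(A[i, j] * (1 - A[i, j]) / n_i)
            assert abs(emp - A[i, j]) < 4 * max(sd, 1e-3)
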