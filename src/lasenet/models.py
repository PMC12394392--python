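"""Generative simulators for five computational cognitive models.

Each model describes a biological agent performing a trial-based task:
the agent observes a stimulus, emits an action, and receives a reward.
The simulators produce both the observable sequence Y (stimuli, actions,
rewards) and the aligned latent trajectory Z (continuous channels such as
the chosen action's Q-value, and/or discrete state labels such as the
attentive state or the internally chosen rule) that estimators are later
asked to recover.

Models
------
``4prl``
    Four-parameter Q-learning (asymmetric learning rates, softmax with
    choice stickiness) in a two-armed probabilistic-reversal bandit.
``metarl``
    The same learner modulated by a two-state hidden Markov process over
    attentive states (engaged vs. random), with forgetting of the
    unchosen option.
``hrl``
    Hierarchical RL: three colored arrows each point left or right; the
    agent picks an arrow (unobservable) by softmax over arrow values and
    emits the side that arrow points to.
``weber``
    Bayesian task-set learner with Weber-scaled behavioral noise: a
    posterior over the 24 injective stimulus->action mappings, with
    mapping selection corrupted in proportion to the distance between
    consecutive posterior beliefs.
``glmhmm``
    Three-state GLM-HMM: per-state Bernoulli GLM over signed-contrast
    stimulus, bias, previous choice, and win-stay-lose-switch regressors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, SchemaError

# --------------------------------------------------------------------------
# Model registry
# --------------------------------------------------------------------------

FOURP_RL = "4prl"
META_RL = "metarl"
HRL = "hrl"
WEBER = "weber"
GLMHMM = "glmhmm"

MODEL_IDS = (FOURP_RL, META_RL, HRL, WEBER, GLMHMM)

#: the 24 injective mappings from 3 stimuli to 4 actions, in a fixed order
WEBER_MAPPINGS: Tuple[Tuple[int, int, int], ...] = tuple(
    itertools.permutations(range(4), 3)
)

#: signed-contrast stimulus set for the two-choice perceptual task
GLMHMM_CONTRASTS = np.array(
    [-1.0, -0.5, -0.25, -0.125, -0.0625, 0.0, 0.0625, 0.125, 0.25, 0.5, 1.0]
)


@dataclass(frozen=True)
class ModelSpec:
    """Static description of one cognitive model's interface."""

    model_id: str
    param_names: Tuple[str, ...]
    bounds: Mapping[str, Tuple[float, float]]
    stimulus_dim: int      # width of the per-trial stimulus coding
    input_dim: int         # width of the encoded observable row [a, r, s...]
    n_actions: int
    cont_channels: int     # continuous latent channels (0 or 1)
    n_states: Optional[int]  # discrete latent space size, None if absent


def _glmhmm_names() -> Tuple[str, ...]:
    names = []
    for k in range(3):
        for reg in ("stim", "bias", "prevc", "wsls"):
            names.append(f"w{k}_{reg}")
    for i in range(3):
        for j in range(3):
            names.append(f"a{i}{j}")
    return tuple(names)


MODEL_SPECS: Dict[str, ModelSpec] = {
    FOURP_RL: ModelSpec(
        FOURP_RL,
        ("alpha_pos", "alpha_neg", "beta", "kappa"),
        {"alpha_pos": (0, 1), "alpha_neg": (0, 1), "beta": (0, 10), "kappa": (-1, 1)},
        stimulus_dim=0, input_dim=2, n_actions=2, cont_channels=1, n_states=None,
    ),
    META_RL: ModelSpec(
        META_RL,
        ("alpha_pos", "alpha_neg", "beta", "kappa", "forget", "bias",
         "p_stay_engaged", "p_stay_random", "p_engaged0"),
        {"alpha_pos": (0, 1), "alpha_neg": (0, 1), "beta": (0, 10),
         "kappa": (-1, 1), "forget": (0, 1), "bias": (0, 1),
         "p_stay_engaged": (0, 1), "p_stay_random": (0, 1), "p_engaged0": (0, 1)},
        stimulus_dim=0, input_dim=2, n_actions=2, cont_channels=1, n_states=2,
    ),
    HRL: ModelSpec(
        HRL,
        ("alpha", "beta"),
        {"alpha": (0, 1), "beta": (0, 10)},
        stimulus_dim=3, input_dim=5, n_actions=2, cont_channels=1, n_states=3,
    ),
    WEBER: ModelSpec(
        WEBER,
        ("mu", "lam", "select_beta"),
        {"mu": (0, 1), "lam": (0, 2), "select_beta": (0, 20)},
        stimulus_dim=7, input_dim=9, n_actions=4, cont_channels=1, n_states=24,
    ),
    GLMHMM: ModelSpec(
        GLMHMM,
        _glmhmm_names(),
        {**{f"w{k}_{r}": (-10.0, 10.0)
            for k in range(3) for r in ("stim", "bias", "prevc", "wsls")},
         **{f"a{i}{j}": (0.0, 1.0) for i in range(3) for j in range(3)}},
        stimulus_dim=1, input_dim=3, n_actions=2, cont_channels=0, n_states=3,
    ),
}


def get_spec(model_id: str) -> ModelSpec:
    try:
        return MODEL_SPECS[model_id]
    except KeyError:
        raise InvalidInputError(
            f"unknown model {model_id!r}; expected one of {MODEL_IDS}"
        ) from None


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """A named, bounded, time-invariant parameter vector for one model."""

    model_id: str
    values: Dict[str, float]

    def __post_init__(self) -> None:
        spec = get_spec(self.model_id)
        missing = set(spec.param_names) - set(self.values)
        extra = set(self.values) - set(spec.param_names)
        if missing or extra:
            raise InvalidParameterError(
                f"{self.model_id}: parameter names mismatch "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
            )
        for name, v in self.values.items():
            lo, hi = spec.bounds[name]
            if not (lo <= v <= hi):
                raise InvalidParameterError(
                    f"{self.model_id}: {name}={v} outside [{lo}, {hi}]"
                )
        if self.model_id == GLMHMM:
            A = self.transition_matrix()
            if not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
                raise InvalidParameterError(
                    "glmhmm: transition-matrix rows must sum to 1"
                )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        spec = get_spec(self.model_id)
        return np.array([self.values[n] for n in spec.param_names], dtype=float)

    @classmethod
    def from_array(cls, model_id: str, arr: Sequence[float]) -> "ModelParameters":
        spec = get_spec(model_id)
        if len(arr) != len(spec.param_names):
            raise InvalidParameterError(
                f"{model_id}: expected {len(spec.param_names)} values, got {len(arr)}"
            )
        return cls(model_id, dict(zip(spec.param_names, map(float, arr))))

    # GLM-HMM conveniences
    def glm_weights(self) -> np.ndarray:
        """3 x 4 weight matrix, rows = states, cols = (stim, bias, prevc, wsls)."""
        return np.array(
            [[self.values[f"w{k}_{r}"] for r in ("stim", "bias", "prevc", "wsls")]
             for k in range(3)]
        )

    def transition_matrix(self) -> np.ndarray:
        return np.array(
            [[self.values[f"a{i}{j}"] for j in range(3)] for i in range(3)]
        )


@dataclass
class TaskConfig:
    """Task-environment settings for one model's benchmark task."""

    model_id: str
    n_trials: int = 720
    reward_prob_high: float = 0.8
    reward_prob_low: float = 0.2
    reversal_prob: float = 0.02
    mapping_shift_prob: float = 0.03
    stimulus_dim: int = field(default=-1)

    def __post_init__(self) -> None:
        spec = get_spec(self.model_id)
        if self.stimulus_dim == -1:
            self.stimulus_dim = spec.stimulus_dim
        if self.stimulus_dim != spec.stimulus_dim:
            raise InvalidInputError(
                f"{self.model_id}: stimulus_dim must be {spec.stimulus_dim}"
            )
        if self.n_trials < 1:
            raise InvalidInputError("n_trials must be >= 1")
        for p in (self.reward_prob_high, self.reward_prob_low,
                  self.reversal_prob, self.mapping_shift_prob):
            if not (0.0 <= p <= 1.0):
                raise InvalidInputError(f"probability {p} outside [0, 1]")


def default_task(model_id: str, n_trials: int = 720) -> TaskConfig:
    """Benchmark task configuration for a model.

    The HRL correct arrow resamples at the same 3% per-trial volatility as
    the task-set environment; the bandit tasks reverse at 2% per trial with
    0.8/0.2 reward probabilities.
    """
    if model_id == HRL:
        return TaskConfig(model_id, n_trials=n_trials, reversal_prob=0.03)
    return TaskConfig(model_id, n_trials=n_trials)


@dataclass
class BehavioralSession:
    """One agent's observable sequence Y over T trials."""

    agent_id: str
    stimuli: np.ndarray   # T x stimulus_dim (may have 0 columns)
    actions: np.ndarray   # T ints
    rewards: np.ndarray   # T ints in {0, 1}
    model_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.stimuli = np.asarray(self.stimuli, dtype=float)
        self.actions = np.asarray(self.actions, dtype=int)
        self.rewards = np.asarray(self.rewards, dtype=int)
        T = len(self.actions)
        if self.stimuli.ndim == 1:
            self.stimuli = self.stimuli.reshape(T, -1) if T else self.stimuli.reshape(0, 1)
        if self.stimuli.shape[0] != T or len(self.rewards) != T:
            raise SchemaError("stimuli, actions and rewards must share length T")
        if self.model_id is not None:
            spec = get_spec(self.model_id)
            if self.stimuli.shape[1] != spec.stimulus_dim:
                raise SchemaError(
                    f"{self.model_id}: stimulus width {self.stimuli.shape[1]} "
                    f"!= {spec.stimulus_dim}"
                )
            if T and (self.actions.min() < 0 or self.actions.max() >= spec.n_actions):
                raise SchemaError(
                    f"{self.model_id}: actions outside 0..{spec.n_actions - 1}"
                )

    @property
    def n_trials(self) -> int:
        return len(self.actions)


@dataclass
class LatentTrajectory:
    """Per-trial latent values Z aligned with a session."""

    continuous: np.ndarray          # T x C (C may be 0)
    discrete: Optional[np.ndarray]  # T ints or None
    state_space_size: int = 0

    def __post_init__(self) -> None:
        self.continuous = np.asarray(self.continuous, dtype=float)
        if self.continuous.ndim == 1:
            self.continuous = self.continuous[:, None]
        if self.discrete is not None:
            self.discrete = np.asarray(self.discrete, dtype=int)
            if self.state_space_size <= 0:
                raise SchemaError("state_space_size required with discrete labels")
            if len(self.discrete) and (
                self.discrete.min() < 0 or self.discrete.max() >= self.state_space_size
            ):
                raise SchemaError("discrete labels outside 0..M-1")


# --------------------------------------------------------------------------
# Elementary update rules
# --------------------------------------------------------------------------

def qvalue_update(q: float, r: float, alpha: float) -> Tuple[float, float]:
    """Delta-rule update of the chosen action's value.

    Returns ``(updated_value, rpe)`` with ``rpe = r - q`` and
    ``updated = q + alpha * rpe``.
    """
    if not (0.0 <= alpha <= 1.0):
        raise InvalidParameterError(f"learning rate {alpha} outside [0, 1]")
    rpe = r - q
    return q + alpha * rpe, rpe


def softmax_policy(values: Sequence[float], beta: float) -> np.ndarray:
    """Softmax choice probabilities over action/cue values.

    ``beta`` is the inverse temperature: 0 gives the uniform policy, large
    values approach the argmax. Shift-invariant and numerically stable.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidInputError("softmax_policy requires a non-empty value vector")
    if beta < 0:
        raise InvalidParameterError(f"inverse temperature {beta} must be >= 0")
    z = beta * v
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _softmax_logits(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


# --------------------------------------------------------------------------
# Simulators
# --------------------------------------------------------------------------

def _check_params(params: ModelParameters, model_id: str) -> None:
    if params.model_id != model_id:
        raise InvalidParameterError(
            f"expected {model_id} parameters, got {params.model_id}"
        )


def simulate_4prl(
    params: ModelParameters, task: TaskConfig, rng: np.random.Generator
) -> Tuple[BehavioralSession, LatentTrajectory]:
    """Four-parameter RL in the two-armed probabilistic-reversal bandit.

    The continuous latent channel is the chosen action's Q-value *before*
    the trial's update, so that ``rpe = r - Q_t(a_t)``.
    """
    _check_params(params, FOURP_RL)
    T = task.n_trials
    a_pos, a_neg = params["alpha_pos"], params["alpha_neg"]
    beta, kappa = params["beta"], params["kappa"]

    Q = np.array([0.5, 0.5])
    correct = int(rng.integers(2))
    prev_a = -1
    actions = np.empty(T, dtype=int)
    rewards = np.empty(T, dtype=int)
    chosen_q = np.empty(T)
    for t in range(T):
        if t > 0 and rng.random() < task.reversal_prob:
            correct = 1 - correct
        logits = beta * Q
        if prev_a >= 0:
            logits = logits.copy()
            logits[prev_a] += kappa
        p = _softmax_logits(logits)
        a = int(rng.random() < p[1])
        p_r = task.reward_prob_high if a == correct else task.reward_prob_low
        r = int(rng.random() < p_r)
        chosen_q[t] = Q[a]
        delta = r - Q[a]
        Q[a] += (a_pos if delta >= 0 else a_neg) * delta
        actions[t] = a
        rewards[t] = r
        prev_a = a

    session = BehavioralSession("0", np.empty((T, 0)), actions, rewards, FOURP_RL)
    latents = LatentTrajectory(chosen_q, None)
    return session, latents


def simulate_metarl(
    params: ModelParameters, task: TaskConfig, rng: np.random.Generator
) -> Tuple[BehavioralSession, LatentTrajectory]:
    """Meta RL: Q-learning gated by a 2-state attentive HMM.

    In the engaged state (label 0) actions follow the sticky softmax over
    Q-values; in the random state (label 1) actions are drawn from a fixed
    biased coin that ignores the Q-values. Value updates (asymmetric
    learning rates for the chosen action, forgetting toward 0.5 for the
    unchosen action) run in both states.
    """
    _check_params(params, META_RL)
    T = task.n_trials
    a_pos, a_neg = params["alpha_pos"], params["alpha_neg"]
    beta, kappa = params["beta"], params["kappa"]
    forget, bias = params["forget"], params["bias"]
    stay = (params["p_stay_engaged"], params["p_stay_random"])

    Q = np.array([0.5, 0.5])
    correct = int(rng.integers(2))
    state = 0 if rng.random() < params["p_engaged0"] else 1
    prev_a = -1
    actions = np.empty(T, dtype=int)
    rewards = np.empty(T, dtype=int)
    chosen_q = np.empty(T)
    states = np.empty(T, dtype=int)
    for t in range(T):
        if t > 0:
            if rng.random() >= stay[state]:
                state = 1 - state
            if rng.random() < task.reversal_prob:
                correct = 1 - correct
        if state == 0:
            logits = beta * Q
            if prev_a >= 0:
                logits = logits.copy()
                logits[prev_a] += kappa
            p1 = _softmax_logits(logits)[1]
        else:
            p1 = bias
        a = int(rng.random() < p1)
        p_r = task.reward_prob_high if a == correct else task.reward_prob_low
        r = int(rng.random() < p_r)
        chosen_q[t] = Q[a]
        states[t] = state
        delta = r - Q[a]
        Q[a] += (a_pos if delta >= 0 else a_neg) * delta
        Q[1 - a] += forget * (0.5 - Q[1 - a])
        actions[t] = a
        rewards[t] = r
        prev_a = a

    session = BehavioralSession("0", np.empty((T, 0)), actions, rewards, META_RL)
    latents = LatentTrajectory(chosen_q, states, state_space_size=2)
    return session, latents


def simulate_hrl(
    params: ModelParameters, task: TaskConfig, rng: np.random.Generator
) -> Tuple[BehavioralSession, LatentTrajectory]:
    """Hierarchical RL in the three-arrow task.

    Each trial the three arrows point left (0) or right (1) independently.
    The agent samples an arrow by softmax over the three arrow Q-values,
    deterministically emits that arrow's side, and is rewarded iff the
    emitted side equals the currently correct arrow's side. Only the
    chosen arrow's value is updated. The chosen arrow itself is the
    discrete latent; its pre-update Q-value is the continuous latent.
    """
    _check_params(params, HRL)
    T = task.n_trials
    alpha, beta = params["alpha"], params["beta"]

    Q = np.full(3, 0.5)
    correct = int(rng.integers(3))
    actions = np.empty(T, dtype=int)
    rewards = np.empty(T, dtype=int)
    stimuli = np.empty((T, 3))
    chosen_q = np.empty(T)
    arrows = np.empty(T, dtype=int)
    for t in range(T):
        if t > 0 and rng.random() < task.reversal_prob:
            correct = int(rng.integers(3))
        dirs = rng.integers(0, 2, size=3)
        p = _softmax_logits(beta * Q)
        arrow = int(rng.choice(3, p=p))
        a = int(dirs[arrow])
        r = int(a == dirs[correct])
        chosen_q[t] = Q[arrow]
        Q[arrow] += alpha * (r - Q[arrow])
        stimuli[t] = dirs
        actions[t] = a
        rewards[t] = r
        arrows[t] = arrow

    session = BehavioralSession("0", stimuli, actions, rewards, HRL)
    latents = LatentTrajectory(chosen_q, arrows, state_space_size=3)
    return session, latents


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(q[mask]))))


def weber_predict(belief: np.ndarray, hazard: float) -> np.ndarray:
    """Change-point prediction step: mix the posterior toward uniform."""
    return (1.0 - hazard) * belief + hazard / 24.0


def weber_condition(belief: np.ndarray, s: int, a: int, r: int) -> np.ndarray:
    """Condition the task-set belief on one (stimulus, action, reward)
    triple under the deterministic reward rule r = 1{mapping(s) = a}."""
    like = np.array(
        [1.0 if (m[s] == a) == bool(r) else 0.0 for m in WEBER_MAPPINGS]
    )
    post = belief * like
    total = post.sum()
    if total <= 0:  # cannot happen after a predict step, guard anyway
        return np.full(24, 1.0 / 24.0)
    return post / total


def weber_belief_update(
    belief: np.ndarray, s: int, a: int, r: int, hazard: float
) -> np.ndarray:
    """One full Bayes step: hazard prediction followed by conditioning."""
    return weber_condition(weber_predict(belief, hazard), s, a, r)


def weber_noisy_update(
    belief: np.ndarray, s: int, a: int, r: int, hazard: float,
    mu: float, lam: float, rng: np.random.Generator,
) -> Tuple[np.ndarray, float, float]:
    """One noisy-inference step of the task-set learner.

    ``belief`` is the belief held while acting (hazard already applied,
    hence strictly positive). The exact update conditions on the trial's
    observation and re-applies the change hazard; ``d`` is the KL
    divergence from the pre-update to the post-update belief, the
    Weber-scaled noise amplitude is ``eps ~ Uniform(0, mu + lam * d)``,
    and the log-posterior is perturbed by i.i.d. Gaussian noise of that
    standard deviation. Returns ``(noisy posterior, d, eps)``.
    """
    exact = weber_predict(weber_condition(belief, s, a, r), hazard)
    d = _kl(belief, exact)
    cap = mu + lam * d
    eps = rng.uniform(0.0, cap) if cap > 0 else 0.0
    if eps > 0:
        logb = np.log(np.maximum(exact, 1e-300)) + rng.normal(0.0, eps, 24)
        logb -= logb.max()
        noisy = np.exp(logb)
        noisy /= noisy.sum()
    else:
        noisy = exact
    return noisy, d, eps


def simulate_weber(
    params: ModelParameters, task: TaskConfig, rng: np.random.Generator
) -> Tuple[BehavioralSession, LatentTrajectory]:
    """Weber-imprecision task-set learner (3 stimuli -> 4 actions).

    The agent performs noisy Bayesian inference over the 24 injective
    stimulus->action mappings (3% change hazard): after each exact Bayes
    update the log-posterior is corrupted by Gaussian noise whose
    amplitude ``eps_t`` is uniform on ``(0, mu + lam * d_t)``, where
    ``d_t`` is the Kullback-Leibler distance between the posterior
    beliefs on consecutive trials - imprecision scales with the size of
    the belief update, after Weber's law. Each trial the agent selects a
    mapping from the sharpened current belief
    ``P(m) propto b(m)**select_beta`` and emits that mapping's action for
    the shown stimulus. The continuous latent is ``d_t`` (0 on the first
    trial); the discrete latent is the selected mapping.

    Stimuli are recorded as 7-wide one-hot rows: the three task stimuli
    occupy three of seven slots, assigned at random per agent (stimulus s
    is the s-th smallest active slot, so the identity is recoverable
    from the coding alone).
    """
    _check_params(params, WEBER)
    T = task.n_trials
    mu, lam, sbeta = params["mu"], params["lam"], params["select_beta"]
    h = task.mapping_shift_prob

    slots = np.sort(rng.choice(7, size=3, replace=False))
    true_map = int(rng.integers(24))
    belief = np.full(24, 1.0 / 24.0)   # belief held while acting on trial t
    actions = np.empty(T, dtype=int)
    rewards = np.empty(T, dtype=int)
    stimuli = np.zeros((T, 7))
    dist = np.empty(T)
    chosen = np.empty(T, dtype=int)
    d_next = 0.0
    for t in range(T):
        if t > 0 and rng.random() < h:
            true_map = int(rng.integers(24))
        sel = belief ** sbeta
        sel = sel / sel.sum()
        m = int(rng.choice(24, p=sel))
        s = int(rng.integers(3))
        a = WEBER_MAPPINGS[m][s]
        r = int(a == WEBER_MAPPINGS[true_map][s])
        stimuli[t, slots[s]] = 1.0
        actions[t] = a
        rewards[t] = r
        dist[t] = d_next
        chosen[t] = m
        belief, d_next, _ = weber_noisy_update(
            belief, s, a, r, h, mu, lam, rng)

    session = BehavioralSession("0", stimuli, actions, rewards, WEBER)
    latents = LatentTrajectory(dist, chosen, state_space_size=24)
    return session, latents


def glmhmm_regressors(
    stimuli: np.ndarray, actions: np.ndarray, rewards: np.ndarray
) -> np.ndarray:
    """T x 4 design matrix: signed stimulus, bias, previous choice (+-1),
    win-stay-lose-switch (previous choice signed by previous reward).
    History terms are 0 on the first trial."""
    s = np.asarray(stimuli, dtype=float).reshape(len(actions), -1)[:, 0]
    T = len(actions)
    X = np.zeros((T, 4))
    X[:, 0] = s
    X[:, 1] = 1.0
    if T > 1:
        prevc = 2.0 * np.asarray(actions[:-1], dtype=float) - 1.0
        prevr = 2.0 * np.asarray(rewards[:-1], dtype=float) - 1.0
        X[1:, 2] = prevc
        X[1:, 3] = prevc * prevr
    return X


def simulate_glmhmm(
    params: ModelParameters, task: TaskConfig, rng: np.random.Generator
) -> Tuple[BehavioralSession, LatentTrajectory]:
    """Three-state GLM-HMM in the two-choice perceptual task.

    A hidden 3-state Markov chain (uniform initial distribution) selects
    which Bernoulli GLM generates the choice on each trial. Stimuli are
    signed contrasts drawn uniformly from a symmetric set; reward is 1 when
    the choice matches the stimulus side (coin flip at zero contrast).
    """
    _check_params(params, GLMHMM)
    T = task.n_trials
    W = params.glm_weights()
    A = params.transition_matrix()

    z = int(rng.integers(3))
    prev_a, prev_r = None, None
    actions = np.empty(T, dtype=int)
    rewards = np.empty(T, dtype=int)
    stimuli = np.empty((T, 1))
    states = np.empty(T, dtype=int)
    for t in range(T):
        if t > 0:
            z = int(rng.choice(3, p=A[z]))
        s = float(rng.choice(GLMHMM_CONTRASTS))
        x = np.array([
            s, 1.0,
            0.0 if prev_a is None else 2.0 * prev_a - 1.0,
            0.0 if prev_a is None else (2.0 * prev_a - 1.0) * (2.0 * prev_r - 1.0),
        ])
        p1 = 1.0 / (1.0 + np.exp(-float(W[z] @ x)))
        a = int(rng.random() < p1)
        if s > 0:
            correct = 1
        elif s < 0:
            correct = 0
        else:
            correct = int(rng.integers(2))
        r = int(a == correct)
        stimuli[t, 0] = s
        actions[t] = a
        rewards[t] = r
        states[t] = z
        prev_a, prev_r = a, r

    session = BehavioralSession("0", stimuli, actions, rewards, GLMHMM)
    latents = LatentTrajectory(np.empty((T, 0)), states, state_space_size=3)
    return session, latents


SIMULATORS = {
    FOURP_RL: simulate_4prl,
    META_RL: simulate_metarl,
    HRL: simulate_hrl,
    WEBER: simulate_weber,
    GLMHMM: simulate_glmhmm,
}


def simulate(
    model_id: str,
    params: ModelParameters,
    task: TaskConfig,
    rng: np.random.Generator,
    agent_id: str = "0",
) -> Tuple[BehavioralSession, LatentTrajectory]:
    """Dispatch to the model's simulator and stamp the agent id."""
    session, latents = SIMULATORS[get_spec(model_id).model_id](params, task, rng)
    session.agent_id = str(agent_id)
    return session, latents
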