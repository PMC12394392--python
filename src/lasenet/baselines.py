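"""Likelihood-dependent comparator estimators.

For the tractable bandit models (4P-RL, Meta RL) the latent Q-trajectory
is a deterministic function of the observed actions and rewards, so the
likelihood is available in closed form (softmax policy, with a 2-state
forward algorithm for Meta RL) and latents are recovered by fitting theta
(MLE/MAP) and replaying the model. For the intractable models the package
provides a known-parameter particle filter (HRL, Weber) and an EM fitter
(GLM-HMM), plus exact path-enumeration oracles used to validate them at
small T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from . import models as cm
from .datasets import PriorSpec
from .errors import (
    EMFailureError,
    FilterDegeneracyError,
    InvalidParameterError,
    SchemaError,
    UnsupportedOperationError,
)

# --------------------------------------------------------------------------
# Deterministic replay of the bandit learners
# --------------------------------------------------------------------------

def _replay_bandit(params: cm.ModelParameters, actions: np.ndarray,
                   rewards: np.ndarray) -> np.ndarray:
    """Pre-update Q-values (T x 2) along an observed bandit session.

    Updates use the asymmetric learning rates; for Meta RL the unchosen
    action additionally decays toward 0.5 at the forgetting rate.
    """
    a_pos, a_neg = params["alpha_pos"], params["alpha_neg"]
    forget = params.values.get("forget", 0.0)
    T = len(actions)
    Q = np.array([0.5, 0.5])
    out = np.empty((T, 2))
    for t in range(T):
        out[t] = Q
        a, r = actions[t], rewards[t]
        delta = r - Q[a]
        Q[a] += (a_pos if delta >= 0 else a_neg) * delta
        if forget:
            Q[1 - a] += forget * (0.5 - Q[1 - a])
    return out


def _policy_logp(params: cm.ModelParameters, Q: np.ndarray,
                 actions: np.ndarray) -> np.ndarray:
    """Per-trial log probability of the observed action under the sticky
    softmax policy (T-vector)."""
    beta, kappa = params["beta"], params.values.get("kappa", 0.0)
    T = len(actions)
    logits = beta * Q
    if T > 1:
        logits[np.arange(1, T), actions[:-1]] += kappa
    logits -= logits.max(axis=1, keepdims=True)
    logp = logits - np.log(np.exp(logits).sum(axis=1))[:, None]
    return logp[np.arange(T), actions]


def loglik_4prl(params: cm.ModelParameters, session: cm.BehavioralSession) -> float:
    """Exact log-likelihood of a two-armed bandit session under 4P-RL."""
    if session.n_trials == 0:
        raise SchemaError("empty session")
    Q = _replay_bandit(params, session.actions, session.rewards)
    return float(_policy_logp(params, Q, session.actions).sum())


def _metarl_emission_logp(params: cm.ModelParameters,
                          session: cm.BehavioralSession) -> np.ndarray:
    """T x 2 per-trial action log-probabilities for (engaged, random)."""
    Q = _replay_bandit(params, session.actions, session.rewards)
    engaged = _policy_logp(params, Q, session.actions)
    bias = params["bias"]
    p1 = np.clip(bias, 1e-12, 1 - 1e-12)
    random = np.where(session.actions == 1, np.log(p1), np.log(1 - p1))
    return np.stack([engaged, random], axis=1)


def _metarl_chain(params: cm.ModelParameters) -> Tuple[np.ndarray, np.ndarray]:
    pe, pr = params["p_stay_engaged"], params["p_stay_random"]
    A = np.array([[pe, 1 - pe], [1 - pr, pr]])
    pi = np.array([params["p_engaged0"], 1 - params["p_engaged0"]])
    return A, pi


def _forward_backward(log_emit: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward. Returns (loglik, gamma (T,K), xi_sum (K,K))."""
    T, K = log_emit.shape
    emit = np.exp(log_emit - log_emit.max(axis=1, keepdims=True))
    shift = log_emit.max(axis=1)
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * emit[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * emit[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (emit[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        xi = (alpha[t][:, None] * A) * (emit[t + 1] * beta[t + 1])[None, :]
        xi_sum += xi / xi.sum()
    loglik = float(np.log(c).sum() + shift.sum())
    return loglik, gamma, xi_sum


def _forward_backward_batch(log_emit: np.ndarray, A: np.ndarray,
                            pi: np.ndarray):
    """Scaled forward-backward over a stack of equal-length sessions.

    ``log_emit`` is (S, T, K). Returns (loglik (S,), gamma (S, T, K),
    xi_sum (K, K) accumulated over sessions and trials).
    """
    S, T, K = log_emit.shape
    shift = log_emit.max(axis=2)
    emit = np.exp(log_emit - shift[:, :, None])
    alpha = np.empty((S, T, K))
    c = np.empty((S, T))
    a = pi[None, :] * emit[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * emit[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    beta = np.empty((S, T, K))
    beta[:, -1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t] = ((emit[:, t + 1] * beta[:, t + 1]) @ A.T) / c[:, t + 1, None]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        xi = (alpha[:, t, :, None] * A[None]) * (
            emit[:, t + 1] * beta[:, t + 1])[:, None, :]
        xi /= xi.sum(axis=(1, 2))[:, None, None]
        xi_sum += xi.sum(axis=0)
    loglik = np.log(c).sum(axis=1) + shift.sum(axis=1)
    return loglik, gamma, xi_sum


def loglik_metarl(params: cm.ModelParameters, session: cm.BehavioralSession) -> float:
    """Forward-algorithm log-likelihood marginalizing the attentive state."""
    if session.n_trials == 0:
        raise SchemaError("empty session")
    log_emit = _metarl_emission_logp(params, session)
    A, pi = _metarl_chain(params)
    loglik, _, _ = _forward_backward(log_emit, A, pi)
    return loglik


def metarl_state_posterior(params: cm.ModelParameters,
                           session: cm.BehavioralSession) -> np.ndarray:
    """Smoothed per-trial attentive-state posterior (T x 2, rows sum 1)."""
    log_emit = _metarl_emission_logp(params, session)
    A, pi = _metarl_chain(params)
    _, gamma, _ = _forward_backward(log_emit, A, pi)
    return gamma


# --------------------------------------------------------------------------
# MLE / MAP fitting of the tractable models
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """Best parameter estimate for one session, with optimizer diagnostics."""

    params: cm.ModelParameters
    objective: float              # maximized log-likelihood / log-posterior
    n_restarts: int
    converged: bool
    restart_objectives: List[float] = field(default_factory=list)


_LOGLIKS = {cm.FOURP_RL: loglik_4prl, cm.META_RL: loglik_metarl}


def _log_prior(prior: PriorSpec, params: cm.ModelParameters) -> float:
    from scipy.stats import beta as beta_dist, norm
    total = 0.0
    for name, dist in prior.dists.items():
        v = params[name]
        kind = dist[0]
        if kind == "uniform":
            lo, hi = dist[1], dist[2]
            total += -np.inf if not (lo <= v <= hi) else -np.log(hi - lo)
        elif kind == "beta":
            a, b, lo, hi = dist[1:]
            x = (v - lo) / (hi - lo)
            total += beta_dist.logpdf(x, a, b) - np.log(hi - lo)
        elif kind == "normal":
            total += norm.logpdf(v, dist[1], dist[2])
    return float(total)


def _fit(model_id: str, session: cm.BehavioralSession, n_restarts: int,
         rng: np.random.Generator, prior: Optional[PriorSpec]) -> FitResult:
    if model_id not in _LOGLIKS:
        raise UnsupportedOperationError(
            f"likelihood fitting is only defined for {sorted(_LOGLIKS)}")
    if session.n_trials == 0:
        raise SchemaError("cannot fit an empty session")
    spec = cm.get_spec(model_id)
    names = spec.param_names
    bounds = [spec.bounds[n] for n in names]
    # shrink the box slightly so boundary values stay valid parameters
    eps = 1e-6
    opt_bounds = [(lo + eps * (hi - lo), hi - eps * (hi - lo))
                  for lo, hi in bounds]
    loglik = _LOGLIKS[model_id]

    def objective(x: np.ndarray) -> float:
        p = cm.ModelParameters(model_id, dict(zip(names, map(float, x))))
        val = loglik(p, session)
        if prior is not None:
            val += _log_prior(prior, p)
        return -val if np.isfinite(val) else 1e12

    best_x, best_val, any_success = None, np.inf, False
    restart_objectives = []
    for _ in range(max(1, n_restarts)):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in opt_bounds])
        res = minimize(objective, x0, method="L-BFGS-B", bounds=opt_bounds)
        restart_objectives.append(-float(res.fun))
        any_success = any_success or bool(res.success)
        if res.fun < best_val:
            best_val, best_x = float(res.fun), res.x
    theta = cm.ModelParameters(model_id, dict(zip(names, map(float, best_x))))
    return FitResult(theta, -best_val, max(1, n_restarts), any_success,
                     restart_objectives)


def fit_mle(model_id: str, session: cm.BehavioralSession,
            n_restarts: int = 10,
            rng: Optional[np.random.Generator] = None) -> FitResult:
    """Multi-start bounded maximum-likelihood fit (4P-RL, Meta RL)."""
    return _fit(model_id, session, n_restarts,
                rng or np.random.default_rng(0), None)


def fit_map(model_id: str, session: cm.BehavioralSession, prior: PriorSpec,
            n_restarts: int = 10,
            rng: Optional[np.random.Generator] = None) -> FitResult:
    """Maximum a posteriori fit: adds the log-prior to the objective."""
    return _fit(model_id, session, n_restarts,
                rng or np.random.default_rng(0), prior)


def derive_latents(model_id: str, theta: cm.ModelParameters,
                   session: cm.BehavioralSession) -> cm.LatentTrajectory:
    """Replay a tractable model over the observed sequence with fixed theta.

    4P-RL yields the chosen-action Q-value channel; Meta RL additionally
    yields the forward-backward attentive-state posterior, with the label
    sequence taken as its per-trial argmax.
    """
    if model_id == cm.FOURP_RL:
        Q = _replay_bandit(theta, session.actions, session.rewards)
        chosen = Q[np.arange(session.n_trials), session.actions]
        return cm.LatentTrajectory(chosen, None)
    if model_id == cm.META_RL:
        Q = _replay_bandit(theta, session.actions, session.rewards)
        chosen = Q[np.arange(session.n_trials), session.actions]
        gamma = metarl_state_posterior(theta, session)
        return cm.LatentTrajectory(chosen, gamma.argmax(axis=1),
                                   state_space_size=2)
    raise UnsupportedOperationError(
        f"{model_id}: latents are not a deterministic replay; "
        "use particle_filter or glmhmm_em")


# --------------------------------------------------------------------------
# Particle filtering for the intractable models (known theta)
# --------------------------------------------------------------------------

@dataclass
class ParticleFilterConfig:
    n_particles: int = 2000
    resample_threshold: float = 0.5   # ESS fraction triggering resampling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise InvalidParameterError("n_particles must be >= 2")
        if not (0.0 < self.resample_threshold <= 1.0):
            raise InvalidParameterError("resample_threshold must be in (0, 1]")


@dataclass
class FilterResult:
    """Per-trial filtered posterior over the discrete latent plus the
    posterior-mean continuous latent."""

    state_probs: np.ndarray          # T x M
    continuous: np.ndarray           # T

    @property
    def states(self) -> np.ndarray:
        return self.state_probs.argmax(axis=1)


def _systematic_resample(weights: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    P = len(weights)
    positions = (rng.random() + np.arange(P)) / P
    return np.searchsorted(np.cumsum(weights), positions)


def _pf_hrl(theta: cm.ModelParameters, session: cm.BehavioralSession,
            cfg: ParticleFilterConfig) -> FilterResult:
    alpha, beta = theta["alpha"], theta["beta"]
    P = cfg.n_particles
    rng = np.random.default_rng(cfg.seed)
    T = session.n_trials
    Q = np.full((P, 3), 0.5)
    logw = np.zeros(P)
    probs_out = np.empty((T, 3))
    cont_out = np.empty(T)
    for t in range(T):
        dirs = session.stimuli[t].astype(int)
        a, r = int(session.actions[t]), int(session.rewards[t])
        logits = beta * Q
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        p_arrow = e / e.sum(axis=1, keepdims=True)        # P x 3
        consistent = (dirs == a)                           # 3 bools
        if not consistent.any():
            raise FilterDegeneracyError(t)
        # marginal proposal: weight by the consistent mass, sample within it
        mass = p_arrow[:, consistent].sum(axis=1)
        if not (mass > 0).any():
            raise FilterDegeneracyError(t)
        cond = p_arrow * consistent[None, :]
        cond = cond / np.clip(mass, 1e-300, None)[:, None]
        u = rng.random(P)
        arrows = (u[:, None] > np.cumsum(cond, axis=1)).sum(axis=1)
        arrows = np.clip(arrows, 0, 2)
        logw = logw + np.log(np.clip(mass, 1e-300, None))
        w = np.exp(logw - logw.max())
        w_sum = w.sum()
        if w_sum == 0 or not np.isfinite(w_sum):
            raise FilterDegeneracyError(t)
        w = w / w_sum
        probs_out[t] = np.bincount(arrows, weights=w, minlength=3)
        cont_out[t] = float((w * Q[np.arange(P), arrows]).sum())
        Q[np.arange(P), arrows] += alpha * (r - Q[np.arange(P), arrows])
        ess = 1.0 / (w ** 2).sum()
        if ess < cfg.resample_threshold * P:
            idx = _systematic_resample(w, rng)
            Q = Q[idx]
            logw = np.zeros(P)
    return FilterResult(probs_out, cont_out)


def weber_stimulus_indices(session: cm.BehavioralSession) -> np.ndarray:
    """Recover the stimulus identity (0..2) from the 7-wide one-hot rows."""
    slots = np.flatnonzero(session.stimuli.any(axis=0))
    if len(slots) > 3:
        raise SchemaError("more than 3 active stimulus slots")
    hot = session.stimuli.argmax(axis=1)
    return np.searchsorted(slots, hot)


def weber_belief_trajectory(
    session: cm.BehavioralSession, hazard: float = 0.03
) -> Tuple[np.ndarray, np.ndarray]:
    """Noise-free Bayesian replay of a task-set session.

    Returns the exact per-trial beliefs (T x 24, the belief held while
    acting on trial t, hazard applied) and the consecutive-belief KL
    update distances d (T,), d_1 = 0. This is the mu = lam = 0 limit of
    the generative model.
    """
    s_idx = weber_stimulus_indices(session)
    T = session.n_trials
    beliefs = np.empty((T, 24))
    d = np.zeros(T)
    belief = np.full(24, 1.0 / 24.0)
    for t in range(T):
        beliefs[t] = belief
        nxt = cm.weber_predict(
            cm.weber_condition(belief, int(s_idx[t]),
                               int(session.actions[t]),
                               int(session.rewards[t])), hazard)
        if t + 1 < T:
            d[t + 1] = cm._kl(belief, nxt)
        belief = nxt
    return beliefs, d


def _pf_weber(theta: cm.ModelParameters, session: cm.BehavioralSession,
              cfg: ParticleFilterConfig, hazard: float = 0.03) -> FilterResult:
    """Particles carry the agent's noisy belief over the 24 mappings.

    Each step: the mapping choice is Rao-Blackwellized (the incremental
    weight is the selection-distribution mass on the action-consistent
    mappings, and the per-trial mapping posterior mixes each particle's
    conditional), then every particle performs the noisy inference update
    with its own sampled Weber-scaled noise.
    """
    mu, lam, sbeta = theta["mu"], theta["lam"], theta["select_beta"]
    P = cfg.n_particles
    rng = np.random.default_rng(cfg.seed)
    T = session.n_trials
    s_idx = weber_stimulus_indices(session)
    map_of = np.array(cm.WEBER_MAPPINGS)                  # 24 x 3
    B = np.full((P, 24), 1.0 / 24.0)                      # beliefs
    d_p = np.zeros(P)                                     # last update dist
    logw = np.zeros(P)
    probs_out = np.empty((T, 24))
    cont_out = np.empty(T)
    for t in range(T):
        s, a, r = int(s_idx[t]), int(session.actions[t]), int(session.rewards[t])
        sel = B ** sbeta
        sel /= sel.sum(axis=1, keepdims=True)
        consistent = (map_of[:, s] == a)                  # (24,)
        mass = sel[:, consistent].sum(axis=1)
        logw = logw + np.log(np.clip(mass, 1e-300, None))
        w = np.exp(logw - logw.max())
        w_sum = w.sum()
        if w_sum == 0 or not np.isfinite(w_sum):
            raise FilterDegeneracyError(t)
        w /= w_sum
        cond = sel * consistent[None, :]
        cond /= np.clip(mass, 1e-300, None)[:, None]
        probs_out[t] = w @ cond
        cont_out[t] = float(w @ d_p)
        # noisy inference update per particle
        like = ((map_of[:, s] == a) == bool(r)).astype(float)
        post = B * like[None, :]
        post /= np.clip(post.sum(axis=1, keepdims=True), 1e-300, None)
        exact = (1.0 - hazard) * post + hazard / 24.0
        with np.errstate(divide="ignore", invalid="ignore"):
            logratio = np.where(B > 0, np.log(B) - np.log(exact), 0.0)
        d_p = np.sum(B * logratio, axis=1)
        cap = mu + lam * d_p
        eps = rng.uniform(0.0, 1.0, P) * cap
        logb = np.log(np.clip(exact, 1e-300, None))
        logb += rng.normal(0.0, 1.0, (P, 24)) * eps[:, None]
        logb -= logb.max(axis=1, keepdims=True)
        B = np.exp(logb)
        B /= B.sum(axis=1, keepdims=True)
        ess = 1.0 / (w ** 2).sum()
        if ess < cfg.resample_threshold * P:
            idx = _systematic_resample(w, rng)
            B, d_p = B[idx], d_p[idx]
            logw = np.zeros(P)
    return FilterResult(probs_out, cont_out)


def particle_filter(model_id: str, theta: cm.ModelParameters,
                    session: cm.BehavioralSession,
                    pfcfg: ParticleFilterConfig,
                    hazard: float = 0.03) -> FilterResult:
    """Known-parameter particle filtering of the intractable latents.

    HRL particles carry the arrow Q-vector along sampled arrow-choice
    histories; Weber particles carry the selected mapping on top of the
    exact Bayes belief trajectory. Proposals are the model's own choice
    distribution restricted to observation-consistent latents, with the
    consistent mass as the importance weight (the Rao-Blackwellized form
    of the bootstrap step); systematic resampling triggers when the
    effective sample size drops below ``resample_threshold * n_particles``.
    """
    if theta.model_id != model_id:
        raise InvalidParameterError(
            f"theta is for {theta.model_id!r}, filter for {model_id!r}")
    if model_id == cm.HRL:
        return _pf_hrl(theta, session, pfcfg)
    if model_id == cm.WEBER:
        return _pf_weber(theta, session, pfcfg, hazard)
    raise UnsupportedOperationError(
        "particle filtering is defined for the hrl and weber models")


# --------------------------------------------------------------------------
# Exact enumeration oracles (small T)
# --------------------------------------------------------------------------

_ENUM_LIMIT = 12


def enumerate_latent_posterior(model_id: str, theta: cm.ModelParameters,
                               session: cm.BehavioralSession):
    """Exact latent posteriors by summing over all discrete latent paths.

    For HRL returns (loglik, filtered T x 3 arrow posteriors) matching the
    particle filter's filtering distribution; for Meta RL returns
    (loglik, smoothed T x 2 state posteriors). Only feasible for small T.
    """
    T = session.n_trials
    if T > _ENUM_LIMIT:
        raise UnsupportedOperationError(
            f"enumeration over {T} trials exceeds the T <= {_ENUM_LIMIT} limit")
    if model_id == cm.HRL:
        return _enumerate_hrl(theta, session)
    if model_id == cm.META_RL:
        log_emit = _metarl_emission_logp(theta, session)
        A, pi = _metarl_chain(theta)
        return _enumerate_hmm_paths(log_emit, A, pi)
    raise UnsupportedOperationError(
        "enumeration is defined for the hrl and metarl models")


def _enumerate_hrl(theta: cm.ModelParameters, session: cm.BehavioralSession):
    alpha, beta = theta["alpha"], theta["beta"]
    T = session.n_trials
    Q = np.full((1, 3), 0.5)
    logw = np.zeros(1)
    filtered = np.empty((T, 3))
    for t in range(T):
        dirs = session.stimuli[t].astype(int)
        a, r = int(session.actions[t]), int(session.rewards[t])
        n = Q.shape[0]
        logits = beta * Q
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        p_arrow = e / e.sum(axis=1, keepdims=True)
        like = (dirs == a).astype(float)
        # branch every path over the 3 arrows
        logw = (logw[:, None] + np.log(
            np.clip(p_arrow * like[None, :], 1e-300, None))).ravel()
        arrows = np.tile(np.arange(3), n)
        Q = np.repeat(Q, 3, axis=0)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        filtered[t] = np.bincount(arrows, weights=w, minlength=3)
        Q[np.arange(3 * n), arrows] += alpha * (r - Q[np.arange(3 * n), arrows])
        # prune impossible paths to keep growth at 3^t manageable
        keep = np.isfinite(logw) & (logw > -600)
        Q, logw = Q[keep], logw[keep]
    loglik = float(logsumexp(logw)) if len(logw) else -np.inf
    return loglik, filtered


def _enumerate_hmm_paths(log_emit: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Brute-force sum over all K^T state paths: (loglik, smoothed T x K)."""
    T, K = log_emit.shape
    logA = np.log(np.clip(A, 1e-300, None))
    logpi = np.log(np.clip(pi, 1e-300, None))
    paths = np.array(np.meshgrid(*([np.arange(K)] * T),
                                 indexing="ij")).reshape(T, -1).T
    logp = logpi[paths[:, 0]] + log_emit[0, paths[:, 0]]
    for t in range(1, T):
        logp = logp + logA[paths[:, t - 1], paths[:, t]] + log_emit[t, paths[:, t]]
    loglik = float(logsumexp(logp))
    w = np.exp(logp - loglik)
    smoothed = np.stack(
        [np.bincount(paths[:, t], weights=w, minlength=K) for t in range(T)])
    return loglik, smoothed


def glmhmm_enumerated_posterior(weights: np.ndarray, A: np.ndarray,
                                pi: np.ndarray,
                                session: cm.BehavioralSession):
    """3^T enumeration oracle for GLM-HMM smoothed state posteriors."""
    log_emit = _glmhmm_log_emissions(weights, session)
    return _enumerate_hmm_paths(log_emit, A, pi)


# --------------------------------------------------------------------------
# GLM-HMM expectation-maximization
# --------------------------------------------------------------------------

def _glmhmm_log_emissions(weights: np.ndarray,
                          session: cm.BehavioralSession) -> np.ndarray:
    X = cm.glmhmm_regressors(session.stimuli, session.actions, session.rewards)
    z = X @ weights.T                                     # T x K logits
    # log Bernoulli(a | sigmoid(z)) computed stably via logaddexp
    a = session.actions[:, None]
    return np.where(a == 1, -np.logaddexp(0.0, -z), -np.logaddexp(0.0, z))


@dataclass
class GLMHMMFit:
    """EM-fitted 3-state GLM-HMM."""

    weights: np.ndarray           # K x 4
    transitions: np.ndarray       # K x K
    initial: np.ndarray           # K
    loglik_history: List[float]
    converged: bool

    def state_posteriors(self, session: cm.BehavioralSession) -> np.ndarray:
        log_emit = _glmhmm_log_emissions(self.weights, session)
        _, gamma, _ = _forward_backward(log_emit, self.transitions, self.initial)
        return gamma

    def posteriors_batch(
            self, sessions: Sequence[cm.BehavioralSession]) -> np.ndarray:
        """(S, T, K) smoothed posteriors for equal-length sessions."""
        log_emit = np.stack(
            [_glmhmm_log_emissions(self.weights, s) for s in sessions])
        _, gamma, _ = _forward_backward_batch(
            log_emit, self.transitions, self.initial)
        return gamma

    def loglik(self, session: cm.BehavioralSession) -> float:
        log_emit = _glmhmm_log_emissions(self.weights, session)
        ll, _, _ = _forward_backward(log_emit, self.transitions, self.initial)
        return ll


def _weighted_logistic_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                           w0: np.ndarray, n_iter: int = 50,
                           ridge: float = 1e-6) -> np.ndarray:
    """Weighted Bernoulli-GLM MLE by Newton iterations (tiny ridge for
    numerical stability when a state explains few trials)."""
    beta = w0.copy()
    for _ in range(n_iter):
        p = expit(X @ beta)
        g = X.T @ (w * (y - p)) - ridge * beta
        s = np.clip(w * p * (1 - p), 1e-10, None)
        H = (X * s[:, None]).T @ X + ridge * np.eye(X.shape[1])
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def glmhmm_em(sessions: Sequence[cm.BehavioralSession],
              n_states: int = 3,
              init: Optional[Dict] = None,
              max_iter: int = 100,
              tol: float = 1e-4,
              rng: Optional[np.random.Generator] = None,
              n_restarts: int = 3) -> GLMHMMFit:
    """Baum-Welch EM for the GLM-HMM.

    E-step runs forward-backward per session; the M-step re-estimates the
    transition matrix and initial distribution in closed form and each
    state's GLM weights by posterior-weighted logistic regression. The
    data log-likelihood is non-decreasing across iterations (up to the
    M-step's small ridge regularizer) and iteration stops when the
    improvement falls below ``tol``.

    Initialization (when ``init`` is not given): each restart fits one
    Bernoulli GLM to all trials pooled, replicates it per state with
    Gaussian perturbations, and starts from sticky transitions; the
    restart with the best final log-likelihood is returned.
    """
    if len(sessions) == 0:
        raise SchemaError("glmhmm_em needs at least one session")
    rng = rng or np.random.default_rng(0)
    K = n_states

    designs = [cm.glmhmm_regressors(s.stimuli, s.actions, s.rewards)
               for s in sessions]
    if init is not None:
        inits = [(np.array(init["weights"], dtype=float),
                  np.array(init["transitions"], dtype=float),
                  np.array(init["initial"], dtype=float))]
    else:
        X0 = np.vstack(designs)
        y0 = np.concatenate([s.actions for s in sessions]).astype(float)
        w_pool = _weighted_logistic_fit(X0, y0, np.ones(len(y0)),
                                        np.zeros(X0.shape[1]))
        inits = []
        for _ in range(max(1, n_restarts)):
            W0 = w_pool[None, :] + rng.normal(0.0, 1.0, size=(K, 4))
            A0 = 0.90 * np.eye(K) + 0.10 / K
            A0 /= A0.sum(axis=1, keepdims=True)
            inits.append((W0, A0, np.full(K, 1.0 / K)))
    best: Optional[GLMHMMFit] = None
    for W0, A0, pi0 in inits:
        fit = _glmhmm_em_once(sessions, designs, W0, A0, pi0, max_iter, tol)
        if best is None or fit.loglik_history[-1] > best.loglik_history[-1]:
            best = fit
    return best


def _glmhmm_em_once(sessions, designs, W, A, pi, max_iter, tol) -> GLMHMMFit:
    K = len(pi)
    W, A, pi = W.copy(), A.copy(), pi.copy()
    ys = [s.actions.astype(float) for s in sessions]
    Xall = np.vstack(designs)
    yall = np.concatenate(ys)
    same_T = len({s.n_trials for s in sessions}) == 1
    history: List[float] = []
    converged = False
    for it in range(max_iter):
        if same_T:
            log_emit = np.stack(
                [_glmhmm_log_emissions(W, s) for s in sessions])
            lls, gamma_b, xi_total = _forward_backward_batch(log_emit, A, pi)
            total_ll = float(lls.sum())
            pi_total = gamma_b[:, 0].sum(axis=0)
            G = gamma_b.reshape(-1, K)
        else:
            total_ll = 0.0
            gammas = []
            xi_total = np.zeros((K, K))
            pi_total = np.zeros(K)
            for s in sessions:
                log_emit = _glmhmm_log_emissions(W, s)
                ll, gamma, xi = _forward_backward(log_emit, A, pi)
                total_ll += ll
                gammas.append(gamma)
                xi_total += xi
                pi_total += gamma[0]
            G = np.vstack(gammas)                          # (sum T) x K
        if not np.isfinite(total_ll):
            raise EMFailureError(it)
        history.append(total_ll)
        if it > 0 and history[-1] - history[-2] < tol:
            converged = True
            break
        A = xi_total / np.clip(xi_total.sum(axis=1, keepdims=True), 1e-12, None)
        pi = pi_total / pi_total.sum()
        for k in range(K):
            W[k] = _weighted_logistic_fit(Xall, yall, G[:, k], W[k])
    return GLMHMMFit(W, A, pi, history, converged)


def align_states(posterior_states: np.ndarray, true_states: np.ndarray,
                 n_states: int) -> np.ndarray:
    """Permutation of fitted-state labels that best overlaps the true
    labels (Hungarian assignment on the co-occurrence matrix). Returns
    ``perm`` with ``perm[fitted_label] = aligned_label``."""
    from scipy.optimize import linear_sum_assignment
    C = np.zeros((n_states, n_states))
    for i in range(n_states):
        for j in range(n_states):
            C[i, j] = np.sum((posterior_states == i) & (true_states == j))
    row, col = linear_sum_assignment(-C)
    perm = np.empty(n_states, dtype=int)
    perm[row] = col
    return perm
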