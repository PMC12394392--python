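"""Priors over model parameters and construction of encoded datasets.

A training corpus is built by (1) sampling one parameter set per synthetic
agent from a prior, (2) running the model simulator once per agent, and
(3) encoding each session into the fixed observable layout
``[action, reward, stimulus coding...]`` whose width is 2, 2, 5, 9, or 3
for the five models. Targets are the aligned latent trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import models as cm
from .errors import ConfigError, SchemaError

# --------------------------------------------------------------------------
# Priors
# --------------------------------------------------------------------------

#: distribution descriptors: ("uniform", lo, hi) | ("beta", a, b, lo, hi)
#: | ("normal", mean, sigma)  (normal draws are clipped to the parameter
#: bounds, i.e. truncated)
Dist = Tuple


@dataclass
class PriorSpec:
    """Sampling distributions for one model's parameters.

    For the GLM-HMM the weight block is sampled around canonical state
    profiles with noise scale ``sigma`` and the transition matrix is built
    sticky with stationary state occupancy set by the skew ``gamma``
    (-1, 0, +1); the ``dists`` map is unused for that block.
    """

    model_id: str
    dists: Dict[str, Dist] = field(default_factory=dict)
    gamma: int = 0          # state-occupancy skew for glmhmm: -1, 0, +1
    sigma: float = 1.0      # GLM-weight noise scale for glmhmm

    def describe(self) -> Dict:
        return {
            "model_id": self.model_id,
            "dists": {k: list(v) for k, v in self.dists.items()},
            "gamma": self.gamma,
            "sigma": self.sigma,
        }


#: canonical GLM-HMM state profiles (rows: engaged, biased-right,
#: biased-left; cols: stimulus, bias, previous-choice, win-stay-lose-switch)
GLMHMM_WEIGHT_MEANS = np.array([
    [6.0, 0.0, 0.5, 1.0],
    [1.0, 3.0, 0.0, 0.0],
    [1.0, -3.0, 0.0, 0.0],
])

#: named beta-prior variants for the 4P-RL softmax temperature study
BETA_PRIOR_VARIANTS: Dict[str, Dist] = {
    "uniform": ("uniform", 0.0, 10.0),
    "beta55": ("beta", 5.0, 5.0, 0.0, 10.0),
    "beta28": ("beta", 2.0, 8.0, 0.0, 10.0),
    "beta82": ("beta", 8.0, 2.0, 0.0, 10.0),
}


def default_prior(model_id: str, beta_variant: str = "uniform",
                  gamma: int = 0, sigma: float = 1.0) -> PriorSpec:
    """The benchmark training prior for a model.

    ``beta_variant`` selects the softmax-temperature prior for the RL
    bandit models (the prior-misspecification study trains one estimator
    per variant); ``gamma``/``sigma`` configure the GLM-HMM occupancy skew
    and weight noise.
    """
    if beta_variant not in BETA_PRIOR_VARIANTS:
        raise ConfigError(f"unknown beta prior variant {beta_variant!r}")
    beta_dist = BETA_PRIOR_VARIANTS[beta_variant]
    if model_id == cm.FOURP_RL:
        return PriorSpec(model_id, {
            "alpha_pos": ("uniform", 0.0, 1.0),
            "alpha_neg": ("uniform", 0.0, 1.0),
            "beta": beta_dist,
            "kappa": ("uniform", -1.0, 1.0),
        })
    if model_id == cm.META_RL:
        return PriorSpec(model_id, {
            "alpha_pos": ("uniform", 0.0, 1.0),
            "alpha_neg": ("uniform", 0.0, 1.0),
            "beta": beta_dist,
            "kappa": ("uniform", -1.0, 1.0),
            "forget": ("uniform", 0.0, 0.3),
            "bias": ("uniform", 0.2, 0.8),
            "p_stay_engaged": ("uniform", 0.9, 0.99),
            "p_stay_random": ("uniform", 0.8, 0.95),
            "p_engaged0": ("uniform", 0.5, 1.0),
        })
    if model_id == cm.HRL:
        return PriorSpec(model_id, {
            "alpha": ("uniform", 0.0, 1.0),
            "beta": beta_dist,
        })
    if model_id == cm.WEBER:
        return PriorSpec(model_id, {
            "mu": ("uniform", 0.0, 0.5),
            "lam": ("uniform", 0.0, 1.0),
            "select_beta": ("uniform", 1.0, 10.0),
        })
    if model_id == cm.GLMHMM:
        return PriorSpec(model_id, gamma=gamma, sigma=sigma)
    raise ConfigError(f"unknown model {model_id!r}")


def _draw(dist: Dist, lo_hi: Tuple[float, float], rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    if kind == "beta":
        a, b, lo, hi = dist[1:]
        return float(lo + (hi - lo) * rng.beta(a, b))
    if kind == "normal":
        mean, sigma = dist[1:]
        return float(np.clip(rng.normal(mean, sigma), lo_hi[0], lo_hi[1]))
    raise ConfigError(f"unknown distribution descriptor {dist!r}")


def _sample_glmhmm(prior: PriorSpec, rng: np.random.Generator) -> cm.ModelParameters:
    W = GLMHMM_WEIGHT_MEANS + rng.normal(0.0, prior.sigma, size=(3, 4))
    W = np.clip(W, -10.0, 10.0)
    # stationary occupancy set by the skew; sticky rows k*I + (1-k)*1 pi^T
    pi = np.exp(prior.gamma * np.array([1.0, 0.0, -1.0]))
    pi = pi / pi.sum()
    k = rng.uniform(0.90, 0.97)
    A = k * np.eye(3) + (1.0 - k) * np.tile(pi, (3, 1))
    values: Dict[str, float] = {}
    for s in range(3):
        for j, reg in enumerate(("stim", "bias", "prevc", "wsls")):
            values[f"w{s}_{reg}"] = float(W[s, j])
    for i in range(3):
        for j in range(3):
            values[f"a{i}{j}"] = float(A[i, j])
    return cm.ModelParameters(cm.GLMHMM, values)


def sample_parameters(
    prior: PriorSpec, n: int, rng: np.random.Generator
) -> List[cm.ModelParameters]:
    """Draw ``n`` in-bounds parameter sets from the prior."""
    if n < 1:
        raise ConfigError(f"need n >= 1 parameter draws, got {n}")
    spec = cm.get_spec(prior.model_id)
    if prior.model_id == cm.GLMHMM:
        return [_sample_glmhmm(prior, rng) for _ in range(n)]
    missing = set(spec.param_names) - set(prior.dists)
    if missing:
        raise ConfigError(f"prior missing distributions for {sorted(missing)}")
    out = []
    for _ in range(n):
        values = {
            name: _draw(prior.dists[name], spec.bounds[name], rng)
            for name in spec.param_names
        }
        out.append(cm.ModelParameters(prior.model_id, values))
    return out


# --------------------------------------------------------------------------
# Session encoding
# --------------------------------------------------------------------------

def encode_session(session: cm.BehavioralSession, model_id: str) -> np.ndarray:
    """T x D_in observable matrix with fixed column order
    ``[action, reward, stimulus coding...]``."""
    spec = cm.get_spec(model_id)
    T = session.n_trials
    if session.stimuli.shape[1] != spec.stimulus_dim:
        raise SchemaError(
            f"{model_id}: stimulus width {session.stimuli.shape[1]} "
            f"!= {spec.stimulus_dim}"
        )
    X = np.empty((T, spec.input_dim), dtype=np.float32)
    X[:, 0] = session.actions
    X[:, 1] = session.rewards
    if spec.stimulus_dim:
        X[:, 2:] = session.stimuli
    return X


def decode_session(
    X: np.ndarray, model_id: str, agent_id: str = "0"
) -> cm.BehavioralSession:
    """Inverse of :func:`encode_session`."""
    spec = cm.get_spec(model_id)
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise SchemaError(
            f"{model_id}: expected T x {spec.input_dim} matrix, got {X.shape}"
        )
    return cm.BehavioralSession(
        agent_id, X[:, 2:].astype(float), X[:, 0].astype(int),
        X[:, 1].astype(int), model_id,
    )


# --------------------------------------------------------------------------
# Dataset container
# --------------------------------------------------------------------------

@dataclass
class EncodedDataset:
    """Fixed-shape tensors for training/evaluating estimators.

    ``inputs`` is N x T x D_in; ``targets_cont`` N x T x C;
    ``targets_disc`` N x T integer labels (or None); ``mask`` N x T with 1
    for real trials and 0 for padding. The train/validation split is by
    agent, disjoint.
    """

    model_id: str
    inputs: np.ndarray
    targets_cont: np.ndarray
    targets_disc: Optional[np.ndarray]
    mask: np.ndarray
    train_idx: np.ndarray
    val_idx: np.ndarray
    meta: Dict = field(default_factory=dict)
    params: Optional[List[cm.ModelParameters]] = None
    sessions: Optional[List[cm.BehavioralSession]] = None

    @property
    def n_agents(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_trials(self) -> int:
        return self.inputs.shape[1]

    def subset(self, idx: np.ndarray) -> "EncodedDataset":
        idx = np.asarray(idx)
        return EncodedDataset(
            self.model_id, self.inputs[idx], self.targets_cont[idx],
            None if self.targets_disc is None else self.targets_disc[idx],
            self.mask[idx], np.arange(len(idx)), np.empty(0, dtype=int),
            dict(self.meta),
            None if self.params is None else [self.params[i] for i in idx],
            None if self.sessions is None else [self.sessions[i] for i in idx],
        )


def pad_sessions(
    matrices: Sequence[np.ndarray],
) -> Tuple[np.ndarray, np.ndarray]:
    """Stack variable-length T_i x D matrices into N x T_max x D plus a
    0/1 validity mask."""
    n = len(matrices)
    T = max((m.shape[0] for m in matrices), default=0)
    D = matrices[0].shape[1] if n else 0
    X = np.zeros((n, T, D), dtype=np.float32)
    mask = np.zeros((n, T), dtype=np.float32)
    for i, m in enumerate(matrices):
        X[i, : m.shape[0]] = m
        mask[i, : m.shape[0]] = 1.0
    return X, mask


def build_dataset(
    model_id: str,
    prior: PriorSpec,
    n_agents: int,
    task: cm.TaskConfig,
    rng: np.random.Generator,
    val_fraction: float = 0.10,
    keep_sessions: bool = False,
) -> EncodedDataset:
    """Simulate ``n_agents`` agents (one parameter draw each) and encode.

    The last ``val_fraction`` of agents form the validation split; agents
    are i.i.d. so the index split is disjoint by construction.
    """
    if prior.model_id != model_id:
        raise ConfigError(
            f"prior is for {prior.model_id!r}, dataset for {model_id!r}"
        )
    if n_agents < 1:
        raise ConfigError("n_agents must be >= 1")
    spec = cm.get_spec(model_id)
    seed_state = rng.bit_generator.state  # recorded for the manifest
    params = sample_parameters(prior, n_agents, rng)
    T = task.n_trials
    inputs = np.empty((n_agents, T, spec.input_dim), dtype=np.float32)
    cont = np.empty((n_agents, T, spec.cont_channels), dtype=np.float32)
    disc = (np.empty((n_agents, T), dtype=np.int64)
            if spec.n_states is not None else None)
    sessions: List[cm.BehavioralSession] = []
    for i in range(n_agents):
        session, latents = cm.simulate(model_id, params[i], task, rng, agent_id=str(i))
        inputs[i] = encode_session(session, model_id)
        cont[i] = latents.continuous
        if disc is not None:
            disc[i] = latents.discrete
        if keep_sessions:
            sessions.append(session)
    n_val = int(round(n_agents * val_fraction))
    n_val = min(max(n_val, 1 if n_agents > 1 and val_fraction > 0 else 0),
                n_agents - 1 if n_agents > 1 else 0)
    train_idx = np.arange(0, n_agents - n_val)
    val_idx = np.arange(n_agents - n_val, n_agents)
    return EncodedDataset(
        model_id, inputs, cont, disc, np.ones((n_agents, T), dtype=np.float32),
        train_idx, val_idx,
        meta={
            "model_id": model_id,
            "prior": prior.describe(),
            "n_agents": n_agents,
            "n_trials": T,
            "val_fraction": val_fraction,
            "rng_state": str(seed_state.get("state", {}).get("state", "")),
        },
        params=params,
        sessions=sessions if keep_sessions else None,
    )


# --------------------------------------------------------------------------
# Persistence (long-format CSV + JSON manifest)
# --------------------------------------------------------------------------

def _long_frame(tensor: np.ndarray, prefix: str) -> pd.DataFrame:
    n, T = tensor.shape[:2]
    D = tensor.shape[2] if tensor.ndim == 3 else 1
    flat = tensor.reshape(n * T, D)
    df = pd.DataFrame(flat, columns=[f"{prefix}_{j}" for j in range(D)])
    df.insert(0, "trial", np.tile(np.arange(1, T + 1), n))
    df.insert(0, "agent_id", np.repeat(np.arange(n), T))
    return df


def save_dataset(ds: EncodedDataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _long_frame(ds.inputs, "x").to_csv(directory / "inputs.csv", index=False)
    if ds.targets_cont.shape[2]:
        _long_frame(ds.targets_cont, "cont").to_csv(
            directory / "targets_cont.csv", index=False)
    if ds.targets_disc is not None:
        _long_frame(ds.targets_disc[:, :, None], "state").to_csv(
            directory / "targets_disc.csv", index=False)
    meta = dict(ds.meta)
    meta["train_idx"] = ds.train_idx.tolist()
    meta["val_idx"] = ds.val_idx.tolist()
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))


def load_dataset(directory: str | Path) -> EncodedDataset:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    model_id = meta["model_id"]
    spec = cm.get_spec(model_id)
    n, T = meta["n_agents"], meta["n_trials"]
    xs = pd.read_csv(directory / "inputs.csv")
    D = spec.input_dim
    inputs = xs[[f"x_{j}" for j in range(D)]].to_numpy(np.float32).reshape(n, T, D)
    if (directory / "targets_cont.csv").exists():
        cf = pd.read_csv(directory / "targets_cont.csv")
        C = spec.cont_channels
        cont = cf[[f"cont_{j}" for j in range(C)]].to_numpy(np.float32).reshape(n, T, C)
    else:
        cont = np.empty((n, T, 0), dtype=np.float32)
    if (directory / "targets_disc.csv").exists():
        df = pd.read_csv(directory / "targets_disc.csv")
        disc = df["state_0"].to_numpy(np.int64).reshape(n, T)
    else:
        disc = None
    return EncodedDataset(
        model_id, inputs, cont, disc, np.ones((n, T), dtype=np.float32),
        np.array(meta["train_idx"], dtype=int), np.array(meta["val_idx"], dtype=int),
        meta=meta,
    )
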