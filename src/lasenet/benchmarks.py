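"""End-to-end benchmark harness.

Reproduces the synthetic-data comparisons at configurable scale: train a
sequence estimator per cognitive model, evaluate it on unseen simulated
agents, and compare against the likelihood-dependent baselines (MLE for
the tractable models; known-parameter particle filtering for HRL and the
task-set learner; EM for the GLM-HMM), plus the prior-misspecification
study. Every experiment is reproducible from (config, seed): the global
seed is split deterministically into data/init/shuffle/test streams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import models as cm
from .baselines import (
    ParticleFilterConfig, align_states, derive_latents, fit_mle,
    glmhmm_em, metarl_state_posterior, particle_filter,
)
from .datasets import EncodedDataset, PriorSpec, build_dataset, default_prior
from .errors import ConfigError
from .io import spawn_seeds
from .metrics import MetricReport, aggregate, balanced_accuracy, log_loss, rmse
from .network import (
    NetworkConfig, TrainedEstimator, TrainingConfig, build_network,
    predict_latents, train_estimator,
)


@dataclass
class ExperimentConfig:
    """Scale and settings of one benchmark experiment."""

    model_id: str
    train_size: int = 9000
    test_size: int = 1000
    n_trials: int = 720
    gru_units: int = 64
    max_epochs: int = 600
    early_stop_patience: int = 35
    learning_rate: float = 3e-4
    lr_halve_patience: int = 0          # 0 disables the plateau schedule
    batch_size: int = 128
    n_particles: int = 10000
    mle_restarts: int = 10
    seed: int = 0
    beta_variant: str = "uniform"          # training prior for beta
    test_beta_variants: Tuple[str, ...] = ("uniform", "beta55", "beta28", "beta82")
    train_beta_variants: Tuple[str, ...] = ("uniform", "beta55")
    gamma: int = 0
    sigma: float = 1.0
    train_gammas: Tuple[int, ...] = (1, 0)
    test_gammas: Tuple[int, ...] = (-1, 0, 1)
    train_sigmas: Tuple[float, ...] = (0.5, 2.0)
    test_sigmas: Tuple[float, ...] = (1.0,)


def desk_scale_config(model_id: str, seed: int = 0) -> ExperimentConfig:
    """Preset sized so the full intractable benchmark finishes on one CPU:
    1000 training agents, 200 trials, at most 100 epochs (patience 15),
    200 test agents, 2000 particles. The learning rate is raised to 1e-3
    to converge within the reduced epoch budget."""
    return ExperimentConfig(
        model_id, train_size=1000, test_size=200, n_trials=200,
        max_epochs=100, early_stop_patience=15, learning_rate=1e-3,
        n_particles=2000, mle_restarts=5, seed=seed,
    )


def full_scale_config(model_id: str, seed: int = 0) -> ExperimentConfig:
    """Paper-scale preset (hours of CPU time): 9000 training agents
    (6000 for Meta RL), 720 trials, up to 600 epochs."""
    return ExperimentConfig(
        model_id,
        train_size=6000 if model_id == cm.META_RL else 9000,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Building blocks
# --------------------------------------------------------------------------

def _heads(model_id: str) -> Tuple[int, int]:
    spec = cm.get_spec(model_id)
    return spec.cont_channels, spec.n_states or 0


def train_for(cfg: ExperimentConfig,
              prior: Optional[PriorSpec] = None,
              verbose: bool = False) -> TrainedEstimator:
    """Simulate a training corpus from the prior and train the estimator."""
    data_seed, init_seed, shuffle_seed = spawn_seeds(cfg.seed, 3)
    prior = prior or default_prior(cfg.model_id, cfg.beta_variant,
                                   cfg.gamma, cfg.sigma)
    task = cm.default_task(cfg.model_id, cfg.n_trials)
    ds = build_dataset(cfg.model_id, prior, cfg.train_size, task,
                       np.random.default_rng(data_seed))
    C, M = _heads(cfg.model_id)
    net = build_network(
        NetworkConfig(gru_units=cfg.gru_units, head_cont=C, head_disc=M),
        cm.get_spec(cfg.model_id).input_dim, seed=init_seed)
    tcfg = TrainingConfig(
        learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs, early_stop_patience=cfg.early_stop_patience,
        lr_halve_patience=cfg.lr_halve_patience or None,
        seed=shuffle_seed)
    return train_estimator(net, ds, tcfg, verbose=verbose)


def make_test_set(cfg: ExperimentConfig,
                  prior: Optional[PriorSpec] = None) -> EncodedDataset:
    """Held-out agents from a seed stream disjoint from training."""
    test_seed = spawn_seeds(cfg.seed, 4)[3]
    prior = prior or default_prior(cfg.model_id, cfg.beta_variant,
                                   cfg.gamma, cfg.sigma)
    task = cm.default_task(cfg.model_id, cfg.n_trials)
    return build_dataset(cfg.model_id, prior, cfg.test_size, task,
                         np.random.default_rng(test_seed),
                         keep_sessions=True)


def lasenet_metrics(est: TrainedEstimator,
                    test: EncodedDataset) -> Dict[str, np.ndarray]:
    """Per-agent RMSE / log loss / balanced accuracy for the estimator."""
    out = predict_latents(est, test.inputs)
    N = test.n_agents
    res: Dict[str, np.ndarray] = {}
    if out.continuous is not None:
        res["rmse"] = np.array([
            rmse(test.targets_cont[i, :, 0], out.continuous[i, :, 0])
            for i in range(N)])
    if out.state_probs is not None and test.targets_disc is not None:
        res["log_loss"] = np.array([
            log_loss(test.targets_disc[i], out.state_probs[i])
            for i in range(N)])
        states = out.states
        res["balanced_accuracy"] = np.array([
            balanced_accuracy(test.targets_disc[i], states[i])
            for i in range(N)])
    return res


def mle_metrics(cfg: ExperimentConfig,
                test: EncodedDataset) -> Dict[str, np.ndarray]:
    """Fit each test agent by MLE, replay latents, and score them."""
    fit_seeds = spawn_seeds(cfg.seed + 104729, test.n_agents)
    rmses, nlls, accs = [], [], []
    for i in range(test.n_agents):
        session = test.sessions[i]
        fit = fit_mle(cfg.model_id, session, n_restarts=cfg.mle_restarts,
                      rng=np.random.default_rng(fit_seeds[i]))
        lat = derive_latents(cfg.model_id, fit.params, session)
        rmses.append(rmse(test.targets_cont[i, :, 0], lat.continuous[:, 0]))
        if cfg.model_id == cm.META_RL:
            gamma = metarl_state_posterior(fit.params, session)
            nlls.append(log_loss(test.targets_disc[i], gamma))
            accs.append(balanced_accuracy(test.targets_disc[i],
                                          gamma.argmax(axis=1)))
    res = {"rmse": np.array(rmses)}
    if nlls:
        res["log_loss"] = np.array(nlls)
        res["balanced_accuracy"] = np.array(accs)
    return res


def particle_filter_metrics(cfg: ExperimentConfig,
                            test: EncodedDataset) -> Dict[str, np.ndarray]:
    """Known-theta particle filtering per test agent (the SMC comparator)."""
    pf_seeds = spawn_seeds(cfg.seed + 224737, test.n_agents)
    rmses, nlls, accs = [], [], []
    task = cm.default_task(cfg.model_id, cfg.n_trials)
    hazard = (task.reversal_prob if cfg.model_id == cm.HRL
              else task.mapping_shift_prob)
    for i in range(test.n_agents):
        res = particle_filter(
            cfg.model_id, test.params[i], test.sessions[i],
            ParticleFilterConfig(cfg.n_particles, seed=pf_seeds[i]),
            hazard=hazard)
        rmses.append(rmse(test.targets_cont[i, :, 0], res.continuous))
        nlls.append(log_loss(test.targets_disc[i], res.state_probs))
        accs.append(balanced_accuracy(test.targets_disc[i], res.states))
    return {"rmse": np.array(rmses), "log_loss": np.array(nlls),
            "balanced_accuracy": np.array(accs)}


def em_metrics(cfg: ExperimentConfig, test: EncodedDataset,
               max_iter: int = 150) -> Dict[str, np.ndarray]:
    """Fit one GLM-HMM by EM to the test sessions and score the
    forward-backward state posteriors (states aligned to ground truth by
    Hungarian matching on co-occurrence)."""
    em_seed = spawn_seeds(cfg.seed + 350377, 1)[0]
    fit = glmhmm_em(test.sessions, max_iter=max_iter,
                    rng=np.random.default_rng(em_seed))
    gammas = fit.posteriors_batch(test.sessions)
    all_pred = np.concatenate([g.argmax(axis=1) for g in gammas])
    all_true = test.targets_disc.ravel()
    perm = align_states(all_pred, all_true, 3)
    nlls, accs = [], []
    for i, g in enumerate(gammas):
        aligned = np.empty_like(g)
        aligned[:, perm] = g
        nlls.append(log_loss(test.targets_disc[i], aligned))
        accs.append(balanced_accuracy(test.targets_disc[i],
                                      aligned.argmax(axis=1)))
    return {"log_loss": np.array(nlls), "balanced_accuracy": np.array(accs)}


def _to_frame(blocks: Dict[str, Dict[str, np.ndarray]],
              model_id: str) -> pd.DataFrame:
    reports: List[MetricReport] = []
    for estimator, metricset in blocks.items():
        for metric, values in metricset.items():
            reports.append(aggregate(values, metric, model_id, estimator))
    return pd.DataFrame([r.to_row() for r in reports])


# --------------------------------------------------------------------------
# Experiments
# --------------------------------------------------------------------------

def run_tractable_benchmark(cfg: ExperimentConfig) -> pd.DataFrame:
    """LaseNet vs per-agent MLE on the tractable bandit models."""
    if cfg.model_id not in (cm.FOURP_RL, cm.META_RL):
        raise ConfigError("tractable benchmark covers 4prl and metarl")
    if cfg.test_size == 0:
        return pd.DataFrame(
            columns=["metric", "model", "estimator", "mean", "sd", "n"])
    est = train_for(cfg)
    test = make_test_set(cfg)
    return _to_frame({
        "lasenet": lasenet_metrics(est, test),
        "mle": mle_metrics(cfg, test),
    }, cfg.model_id)


def run_intractable_benchmark(cfg: ExperimentConfig) -> pd.DataFrame:
    """LaseNet vs particle filtering (HRL, Weber) or EM (GLM-HMM)."""
    if cfg.model_id not in (cm.HRL, cm.WEBER, cm.GLMHMM):
        raise ConfigError("intractable benchmark covers hrl, weber, glmhmm")
    if cfg.test_size == 0:
        return pd.DataFrame(
            columns=["metric", "model", "estimator", "mean", "sd", "n"])
    est = train_for(cfg)
    test = make_test_set(cfg)
    if cfg.model_id == cm.GLMHMM:
        baseline = {"em": em_metrics(cfg, test)}
    else:
        baseline = {"smc": particle_filter_metrics(cfg, test)}
    return _to_frame({"lasenet": lasenet_metrics(est, test), **baseline},
                     cfg.model_id)


def run_prior_misspecification(cfg: ExperimentConfig) -> pd.DataFrame:
    """Train one estimator per training prior and evaluate on every test
    prior; rows are keyed by (train prior, test prior)."""
    rows = []
    if cfg.model_id == cm.FOURP_RL:
        test_sets = {
            v: make_test_set(cfg, default_prior(cfg.model_id, v))
            for v in cfg.test_beta_variants}
        for train_v in cfg.train_beta_variants:
            est = train_for(cfg, default_prior(cfg.model_id, train_v))
            for test_v, test in test_sets.items():
                vals = lasenet_metrics(est, test)["rmse"]
                rows.append({"train_prior": train_v, "test_prior": test_v,
                             "metric": "rmse", "mean": float(vals.mean()),
                             "sd": float(vals.std()), "n": len(vals)})
    elif cfg.model_id == cm.GLMHMM:
        # skewness sweep (sigma fixed), then sigma sweep (skew fixed)
        test_sets = {
            f"gamma={g}": make_test_set(
                cfg, default_prior(cfg.model_id, gamma=g, sigma=cfg.sigma))
            for g in cfg.test_gammas}
        for g in cfg.train_gammas:
            est = train_for(cfg, default_prior(cfg.model_id, gamma=g,
                                               sigma=cfg.sigma))
            for name, test in test_sets.items():
                m = lasenet_metrics(est, test)
                for metric in ("log_loss", "balanced_accuracy"):
                    rows.append({
                        "train_prior": f"gamma={g}", "test_prior": name,
                        "metric": metric, "mean": float(m[metric].mean()),
                        "sd": float(m[metric].std()), "n": len(m[metric])})
        sigma_tests = {
            f"sigma={s}": make_test_set(
                cfg, default_prior(cfg.model_id, gamma=cfg.gamma, sigma=s))
            for s in cfg.test_sigmas}
        for s in cfg.train_sigmas:
            est = train_for(cfg, default_prior(cfg.model_id, gamma=cfg.gamma,
                                               sigma=s))
            for name, test in sigma_tests.items():
                m = lasenet_metrics(est, test)
                for metric in ("log_loss", "balanced_accuracy"):
                    rows.append({
                        "train_prior": f"sigma={s}", "test_prior": name,
                        "metric": metric, "mean": float(m[metric].mean()),
                        "sd": float(m[metric].std()), "n": len(m[metric])})
    else:
        raise ConfigError(
            "prior-misspecification study covers 4prl and glmhmm")
    return pd.DataFrame(rows)
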