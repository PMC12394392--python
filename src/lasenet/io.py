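"""Serialization of sessions/latents to delimited text, run manifests,
and deterministic seed management.

CSV dialect: comma-separated, header row, UTF-8, 1-based trial index.
Session files carry columns ``agent_id, trial, s_0..s_{D-1}, action,
reward``; latent files carry ``agent_id, trial, cont_0.., state``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import models as cm
from .errors import SchemaError


def spawn_seeds(seed: int, n: int) -> List[int]:
    """Expand one global seed into ``n`` independent component seeds.

    Uses numpy's SeedSequence spawning, so component-level reruns with the
    same global seed reproduce exactly. Returned values fit in 31 bits.
    """
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


# --------------------------------------------------------------------------
# Sessions
# --------------------------------------------------------------------------

def sessions_to_frame(sessions: Sequence[cm.BehavioralSession]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        T, D = s.n_trials, s.stimuli.shape[1]
        df = pd.DataFrame({
            "agent_id": [s.agent_id] * T,
            "trial": np.arange(1, T + 1),
        })
        for j in range(D):
            df[f"s_{j}"] = s.stimuli[:, j]
        df["action"] = s.actions
        df["reward"] = s.rewards
        rows.append(df)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["agent_id", "trial", "action", "reward"])


def save_sessions(sessions: Sequence[cm.BehavioralSession],
                  path: str | Path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def load_sessions(path: str | Path,
                  model_id: Optional[str] = None) -> List[cm.BehavioralSession]:
    df = pd.read_csv(path)
    required = {"agent_id", "trial", "action", "reward"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"session file missing columns {sorted(required - set(df.columns))}")
    stim_cols = sorted(
        [c for c in df.columns if c.startswith("s_")],
        key=lambda c: int(c.split("_")[1]))
    out = []
    for agent_id, g in df.groupby("agent_id", sort=False):
        g = g.sort_values("trial")
        stimuli = (g[stim_cols].to_numpy(float) if stim_cols
                   else np.empty((len(g), 0)))
        out.append(cm.BehavioralSession(
            str(agent_id), stimuli, g["action"].to_numpy(int),
            g["reward"].to_numpy(int), model_id))
    return out


# --------------------------------------------------------------------------
# Latents
# --------------------------------------------------------------------------

def latents_to_frame(latents: Sequence[cm.LatentTrajectory],
                     agent_ids: Sequence[str]) -> pd.DataFrame:
    rows = []
    for lat, aid in zip(latents, agent_ids):
        T = lat.continuous.shape[0]
        df = pd.DataFrame({"agent_id": [aid] * T,
                           "trial": np.arange(1, T + 1)})
        for j in range(lat.continuous.shape[1]):
            df[f"cont_{j}"] = lat.continuous[:, j]
        if lat.discrete is not None:
            df["state"] = lat.discrete
        rows.append(df)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["agent_id", "trial"])


def save_latents(latents: Sequence[cm.LatentTrajectory],
                 agent_ids: Sequence[str], path: str | Path) -> None:
    latents_to_frame(latents, agent_ids).to_csv(path, index=False)


def load_latents(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_fit_result(fit, path: str | Path) -> None:
    """Serialize a parameter-fit result (theta-hat + optimizer
    diagnostics) to JSON; per-trial posteriors go to CSV via
    :func:`save_latents`."""
    payload = {
        "model_id": fit.params.model_id,
        "theta_hat": fit.params.values,
        "objective": fit.objective,
        "n_restarts": fit.n_restarts,
        "converged": fit.converged,
        "restart_objectives": fit.restart_objectives,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# --------------------------------------------------------------------------
# Manifests
# --------------------------------------------------------------------------

def write_manifest(directory: str | Path, config: Dict,
                   seed: Optional[int] = None) -> None:
    """Record everything needed to reproduce an output directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "lasenet",
        "version": __version__,
        "seed": seed,
        "config": config,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                        default=str))
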