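"""Evaluation metrics for latent-trajectory recovery.

Three per-agent metrics: RMSE for continuous latents, negative log loss
for predicted state probabilities, and balanced accuracy (macro-averaged
per-state recall) for hard state labels. ``aggregate`` summarizes a
metric over test agents as mean +/- 2 SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

#: floor applied to probabilities before taking logs
PROB_CLIP = 1e-12


def rmse(z_true: np.ndarray, z_pred: np.ndarray) -> float:
    """Root-mean-squared error between true and predicted sequences."""
    a = np.asarray(z_true, dtype=float).ravel()
    b = np.asarray(z_pred, dtype=float).ravel()
    if a.shape != b.shape or a.size == 0:
        raise SchemaError(f"length mismatch or empty: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def log_loss(z_true: np.ndarray, p: np.ndarray) -> float:
    """Mean negative log probability of the true label per trial.

    ``z_true`` may be integer labels of length T or a T x M one-hot
    matrix; ``p`` is T x M with rows summing to 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2:
        raise SchemaError("p must be T x M with M >= 2")
    T, M = p.shape
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise SchemaError("probability rows must sum to 1")
    z = np.asarray(z_true)
    if z.ndim == 2:
        if z.shape != p.shape:
            raise SchemaError(f"one-hot shape {z.shape} != {p.shape}")
        labels = z.argmax(axis=1)
    else:
        if len(z) != T:
            raise SchemaError(f"labels length {len(z)} != {T}")
        labels = z.astype(int)
    picked = np.clip(p[np.arange(T), labels], PROB_CLIP, None)
    return float(-np.mean(np.log(picked)))


def balanced_accuracy(z_true: np.ndarray, z_pred: np.ndarray) -> float:
    """Macro-average of per-state recall over the states present in
    ``z_true`` (equals (TPR + TNR)/2 in the binary case)."""
    t = np.asarray(z_true).ravel().astype(int)
    p = np.asarray(z_pred).ravel().astype(int)
    if t.size == 0 or t.shape != p.shape:
        raise SchemaError("label sequences must be non-empty and equal length")
    recalls = [np.mean(p[t == s] == s) for s in np.unique(t)]
    return float(np.mean(recalls))


@dataclass
class MetricReport:
    """Per-agent metric values plus their mean and 2-SD band."""

    metric: str
    values: np.ndarray
    model_id: str = ""
    estimator: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        # population SD over test agents
        return float(np.std(self.values))

    @property
    def band(self) -> tuple:
        return (self.mean - 2 * self.sd, self.mean + 2 * self.sd)

    @property
    def n_agents(self) -> int:
        return len(self.values)

    def to_row(self) -> dict:
        return {
            "metric": self.metric, "model": self.model_id,
            "estimator": self.estimator, "mean": self.mean,
            "sd": self.sd, "n": self.n_agents,
        }


def aggregate(values: Sequence[float], metric: str = "",
              model_id: str = "", estimator: str = "") -> MetricReport:
    """Summarize per-agent metric values (mean and 2-SD band)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise SchemaError("aggregate requires at least one value")
    return MetricReport(metric, arr, model_id, estimator)


def reports_to_frame(reports: Sequence[MetricReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])
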