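"""The sequence-labeling estimator network and its training loop.

Architecture: a bidirectional GRU reads the encoded observable sequence
and produces, at every trial, a summary embedding that concatenates the
forward (past) and backward (future) hidden states. A pyramidal MLP (each
layer half the width of the previous, ReLU) maps the embedding to one or
two output heads: a linear head for continuous latents (mean-squared
error) and/or a softmax head over discrete states (cross-entropy). Both
heads share the MLP trunk.

The whole network - forward pass, backpropagation through time, and the
Adam optimizer - is implemented directly on numpy arrays, with the
sequential GRU recurrences JIT-compiled by numba so a full training run
is practical on a single CPU. Gradients are exercised against finite
differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from numba import njit

from .datasets import EncodedDataset
from .errors import ConfigError, SchemaError, TrainingDivergedError

Params = Dict[str, np.ndarray]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Shape of the estimator.

    ``gru_units`` is the hidden width per direction; after the
    bidirectional concatenation (2 * gru_units) each of the ``mlp_depth``
    MLP layers halves the width. ``head_cont`` / ``head_disc`` give the
    number of continuous channels C and discrete states M (0 disables a
    head; at least one must be present).
    """

    gru_units: int = 64
    mlp_depth: int = 2
    head_cont: int = 0
    head_disc: int = 0
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if self.head_cont <= 0 and self.head_disc <= 0:
            raise ConfigError("at least one output head is required")
        if self.gru_units < 1 or self.mlp_depth < 1:
            raise ConfigError("gru_units and mlp_depth must be >= 1")

    def mlp_widths(self) -> List[int]:
        w = self.gru_units * (2 if self.bidirectional else 1)
        widths = []
        for _ in range(self.mlp_depth):
            w = max(w // 2, 1)
            widths.append(w)
        return widths


@dataclass
class TrainingConfig:
    """Optimization settings (Adam, early stopping on validation loss).

    ``lr_halve_patience``, when set, halves the learning rate after that
    many epochs without validation improvement (plateau schedule).
    """

    learning_rate: float = 3e-4
    batch_size: int = 128
    max_epochs: int = 600
    early_stop_patience: int = 35
    val_fraction: float = 0.10
    seed: int = 0
    cont_weight: float = 1.0
    disc_weight: float = 1.0
    lr_halve_patience: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ConfigError("val_fraction must be in (0, 1)")
        if self.early_stop_patience >= self.max_epochs:
            raise ConfigError("early_stop_patience must be < max_epochs")


# --------------------------------------------------------------------------
# JIT-compiled GRU recurrences
# --------------------------------------------------------------------------

@njit(fastmath=True, cache=False)
def _gru_bwd_kernel(dHout, Hs, Gs, Ns, Hpn, Ut, dh, dXp, dHp):
    """Backpropagation through time over all directions at once.

    Gradient arrays (dHout, dXp, dHp) are direction-major (nd, T, B, .);
    the forward caches (Hs, Gs, Ns, Hpn) are time-major (T, nd, B, .);
    ``Ut`` is (nd, 3H, H). Fills dXp (gradient w.r.t. the input
    projection, gate order [r, z, n]) and dHp (gradient w.r.t.
    h_{t-1} @ U + bu).
    """
    ND, T, B, _, H = dXp.shape
    for t in range(T - 1, -1, -1):
        for d in range(ND):
            for b in range(B):
                for j in range(H):
                    dht = dHout[d, t, b, j] + dh[d, b, j]
                    hp = Hs[t - 1, d, b, j] if t > 0 else 0.0
                    r = Gs[t, d, b, 0, j]
                    z = Gs[t, d, b, 1, j]
                    n = Ns[t, d, b, j]
                    da_z = dht * (hp - n) * z * (1.0 - z)
                    da_n = dht * (1.0 - z) * (1.0 - n * n)
                    da_r = da_n * Hpn[t, d, b, j] * r * (1.0 - r)
                    dXp[d, t, b, 0, j] = da_r
                    dXp[d, t, b, 1, j] = da_z
                    dXp[d, t, b, 2, j] = da_n
                    dHp[d, t, b, 0, j] = da_r
                    dHp[d, t, b, 1, j] = da_z
                    dHp[d, t, b, 2, j] = da_n * r
                    dh[d, b, j] = dht * z
            dcarry = np.dot(dHp[d, t].reshape(B, 3 * H), Ut[d])
            for b in range(B):
                for j in range(H):
                    dh[d, b, j] += dcarry[b, j]


def _glorot(rng: np.random.Generator, shape: Tuple[int, int], dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal_gates(rng: np.random.Generator, H: int, dtype) -> np.ndarray:
    """Recurrent weight init: one orthogonal (H, H) block per gate,
    concatenated to (H, 3H) - keeps long products of recurrent Jacobians
    well-conditioned."""
    blocks = []
    for _ in range(3):
        q, r = np.linalg.qr(rng.normal(size=(H, H)))
        blocks.append(q * np.sign(np.diag(r)))
    return np.concatenate(blocks, axis=1).astype(dtype)


class LaseNetwork:
    """Untrained estimator: parameter store plus forward/backward passes."""

    def __init__(self, config: NetworkConfig, input_dim: int,
                 rng: Optional[np.random.Generator] = None,
                 dtype=np.float32):
        if input_dim < 1:
            raise ConfigError("input_dim must be >= 1")
        self.config = config
        self.input_dim = input_dim
        self.dtype = dtype
        rng = rng or np.random.default_rng(0)
        H, D = config.gru_units, input_dim
        p: Params = {}
        for d in self._dirs:
            p[f"Wx_{d}"] = _glorot(rng, (D, 3 * H), dtype)
            p[f"U_{d}"] = _orthogonal_gates(rng, H, dtype)
            p[f"bx_{d}"] = np.zeros(3 * H, dtype=dtype)
            p[f"bu_{d}"] = np.zeros(3 * H, dtype=dtype)
        w_in = H * len(self._dirs)
        for i, w_out in enumerate(config.mlp_widths()):
            p[f"Wm{i}"] = _glorot(rng, (w_in, w_out), dtype)
            p[f"bm{i}"] = np.zeros(w_out, dtype=dtype)
            w_in = w_out
        if config.head_cont:
            p["Wc"] = _glorot(rng, (w_in, config.head_cont), dtype)
            p["bc"] = np.zeros(config.head_cont, dtype=dtype)
        if config.head_disc:
            p["Wd"] = _glorot(rng, (w_in, config.head_disc), dtype)
            p["bd"] = np.zeros(config.head_disc, dtype=dtype)
        self.params = p

    @property
    def _dirs(self) -> List[str]:
        return ["f", "b"] if self.config.bidirectional else ["f"]

    # -- GRU ----------------------------------------------------------------

    def _gru_forward(self, X: np.ndarray):
        """X is (B, T, D). Returns outputs Hs (T, nd, B, H) - direction 1
        in its own (reversed) time order - plus the backward-pass cache.

        The time loop is vectorized over directions and batch; the
        transcendental functions run as single numpy SIMD calls per step
        into preallocated slabs.
        """
        p = self.params
        dirs = self._dirs
        nd = len(dirs)
        B, T, D = X.shape
        H = self.config.gru_units
        dt = X.dtype
        Xd_t = np.empty((nd, T, B, D), dtype=dt)
        Xd_t[0] = X.transpose(1, 0, 2)
        if nd == 2:
            Xd_t[1] = X[:, ::-1].transpose(1, 0, 2)
        U = np.stack([p[f"U_{d}"] for d in dirs])           # (nd, H, 3H)
        bu = np.stack([p[f"bu_{d}"] for d in dirs])[:, None, :]
        Xp = np.empty((nd, T, B, 3 * H), dtype=dt)
        for i, d in enumerate(dirs):
            np.matmul(Xd_t[i].reshape(T * B, D), p[f"Wx_{d}"],
                      out=Xp[i].reshape(T * B, 3 * H))
            Xp[i] += p[f"bx_{d}"]
        h = np.zeros((nd, B, H), dtype=dt)
        Hs = np.empty((T, nd, B, H), dtype=dt)
        Gs = np.empty((T, nd, B, 2 * H), dtype=dt)          # [r, z]
        Ns = np.empty((T, nd, B, H), dtype=dt)
        Hpn = np.empty((T, nd, B, H), dtype=dt)
        pre = np.empty((nd, B, 3 * H), dtype=dt)
        tmp = np.empty((nd, B, H), dtype=dt)
        for t in range(T):
            np.matmul(h, U, out=pre)
            np.add(pre[:, :, 2 * H:], bu[:, :, 2 * H:], out=Hpn[t])
            g = Gs[t]
            np.add(pre[:, :, :2 * H], bu[:, :, :2 * H], out=g)
            g += Xp[:, t, :, :2 * H]
            np.negative(g, out=g)
            np.exp(g, out=g)
            g += 1.0
            np.reciprocal(g, out=g)
            n = Ns[t]
            np.multiply(g[:, :, :H], Hpn[t], out=n)
            n += Xp[:, t, :, 2 * H:]
            np.tanh(n, out=n)
            z = g[:, :, H:]
            np.subtract(h, n, out=tmp)
            tmp *= z
            np.add(n, tmp, out=h)
            np.copyto(Hs[t], h)
        return Hs, (Xd_t, Hs, Gs, Ns, Hpn, U)

    def _gru_backward(self, dHout: np.ndarray, cache, grads: Params):
        """dHout is (nd, T, B, H): per-direction output gradients in each
        direction's own time order."""
        Xd_t, Hs, Gs, Ns, Hpn, U = cache
        nd, T, B, H = dHout.shape
        dt = dHout.dtype
        dXp = np.empty((nd, T, B, 3, H), dtype=dt)
        dHp = np.empty((nd, T, B, 3, H), dtype=dt)
        dh = np.zeros((nd, B, H), dtype=dt)
        Ut = np.ascontiguousarray(U.transpose(0, 2, 1))
        Gs4 = Gs.reshape(T, nd, B, 2, H)
        _gru_bwd_kernel(dHout, Hs, Gs4, Ns, Hpn, Ut, dh, dXp, dHp)
        D = Xd_t.shape[3]
        for i, d in enumerate(self._dirs):
            dHp_f = dHp[i].reshape(T * B, 3 * H)
            dXp_f = dXp[i].reshape(T * B, 3 * H)
            Hprev = np.concatenate(
                [np.zeros((1, B, H), dtype=dt),
                 np.ascontiguousarray(Hs[:-1, i])], axis=0)
            grads[f"U_{d}"] = Hprev.reshape(T * B, H).T @ dHp_f
            grads[f"bu_{d}"] = dHp_f.sum(axis=0)
            grads[f"Wx_{d}"] = Xd_t[i].reshape(T * B, D).T @ dXp_f
            grads[f"bx_{d}"] = dXp_f.sum(axis=0)

    # -- full forward -------------------------------------------------------

    def forward(self, X: np.ndarray, return_cache: bool = False):
        """Map (N, T, D) inputs to head outputs.

        Returns ``(cont, probs)`` (either may be None) and optionally the
        cache needed for the backward pass.
        """
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 3 or X.shape[2] != self.input_dim:
            raise SchemaError(
                f"expected (N, T, {self.input_dim}) input, got {X.shape}"
            )
        B, T, _ = X.shape
        cfg = self.config
        if B == 0 or T == 0:
            cont = np.zeros((B, T, cfg.head_cont)) if cfg.head_cont else None
            probs = np.zeros((B, T, cfg.head_disc)) if cfg.head_disc else None
            return (cont, probs, None) if return_cache else (cont, probs)
        Hs, gru_cache = self._gru_forward(X)
        if cfg.bidirectional:
            # backward direction's outputs come time-reversed
            S = np.concatenate(
                [Hs[:, 0].transpose(1, 0, 2),
                 Hs[::-1, 1].transpose(1, 0, 2)], axis=2)
        else:
            S = Hs[:, 0].transpose(1, 0, 2)
        flat = np.ascontiguousarray(S).reshape(B * T, -1)
        acts = [flat]
        for i in range(cfg.mlp_depth):
            flat = flat @ self.params[f"Wm{i}"] + self.params[f"bm{i}"]
            flat = np.maximum(flat, 0.0)
            acts.append(flat)
        cont = probs = None
        if cfg.head_cont:
            cont = (flat @ self.params["Wc"] + self.params["bc"]).reshape(
                B, T, cfg.head_cont)
        if cfg.head_disc:
            logits = flat @ self.params["Wd"] + self.params["bd"]
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            probs = (e / e.sum(axis=1, keepdims=True)).reshape(
                B, T, cfg.head_disc)
        if return_cache:
            return cont, probs, (X, gru_cache, acts)
        return cont, probs

    # -- loss + gradients ---------------------------------------------------

    def loss_and_grads(
        self,
        X: np.ndarray,
        mask: np.ndarray,
        y_cont: Optional[np.ndarray],
        y_disc: Optional[np.ndarray],
        cont_weight: float = 1.0,
        disc_weight: float = 1.0,
    ) -> Tuple[float, Params, Dict[str, float]]:
        """Masked MSE + cross-entropy loss and its parameter gradients."""
        cfg = self.config
        cont, probs, cache = self.forward(X, return_cache=True)
        Xc, gru_cache, acts = cache
        B, T, _ = Xc.shape
        m = np.asarray(mask, dtype=self.dtype).reshape(B, T)
        n_valid = float(m.sum())
        parts: Dict[str, float] = {}
        dflat = np.zeros_like(acts[-1])
        loss = 0.0
        if cfg.head_cont:
            err = (cont - y_cont) * m[:, :, None]
            denom = n_valid * cfg.head_cont
            mse = float((err ** 2).sum() / denom)
            parts["mse"] = mse
            loss += cont_weight * mse
            dcont = (2.0 * cont_weight / denom) * err
            dflat += dcont.reshape(B * T, -1) @ self.params["Wc"].T
        if cfg.head_disc:
            pflat = probs.reshape(B * T, cfg.head_disc)
            yflat = np.asarray(y_disc).reshape(B * T)
            mflat = m.reshape(B * T)
            picked = np.clip(pflat[np.arange(B * T), yflat], 1e-12, None)
            ce = float(-(np.log(picked) * mflat).sum() / n_valid)
            parts["cross_entropy"] = ce
            loss += disc_weight * ce
            dlogits = pflat.copy()
            dlogits[np.arange(B * T), yflat] -= 1.0
            dlogits *= (disc_weight / n_valid) * mflat[:, None]
            dflat += dlogits @ self.params["Wd"].T
        grads: Params = {}
        if cfg.head_cont:
            dcf = dcont.reshape(B * T, -1)
            grads["Wc"] = acts[-1].T @ dcf
            grads["bc"] = dcf.sum(axis=0)
        if cfg.head_disc:
            grads["Wd"] = acts[-1].T @ dlogits
            grads["bd"] = dlogits.sum(axis=0)
        d = dflat
        for i in range(cfg.mlp_depth - 1, -1, -1):
            d = d * (acts[i + 1] > 0)
            grads[f"Wm{i}"] = acts[i].T @ d
            grads[f"bm{i}"] = d.sum(axis=0)
            d = d @ self.params[f"Wm{i}"].T
        H = cfg.gru_units
        dS = d.reshape(B, T, -1)
        nd = len(self._dirs)
        dHout = np.empty((nd, T, B, H), dtype=dS.dtype)
        dHout[0] = dS[:, :, :H].transpose(1, 0, 2)
        if cfg.bidirectional:
            dHout[1] = dS[:, ::-1, H:].transpose(1, 0, 2)
        self._gru_backward(dHout, gru_cache, grads)
        return float(loss), grads, parts

    def evaluate_loss(self, X, mask, y_cont, y_disc,
                      cont_weight=1.0, disc_weight=1.0,
                      batch_size: int = 256) -> float:
        """Loss without gradients, streamed in batches (trial-weighted)."""
        total, weight = 0.0, 0.0
        for lo in range(0, X.shape[0], batch_size):
            sl = slice(lo, lo + batch_size)
            cont, probs = self.forward(X[sl])
            m = np.asarray(mask[sl], dtype=self.dtype)
            nv = float(m.sum())
            loss = 0.0
            if self.config.head_cont:
                err = (cont - y_cont[sl]) * m[:, :, None]
                loss += cont_weight * float(
                    (err ** 2).sum() / (nv * self.config.head_cont))
            if self.config.head_disc:
                B, T, M = probs.shape
                pf = probs.reshape(B * T, M)
                yf = np.asarray(y_disc[sl]).reshape(B * T)
                picked = np.clip(pf[np.arange(B * T), yf], 1e-12, None)
                loss += disc_weight * float(
                    -(np.log(picked) * m.reshape(B * T)).sum() / nv)
            total += loss * nv
            weight += nv
        return total / weight if weight else 0.0


def build_network(config: NetworkConfig, input_dim: int,
                  seed: int = 0) -> LaseNetwork:
    """Construct an untrained estimator with seeded initialization."""
    return LaseNetwork(config, input_dim, rng=np.random.default_rng(seed))


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

@dataclass
class TrainedEstimator:
    """A trained network plus everything needed to reload and audit it."""

    network: LaseNetwork
    model_id: str
    history: Dict[str, List[float]]
    best_epoch: int
    training_config: TrainingConfig

    @property
    def config(self) -> NetworkConfig:
        return self.network.config

    @property
    def input_dim(self) -> int:
        return self.network.input_dim


@dataclass
class EstimatorOutput:
    """Per-trial predictions from any estimator.

    ``continuous`` is N x T x C (or None); ``state_probs`` is N x T x M
    per-trial probability vectors (or None); ``states`` is the argmax
    label sequence when a discrete head is present.
    """

    continuous: Optional[np.ndarray]
    state_probs: Optional[np.ndarray]

    @property
    def states(self) -> Optional[np.ndarray]:
        if self.state_probs is None:
            return None
        return self.state_probs.argmax(axis=-1)


class _Adam:
    def __init__(self, params: Params, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            g = g.astype(params[k].dtype, copy=False)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def train_estimator(
    network: LaseNetwork,
    dataset: EncodedDataset,
    tcfg: TrainingConfig,
    verbose: bool = False,
) -> TrainedEstimator:
    """Train with Adam and early stopping on the validation split.

    The dataset's own agent-level train/validation split is used. Training
    stops when the validation loss has not improved for
    ``early_stop_patience`` epochs (or at ``max_epochs``) and the weights
    from the best validation epoch are restored.
    """
    cfg = network.config
    spec_cont = dataset.targets_cont.shape[2]
    if cfg.head_cont != spec_cont:
        raise SchemaError(
            f"continuous head {cfg.head_cont} != dataset channels {spec_cont}")
    if cfg.head_disc and dataset.targets_disc is None:
        raise SchemaError("discrete head but dataset has no discrete targets")
    X, Xm = dataset.inputs, dataset.mask
    yc = dataset.targets_cont if cfg.head_cont else None
    yd = dataset.targets_disc if cfg.head_disc else None
    tr, va = dataset.train_idx, dataset.val_idx
    if len(va) == 0:
        raise ConfigError("dataset has an empty validation split")

    rng = np.random.default_rng(tcfg.seed)
    opt = _Adam(network.params, tcfg.learning_rate)
    history: Dict[str, List[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_epoch = -1
    best_weights = {k: v.copy() for k, v in network.params.items()}
    since_best = 0
    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(tr)
        ep_loss, ep_w = 0.0, 0.0
        for lo in range(0, len(order), tcfg.batch_size):
            idx = order[lo: lo + tcfg.batch_size]
            loss, grads, _ = network.loss_and_grads(
                X[idx], Xm[idx],
                None if yc is None else yc[idx],
                None if yd is None else yd[idx],
                tcfg.cont_weight, tcfg.disc_weight,
            )
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            opt.step(network.params, grads)
            ep_loss += loss * len(idx)
            ep_w += len(idx)
        train_loss = ep_loss / ep_w
        val_loss = network.evaluate_loss(
            X[va], Xm[va],
            None if yc is None else yc[va],
            None if yd is None else yd[va],
            tcfg.cont_weight, tcfg.disc_weight,
        )
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(epoch)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if verbose:
            print(f"epoch {epoch}: train {train_loss:.5f} val {val_loss:.5f}")
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_weights = {k: v.copy() for k, v in network.params.items()}
            since_best = 0
        else:
            since_best += 1
            if (tcfg.lr_halve_patience is not None
                    and since_best % tcfg.lr_halve_patience == 0):
                opt.lr *= 0.5
            if since_best >= tcfg.early_stop_patience:
                break
    network.params = best_weights
    return TrainedEstimator(network, dataset.model_id, history, best_epoch, tcfg)


def predict_latents(
    estimator: TrainedEstimator, inputs: np.ndarray, batch_size: int = 256
) -> EstimatorOutput:
    """Amortized inference: one forward pass per batch of agents."""
    X = np.asarray(inputs, dtype=np.float32)
    if X.ndim != 3 or X.shape[2] != estimator.input_dim:
        raise SchemaError(
            f"input shaped {X.shape} incompatible with estimator "
            f"(model {estimator.model_id}, D_in={estimator.input_dim})")
    cfg = estimator.config
    if X.shape[0] == 0:
        return EstimatorOutput(
            np.zeros((0, X.shape[1], cfg.head_cont)) if cfg.head_cont else None,
            np.zeros((0, X.shape[1], cfg.head_disc)) if cfg.head_disc else None,
        )
    conts, probss = [], []
    for lo in range(0, X.shape[0], batch_size):
        cont, probs = estimator.network.forward(X[lo: lo + batch_size])
        if cont is not None:
            conts.append(cont)
        if probs is not None:
            probss.append(probs)
    return EstimatorOutput(
        np.concatenate(conts) if conts else None,
        np.concatenate(probss) if probss else None,
    )


# --------------------------------------------------------------------------
# Checkpoints
# --------------------------------------------------------------------------

def save_estimator(est: TrainedEstimator, directory: str | Path) -> None:
    """Write weight blob (npz) + human-readable estimator.json sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **est.network.params)
    sidecar = {
        "model_id": est.model_id,
        "input_dim": est.input_dim,
        "network": {
            "gru_units": est.config.gru_units,
            "mlp_depth": est.config.mlp_depth,
            "head_cont": est.config.head_cont,
            "head_disc": est.config.head_disc,
            "bidirectional": est.config.bidirectional,
        },
        "training": {
            "learning_rate": est.training_config.learning_rate,
            "batch_size": est.training_config.batch_size,
            "max_epochs": est.training_config.max_epochs,
            "early_stop_patience": est.training_config.early_stop_patience,
            "val_fraction": est.training_config.val_fraction,
            "seed": est.training_config.seed,
        },
        "history": est.history,
        "best_epoch": est.best_epoch,
    }
    (directory / "estimator.json").write_text(json.dumps(sidecar, indent=1))


def load_estimator(directory: str | Path) -> TrainedEstimator:
    directory = Path(directory)
    sidecar = json.loads((directory / "estimator.json").read_text())
    cfg = NetworkConfig(**sidecar["network"])
    net = LaseNetwork(cfg, sidecar["input_dim"])
    with np.load(directory / "weights.npz") as blob:
        net.params = {k: blob[k] for k in blob.files}
    tcfg = TrainingConfig(**sidecar["training"])
    return TrainedEstimator(
        net, sidecar["model_id"], sidecar["history"],
        sidecar["best_epoch"], tcfg,
    )
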