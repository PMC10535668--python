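"""Training loops: masked pretraining, frozen-encoder finetuning, prediction.

Both stages use Adam on an MSE objective and keep the checkpoint with the
lowest held-out loss (the selection criterion, not the epoch count, is the
contract).  All randomness flows from seeds in the config, so runs are
bit-reproducible.
"""
from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from ..config import MVNConfig
from .model import MAEEncoder, MaskedAutoencoder, MVNModel, patchify
from .nn import Adam, Module

__all__ = ["TrainingHistory", "tokenize_windows", "pretrain", "finetune", "predict"]


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val: float = float("inf")


def tokenize_windows(windows: np.ndarray, patch_len: int) -> np.ndarray:
    """(n, n_bins, W) window stack -> (n, n_tokens, patch_dim) token stack."""
    windows = np.asarray(windows, dtype=np.float64)
    return np.stack([patchify(w, patch_len) for w in windows])


def _snapshot(module: Module) -> list[np.ndarray]:
    return [p.data.copy() for p in module.parameters()]


def _restore(module: Module, arrays: list[np.ndarray]) -> None:
    for p, a in zip(module.parameters(), arrays):
        p.data[...] = a


def _val_split(n: int, rng: np.random.Generator, frac: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_val = max(1, int(round(frac * n))) if n > 1 else 0
    return perm[n_val:], perm[:n_val]


def pretrain(
    windows: np.ndarray,
    cfg: MVNConfig,
    epochs: int | None = None,
) -> tuple[MaskedAutoencoder, TrainingHistory]:
    """Masked self-supervised pretraining on unlabeled windows.

    ``windows`` is (n, n_bins, W); 10% are held out for checkpoint
    selection by reconstruction MSE (with fixed per-window masks so the
    validation objective is stable across epochs).
    """
    windows = np.asarray(windows, dtype=np.float64)
    if windows.ndim != 3 or windows.shape[0] == 0:
        raise ValueError("need a non-empty (n, n_bins, W) window stack")
    epochs = cfg.pretrain_epochs if epochs is None else epochs
    tokens = tokenize_windows(windows, cfg.patch_len)
    n, n_tok, _ = tokens.shape

    rng = np.random.default_rng(cfg.seed)
    model = MaskedAutoencoder(cfg, n_tok, np.random.default_rng(rng.integers(2**31)))
    train_idx, val_idx = _val_split(n, rng)
    if len(train_idx) == 0:
        train_idx, val_idx = np.arange(n), np.arange(n)
    val_tokens = tokens[val_idx] if len(val_idx) else tokens[train_idx]
    val_vis, val_masked = model.draw_masks(len(val_tokens), np.random.default_rng(rng.integers(2**31)))

    lr = cfg.pretrain_learning_rate if cfg.pretrain_learning_rate is not None else cfg.learning_rate
    opt = Adam(model.parameters(), lr)
    hist = TrainingHistory()
    best = _snapshot(model)
    for epoch in range(epochs):
        order = rng.permutation(train_idx)
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            batch = tokens[order[lo : lo + cfg.batch_size]]
            vis, masked = model.draw_masks(len(batch), rng)
            loss = model.loss(batch, vis, masked)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        hist.train_loss.append(float(np.mean(losses)))
        val = float(model.loss(val_tokens, val_vis, val_masked).data)
        hist.val_loss.append(val)
        if val < hist.best_val:
            hist.best_val, hist.best_epoch = val, epoch
            best = _snapshot(model)
    _restore(model, best)
    return model, hist


def finetune(
    model: MVNModel,
    windows: np.ndarray,
    labels_bpm: np.ndarray,
    cfg: MVNConfig,
    epochs: int | None = None,
    groups: np.ndarray | None = None,
) -> tuple[MVNModel, TrainingHistory]:
    """Supervised regression on labeled windows; encoder updated only when
    the model was built unfrozen.

    ``groups`` (e.g. recording ids) makes the held-out checkpoint-selection
    split group-aware, so overlapping windows of one recording never sit on
    both sides and the selected checkpoint reflects cross-recording error.
    """
    windows = np.asarray(windows, dtype=np.float64)
    labels_bpm = np.asarray(labels_bpm, dtype=np.float64)
    if len(windows) == 0:
        raise ValueError("empty labeled set")
    if np.ptp(labels_bpm) == 0:
        warnings.warn("all labels identical; regression target is degenerate")
    epochs = cfg.finetune_epochs if epochs is None else epochs
    tokens = tokenize_windows(windows, cfg.patch_len)
    targets = labels_bpm / cfg.label_scale

    rng = np.random.default_rng(cfg.seed + 1)
    if groups is not None:
        uniq = np.unique(groups)
        rng.shuffle(uniq)
        n_val_g = max(1, int(round(0.15 * len(uniq)))) if len(uniq) > 1 else 0
        val_groups = set(uniq[:n_val_g])
        in_val = np.array([g in val_groups for g in groups])
        train_idx, val_idx = np.flatnonzero(~in_val), np.flatnonzero(in_val)
    else:
        train_idx, val_idx = _val_split(len(tokens), rng)
    if len(train_idx) == 0:
        train_idx, val_idx = np.arange(len(tokens)), np.arange(len(tokens))
    if len(val_idx) == 0:
        val_idx = train_idx

    opt = Adam(model.trainable_parameters(), cfg.learning_rate)
    hist = TrainingHistory()
    best = _snapshot(model)
    for epoch in range(epochs):
        order = rng.permutation(train_idx)
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            pred = model.forward(tokens[idx])
            err = pred - targets[idx]
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        hist.train_loss.append(float(np.mean(losses)))
        val_pred = model.forward(tokens[val_idx]).data
        val = float(np.mean((val_pred - targets[val_idx]) ** 2))
        hist.val_loss.append(val)
        if val < hist.best_val:
            hist.best_val, hist.best_epoch = val, epoch
            best = _snapshot(model)
    _restore(model, best)
    return model, hist


def predict(model: MVNModel, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Deterministic forward pass (no masking); BPM per window."""
    windows = np.asarray(windows, dtype=np.float64)
    if windows.ndim == 2:
        windows = windows[None]
    tokens = tokenize_windows(windows, model.cfg.patch_len)
    out = [model.predict(tokens[lo : lo + batch_size])
           for lo in range(0, len(tokens), batch_size)]
    return np.concatenate(out)


def clone_encoder(encoder: MAEEncoder) -> MAEEncoder:
    """Independent deep copy (used to hand each ablation its own encoder)."""
    clone = copy.deepcopy(encoder)
    for p in clone.parameters():
        p.requires_grad = True
        p.grad = None
    return clone
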