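"""Shared optimization protocol for the autoencoder and the multi-task model.

Defaults: AdamW (weight decay 0.05), batch size 32, initial learning
rate 5e-4 halved every five epochs, early stopping with patience 3,
task-loss weights 0.8 (secondary structure) / 0.2 (burial), seed 42.
Sequences are padded to the longest in each batch; padded positions are
masked out of statistics and losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor


@dataclass
class TrainConfig:
    batch_size: int = 32
    initial_lr: float = 0.0005
    lr_halving_period: int = 5
    weight_decay: float = 0.05
    patience: int = 3
    loss_weights: tuple[float, float] = (0.8, 0.2)  # (SS, RSA)
    seed: int = 42
    max_epochs: int = 100

    def __post_init__(self) -> None:
        if abs(sum(self.loss_weights) - 1.0) > 1e-9:
            raise ValueError("loss weights must sum to 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Learning rate at a 0-based epoch: initial * 0.5 ** floor(epoch / period)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.initial_lr * 0.5 ** (epoch // config.lr_halving_period)


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without improvement.

    ``update`` returns True when training should stop; ``best_epoch``
    indexes the best value seen (higher-better by default).
    """

    def __init__(self, patience: int, higher_better: bool = True):
        self.patience = patience
        self.higher_better = higher_better
        self.best: Optional[float] = None
        self.best_epoch: Optional[int] = None
        self._since_best = 0
        self._epoch = -1

    def update(self, value: float) -> bool:
        self._epoch += 1
        improved = self.best is None or (
            value > self.best if self.higher_better else value < self.best)
        if improved:
            self.best = value
            self.best_epoch = self._epoch
            self._since_best = 0
        else:
            self._since_best += 1
        return self._since_best >= self.patience


@dataclass
class Batch:
    """A padded mini-batch: features (N, C, Lmax), validity mask (N, Lmax)."""

    features: np.ndarray
    mask: np.ndarray
    indices: np.ndarray
    lengths: np.ndarray
    labels: dict = field(default_factory=dict)  # name -> (N, Lmax) int array


def make_batches(features: Sequence[np.ndarray], batch_size: int,
                 rng: Optional[np.random.Generator] = None,
                 labels: Optional[dict] = None) -> Iterator[Batch]:
    """Yield shuffled, per-batch-padded batches.

    ``features[i]`` is the L_i x C matrix of record i; ``labels`` maps a
    track name to a sequence of per-record integer arrays.  Padded
    label positions carry -1.
    """
    n = len(features)
    if n == 0:
        raise ValueError("empty corpus")
    order = np.arange(n)
    if rng is not None:
        rng.shuffle(order)
    labels = labels or {}
    for lo in range(0, n, batch_size):
        idx = order[lo:lo + batch_size]
        lens = np.array([features[i].shape[0] for i in idx])
        L_max = int(lens.max())
        C = features[idx[0]].shape[1]
        X = np.zeros((len(idx), C, L_max))
        mask = np.zeros((len(idx), L_max))
        lab = {name: np.full((len(idx), L_max), -1, dtype=np.int64)
               for name in labels}
        for row, i in enumerate(idx):
            L = lens[row]
            X[row, :, :L] = features[i].T
            mask[row, :L] = 1.0
            for name, track in labels.items():
                lab[name][row, :L] = track[i]
        yield Batch(features=X, mask=mask, indices=idx, lengths=lens,
                    labels=lab)


def masked_cross_entropy(logits: Tensor, targets: np.ndarray,
                         mask: np.ndarray) -> Tensor:
    """Cross-entropy over valid positions of (N, C, L) logits."""
    N, C, L = logits.shape
    flat = ag.reshape(ag.transpose(logits, (0, 2, 1)), (N * L, C))
    t = targets.reshape(-1).copy()
    m = mask.reshape(-1).astype(float)
    t[t < 0] = 0  # padded positions are masked out anyway
    return ag.cross_entropy(flat, t, m)


def multitask_loss(ss_logits: Tensor, rsa_logits: Tensor,
                   ss_targets: np.ndarray, rsa_targets: np.ndarray,
                   mask: np.ndarray,
                   weights: tuple[float, float] = (0.8, 0.2)) -> Tensor:
    """Weighted sum of the two task cross-entropies over valid positions."""
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("loss weights must sum to 1")
    w_ss, w_rsa = weights
    loss = ag.mul(masked_cross_entropy(ss_logits, ss_targets, mask), w_ss)
    if w_rsa > 0:
        if rsa_targets is None:
            raise ValueError("RSA task enabled but no RSA targets supplied")
        loss = ag.add(loss, ag.mul(
            masked_cross_entropy(rsa_logits, rsa_targets, mask), w_rsa))
    return loss
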