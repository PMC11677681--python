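"""Segment-masking autoencoder producing the 4-channel sequence encoding.

The encoder is a chain of residual dynamic-convolution blocks: each
block pools the input over valid positions, derives per-sample softmax
attention over a bank of B candidate filters, convolves with the
weighted (combined) filter, and adds a batch-normalized 1x1-projected
residual before a LeakyReLU.  The decoder is a BiLSTM that reconstructs
the residue identity at every position from the narrow encoding.

Training masks one maximal single-category secondary-structure segment
per sequence (chosen uniformly at random each epoch) by zeroing its
one-hot rows, which ties the learned encoding to secondary-structure
segment context.  At encoding time inputs are not masked.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .features import one_hot_encode
from .metrics import extract_segments
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import BiRecurrent, Conv1d, Linear, MaskedBatchNorm1d, Module, _param
from .nn.optim import AdamW
from .records import ProteinRecord
from .train import TrainConfig, lr_schedule, make_batches, masked_cross_entropy

N_AA = 21


@dataclass
class HTAConfig:
    n_blocks: int = 2                 # A: residual dynamic-conv blocks
    n_filters: int = 3                # B: candidate filters per block
    kernel_size: int = 7
    hidden_channels: int = 16
    encoding_channels: int = 4
    decoder_layers: int = 2
    decoder_hidden: int = 20
    leaky_slope: float = 0.01
    mask_mode: str = "zero"           # or "token" (dedicated 22nd channel)
    loss_scope: str = "all"           # or "masked"

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_filters < 1:
            raise ValueError("n_blocks and n_filters must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd")
        if self.mask_mode not in ("zero", "token"):
            raise ValueError(f"unknown mask_mode {self.mask_mode!r}")
        if self.loss_scope not in ("all", "masked"):
            raise ValueError(f"unknown loss_scope {self.loss_scope!r}")

    @property
    def in_channels(self) -> int:
        return N_AA + (1 if self.mask_mode == "token" else 0)


class DyConvBlock(Module):
    """Residual block with a per-sample combined filter.

    attention = Softmax(Conv_1x1(GAP(X))); the combined filter is the
    attention-weighted sum of the B bank filters; output =
    LeakyReLU(BN(Conv_comb(X)) + BN(Conv_1x1(X))).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 n_filters: int, rng: np.random.Generator,
                 leaky_slope: float = 0.01):
        k = 1.0 / np.sqrt(in_channels * kernel_size)
        self.bank = _param(
            rng, (n_filters, out_channels, in_channels, kernel_size), k)
        self.bias = _param(rng, (out_channels,), k)
        self.attn_w = _param(rng, (in_channels, n_filters),
                             1.0 / np.sqrt(in_channels))
        self.attn_b = _param(rng, (n_filters,), 1.0 / np.sqrt(in_channels))
        self.bn_main = MaskedBatchNorm1d(out_channels)
        self.proj = Conv1d(in_channels, out_channels, 1, rng, bias=True)
        self.bn_res = MaskedBatchNorm1d(out_channels)
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.leaky_slope = leaky_slope

    def attention(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """Per-sample softmax weights over the filter bank (rows sum to 1)."""
        m3 = mask[:, None, :].astype(float)
        count = mask.sum(axis=1, keepdims=True).astype(float)  # (N, 1)
        pooled = ag.mul(ag.tsum(ag.mul(x, m3), axis=2), 1.0 / count)  # (N, C)
        logits = ag.add(ag.matmul(pooled, self.attn_w), self.attn_b)
        return ag.softmax(logits, axis=1)  # (N, B)

    def combined_filter(self, weights: Tensor) -> Tensor:
        """Attention-weighted sum of bank filters, one filter per sample."""
        B = self.n_filters
        flat = ag.reshape(self.bank, (B, -1))          # (B, O*C*K)
        comb = ag.matmul(weights, flat)                # (N, O*C*K)
        return ag.reshape(comb, (weights.shape[0], self.out_channels,
                                 self.in_channels, self.kernel_size))

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        weights = self.attention(x, mask)
        comb = self.combined_filter(weights)
        main = ag.conv1d(x, comb, self.bias, padding="same")
        main = self.bn_main(main, mask)
        res = self.bn_res(self.proj(x), mask)
        out = ag.leaky_relu(ag.add(main, res), self.leaky_slope)
        # keep padded positions at zero so downstream convolutions see the
        # same left/right context as an unpadded batch
        return ag.mul(out, mask[:, None, :].astype(float))


class HTA(Module):
    """Encoder (dynamic-conv chain) + decoder (BiLSTM -> 21-way logits)."""

    def __init__(self, config: HTAConfig, rng: np.random.Generator):
        self.config = config
        chans = ([config.in_channels]
                 + [config.hidden_channels] * (config.n_blocks - 1)
                 + [config.encoding_channels])
        self.blocks = [
            DyConvBlock(chans[i], chans[i + 1], config.kernel_size,
                        config.n_filters, rng, config.leaky_slope)
            for i in range(config.n_blocks)
        ]
        self.decoder_rnn = BiRecurrent(
            "lstm", config.encoding_channels, config.decoder_hidden,
            config.decoder_layers, rng)
        self.out = Linear(2 * config.decoder_hidden, N_AA, rng)

    def encode(self, x: Tensor, mask: np.ndarray) -> Tensor:
        out = x
        for block in self.blocks:
            out = block(out, mask)
        return out  # (N, encoding_channels, L)

    def decode(self, encoding: Tensor, mask: np.ndarray) -> Tensor:
        hidden = self.decoder_rnn(encoding, mask=mask)  # (N, 2H, L)
        N, C, L = hidden.shape
        flat = ag.reshape(ag.transpose(hidden, (0, 2, 1)), (N * L, C))
        logits = self.out(flat)
        return ag.transpose(ag.reshape(logits, (N, L, N_AA)), (0, 2, 1))

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        return self.decode(self.encode(x, mask), mask)


# ----------------------------------------------------------- masking

def mask_segment(record: ProteinRecord, rng: np.random.Generator,
                 mask_mode: str = "zero") -> tuple[np.ndarray, np.ndarray]:
    """Mask one uniformly chosen single-category segment of the one-hot input.

    Returns (masked one-hot, boolean mask of masked positions).  Under
    "zero" the masked rows are all-zero; under "token" a 22nd channel is
    appended and set to 1 on masked rows.  Label tracks are untouched.
    """
    if record.ss8 is None:
        raise ValueError(f"record {record.id!r} has no ss8 labels to mask by")
    one_hot = one_hot_encode(record.sequence)
    if mask_mode == "token":
        one_hot = np.concatenate(
            [one_hot, np.zeros((one_hot.shape[0], 1))], axis=1)
    segments = extract_segments(record.ss8)
    seg = segments[int(rng.integers(len(segments)))]
    positions = np.zeros(len(record), dtype=bool)
    positions[seg.start:seg.end] = True
    one_hot[positions, :N_AA] = 0.0
    if mask_mode == "token":
        one_hot[positions, N_AA] = 1.0
    return one_hot, positions


# ----------------------------------------------------------- training

def default_hta_train_config(**overrides) -> TrainConfig:
    """Pre-training protocol for the autoencoder.

    Unlike predictor fine-tuning, learning the narrow sequence code from
    scratch needs a constant learning rate: a halving schedule caps the
    cumulative parameter movement after a few desk-scale epochs (each
    only a handful of updates) and the reconstruction stalls at the
    marginal residue distribution.  Default: constant 2e-3.
    """
    base = dict(initial_lr=0.002, lr_halving_period=10 ** 6)
    base.update(overrides)
    return TrainConfig(**base)


def train_hta(records: Sequence[ProteinRecord], config: HTAConfig,
              train_config: Optional[TrainConfig] = None,
              n_epochs: int = 10,
              ) -> tuple[HTA, list[float]]:
    """Train the autoencoder on a labeled corpus; returns (model, loss history).

    Each epoch draws a fresh random masked segment per sequence.  The
    reconstruction loss is cross-entropy against the true residue
    identities over all valid positions (or masked positions only,
    per ``config.loss_scope``).
    """
    if len(records) == 0:
        raise ValueError("empty corpus")
    tc = train_config or default_hta_train_config()
    rng = np.random.default_rng(tc.seed)
    model = HTA(config, rng)
    opt = AdamW(model.parameters(), lr=tc.initial_lr,
                weight_decay=tc.weight_decay)
    targets = [r.aa_indices for r in records]
    history: list[float] = []
    for epoch in range(n_epochs):
        opt.lr = lr_schedule(epoch, tc)
        model.train()
        epoch_loss = 0.0
        n_batches = 0
        feats, masked_flags = [], []
        for rec in records:
            oh, pos = mask_segment(rec, rng, config.mask_mode)
            feats.append(oh)
            masked_flags.append(pos.astype(np.int64))
        for batch in make_batches(feats, tc.batch_size, rng=rng,
                                  labels={"aa": targets,
                                          "masked": masked_flags}):
            x = Tensor(batch.features)
            logits = model(x, batch.mask)
            loss_mask = batch.mask
            if config.loss_scope == "masked":
                loss_mask = batch.mask * (batch.labels["masked"] == 1)
            loss = masked_cross_entropy(logits, batch.labels["aa"], loss_mask)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        history.append(epoch_loss / n_batches)
    model.eval()
    return model, history


def encode_records(model: HTA, records: Sequence[ProteinRecord],
                   batch_size: int = 32) -> list[np.ndarray]:
    """Export the L x 4 encoding of each record (non-masked input, eval mode)."""
    model.eval()
    feats = [one_hot_encode(r.sequence) for r in records]
    if model.config.mask_mode == "token":
        feats = [np.concatenate([f, np.zeros((f.shape[0], 1))], axis=1)
                 for f in feats]
    out: list[Optional[np.ndarray]] = [None] * len(records)
    for batch in make_batches(feats, batch_size):
        enc = model.encode(Tensor(batch.features), batch.mask)
        for row, i in enumerate(batch.indices):
            L = batch.lengths[row]
            out[i] = enc.data[row, :, :L].T.copy()
    return out


def reconstruction_accuracy(model: HTA, records: Sequence[ProteinRecord],
                            rng: np.random.Generator,
                            masked_only: bool = True) -> float:
    """Fraction of (masked) positions whose residue is reconstructed correctly."""
    model.eval()
    correct = total = 0
    for rec in records:
        oh, pos = mask_segment(rec, rng, model.config.mask_mode)
        logits = model(Tensor(oh.T[None]), np.ones((1, len(rec))))
        pred = logits.data[0].argmax(axis=0)
        sel = pos if masked_only else np.ones(len(rec), dtype=bool)
        correct += int((pred[sel] == rec.aa_indices[sel]).sum())
        total += int(sel.sum())
    return correct / total


# --------------------------------------------------------- checkpoints

def save_hta(model: HTA, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"config": model.config,
                     "state": model.state_dict()}, fh)


def load_hta(path) -> HTA:
    with open(Path(path), "rb") as fh:
        payload = pickle.load(fh)
    model = HTA(payload["config"], np.random.default_rng(0))
    model.load_state_dict(payload["state"])
    model.eval()
    return model
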