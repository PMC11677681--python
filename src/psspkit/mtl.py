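"""Multi-task secondary-structure + burial predictor with MMoE sharing.

Pipeline: the per-residue input channels (one-hot, profiles,
physicochemical, autoencoder encoding — each individually toggleable)
pass through a multi-scale residual convolution; any language-model
embedding joins by concatenation afterwards.  A multi-gate
mixture-of-experts layer then produces one fused feature per task: E
shared expert networks are softly combined by per-task gating networks
whose softmax weights are position-specific, plus a per-task projected
residual.  Each task tower is a causal dilated temporal convolution
stack (dilation doubling per block) followed by a BiGRU, and ends in a
per-position softmax head: an 8-state (or 3-state) secondary-structure
task and a 2-class buried/exposed auxiliary task.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alphabet import SS3, SS8
from .analysis import RSA_THRESHOLD
from .metrics import q_accuracy
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import BiRecurrent, Conv1d, MaskedBatchNorm1d, Module
from .nn.optim import AdamW
from .records import FeatureBundle, ProteinRecord
from .train import (TrainConfig, EarlyStopper, lr_schedule, make_batches,
                    multitask_loss)

FEATURE_WIDTHS = {"one_hot": 21, "pssm": 20, "hmm": 30, "physchem": 7,
                  "hta_encoding": 4}


@dataclass
class MTLConfig:
    scales: tuple[int, ...] = (1, 5, 9)
    channels_per_scale: int = 32
    n_experts: int = 3                  # E
    expert_depth: int = 2               # beta: Conv+BN pairs per expert
    expert_channels: int = 64           # CH
    tcn_blocks: int = 3                 # M, dilation 2**(i-1)
    tcn_kernel: int = 3
    bigru_layers: int = 1
    bigru_hidden: int = 32
    n_classes_ss: int = 8
    leaky_slope: float = 0.01
    features: tuple[str, ...] = ("one_hot", "pssm", "hmm", "physchem",
                                 "hta_encoding")
    embedding_dim: int = 0              # 0 disables the embedding channel
    n_tasks: int = 2

    def __post_init__(self) -> None:
        if not self.scales:
            raise ValueError("at least one convolution scale required")
        if any(s % 2 == 0 for s in self.scales):
            raise ValueError("scales must be odd")
        if self.n_experts < 1:
            raise ValueError("need at least one expert")
        if self.n_classes_ss not in (3, 8):
            raise ValueError("n_classes_ss must be 3 or 8")
        unknown = set(self.features) - set(FEATURE_WIDTHS)
        if unknown:
            raise ValueError(f"unknown feature channels {sorted(unknown)}")
        if not self.features and self.embedding_dim == 0:
            raise ValueError("no input channels enabled")

    @property
    def input_channels(self) -> int:
        return sum(FEATURE_WIDTHS[f] for f in self.features)

    @property
    def fused_channels(self) -> int:
        return len(self.scales) * self.channels_per_scale + self.embedding_dim

    @property
    def ss_states(self) -> str:
        return SS8 if self.n_classes_ss == 8 else SS3


class MultiScaleResConv(Module):
    """Per scale: LeakyReLU(projected residual + scale-s convolution)."""

    def __init__(self, in_channels: int, config: MTLConfig,
                 rng: np.random.Generator):
        cps = config.channels_per_scale
        self.convs = [Conv1d(in_channels, cps, s, rng) for s in config.scales]
        self.residuals = [Conv1d(in_channels, cps, 1, rng)
                          for _ in config.scales]
        self.slope = config.leaky_slope

    def __call__(self, x: Tensor, mask: Optional[np.ndarray] = None,
                 embedding: Optional[Tensor] = None) -> Tensor:
        outs = [ag.leaky_relu(ag.add(res(x), conv(x)), self.slope)
                for conv, res in zip(self.convs, self.residuals)]
        if embedding is not None:
            outs.append(embedding)
        out = ag.concat(outs, axis=1)
        if mask is not None:
            out = ag.mul(out, mask[:, None, :].astype(float))
        return out


class Expert(Module):
    """beta Conv1D+BN pairs (LeakyReLU between pairs)."""

    def __init__(self, in_channels: int, config: MTLConfig,
                 rng: np.random.Generator):
        ch = config.expert_channels
        self.convs, self.bns = [], []
        d_in = in_channels
        for _ in range(config.expert_depth):
            self.convs.append(Conv1d(d_in, ch, 3, rng))
            self.bns.append(MaskedBatchNorm1d(ch))
            d_in = ch
        self.slope = config.leaky_slope

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        out = x
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            out = bn(conv(out), mask)
            if i < len(self.convs) - 1:
                out = ag.leaky_relu(out, self.slope)
            out = ag.mul(out, mask[:, None, :].astype(float))
        return out


class MMoE(Module):
    """Multi-gate mixture of experts with per-task projected residuals.

    Gate weights are softmax-normalized across experts independently at
    every sequence position and broadcast down the channel rows.
    """

    def __init__(self, in_channels: int, config: MTLConfig,
                 rng: np.random.Generator):
        ch = config.expert_channels
        self.experts = [Expert(in_channels, config, rng)
                        for _ in range(config.n_experts)]
        self.gate_convs = [Conv1d(in_channels, config.n_experts, 1, rng)
                           for _ in range(config.n_tasks)]
        self.gate_bns = [MaskedBatchNorm1d(config.n_experts)
                         for _ in range(config.n_tasks)]
        self.res_convs = [Conv1d(in_channels, ch, 1, rng)
                          for _ in range(config.n_tasks)]
        self.res_bns = [MaskedBatchNorm1d(ch) for _ in range(config.n_tasks)]
        self.slope = config.leaky_slope

    def gates(self, x: Tensor, mask: np.ndarray) -> list[Tensor]:
        """Per task: (N, E, L) weights summing to 1 over E at each position."""
        out = []
        for conv, bn in zip(self.gate_convs, self.gate_bns):
            g = ag.leaky_relu(bn(conv(x), mask), self.slope)
            out.append(ag.softmax(g, axis=1))
        return out

    def __call__(self, x: Tensor, mask: np.ndarray) -> list[Tensor]:
        gate_weights = self.gates(x, mask)
        expert_outs = [e(x, mask) for e in self.experts]  # each (N, CH, L)
        fused = []
        for j, (rconv, rbn) in enumerate(zip(self.res_convs, self.res_bns)):
            res = rbn(rconv(x), mask)
            mix = None
            for k, ex in enumerate(expert_outs):
                w = gate_weights[j][:, k:k + 1, :]  # (N, 1, L) broadcast
                term = ag.mul(ex, w)
                mix = term if mix is None else ag.add(mix, term)
            out = ag.leaky_relu(ag.add(res, mix), self.slope)
            fused.append(ag.mul(out, mask[:, None, :].astype(float)))
        return fused


class TCN(Module):
    """Causal dilated residual conv stack; block i has dilation 2**(i-1)."""

    def __init__(self, channels: int, config: MTLConfig,
                 rng: np.random.Generator):
        self.blocks = []
        for i in range(config.tcn_blocks):
            d = 2 ** i
            conv1 = Conv1d(channels, channels, config.tcn_kernel, rng,
                           dilation=d, padding="causal")
            bn1 = MaskedBatchNorm1d(channels)
            conv2 = Conv1d(channels, channels, config.tcn_kernel, rng,
                           dilation=d, padding="causal")
            bn2 = MaskedBatchNorm1d(channels)
            self.blocks.append((conv1, bn1, conv2, bn2))
        self.slope = config.leaky_slope

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        m3 = mask[:, None, :].astype(float)
        out = x
        for conv1, bn1, conv2, bn2 in self.blocks:
            h = ag.mul(ag.leaky_relu(bn1(conv1(out), mask), self.slope), m3)
            h = bn2(conv2(h), mask)
            out = ag.mul(ag.leaky_relu(ag.add(out, h), self.slope), m3)
        return out


class TaskTower(Module):
    """TCN -> BiGRU -> 1x1 conv head producing per-position class logits."""

    def __init__(self, channels: int, n_classes: int, config: MTLConfig,
                 rng: np.random.Generator):
        self.tcn = TCN(channels, config, rng)
        self.rnn = BiRecurrent("gru", channels, config.bigru_hidden,
                               config.bigru_layers, rng)
        self.head = Conv1d(2 * config.bigru_hidden, n_classes, 1, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        out = self.tcn(x, mask)
        out = self.rnn(out, mask=mask)
        return self.head(out)


@dataclass
class MTLOutput:
    """Per-record probability matrices for both tasks."""

    ss_probs: np.ndarray   # L x n_classes_ss, rows sum to 1
    rsa_probs: np.ndarray  # L x 2

    @property
    def ss_string(self) -> str:
        states = SS8 if self.ss_probs.shape[1] == 8 else SS3
        return "".join(states[i] for i in self.ss_probs.argmax(axis=1))

    @property
    def rsa_bins(self) -> np.ndarray:
        return self.rsa_probs.argmax(axis=1)  # 0 buried, 1 exposed


class PSSPMTL(Module):
    """The full multi-task network."""

    def __init__(self, config: MTLConfig, rng: np.random.Generator):
        self.config = config
        self.msrc = MultiScaleResConv(config.input_channels, config, rng)
        self.mmoe = MMoE(config.fused_channels, config, rng)
        self.towers = [
            TaskTower(config.expert_channels, config.n_classes_ss, config, rng),
            TaskTower(config.expert_channels, 2, config, rng),
        ]

    def __call__(self, x: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        cfg = self.config
        embedding = None
        if cfg.embedding_dim > 0:
            if x.shape[1] != cfg.input_channels + cfg.embedding_dim:
                raise ValueError(
                    f"expected {cfg.input_channels + cfg.embedding_dim} "
                    f"channels (conv + embedding), got {x.shape[1]}")
            embedding = x[:, cfg.input_channels:, :]
            x = x[:, :cfg.input_channels, :]
        elif x.shape[1] != cfg.input_channels:
            raise ValueError(
                f"expected {cfg.input_channels} input channels, got {x.shape[1]}")
        fc = self.msrc(x, mask, embedding)
        fused = self.mmoe(fc, mask)
        ss_logits = self.towers[0](fused[0], mask)
        rsa_logits = self.towers[1](fused[1], mask)
        return ss_logits, rsa_logits


# ------------------------------------------------------- data plumbing

def assemble_features(bundles: Sequence[FeatureBundle],
                      config: MTLConfig) -> list[np.ndarray]:
    """Stack each record's enabled channels into an L x C matrix.

    When the embedding channel is enabled its columns are appended last;
    the model routes them around the multi-scale convolution.
    """
    out = []
    for b in bundles:
        mat = b.channels(list(config.features))
        if config.embedding_dim > 0:
            if b.embedding is None:
                raise ValueError("embedding channel enabled but missing")
            if b.embedding.shape[1] != config.embedding_dim:
                raise ValueError(
                    f"embedding width {b.embedding.shape[1]} != configured "
                    f"{config.embedding_dim}")
            mat = np.concatenate([mat, b.embedding], axis=1)
        out.append(mat)
    return out


def ss_targets(records: Sequence[ProteinRecord],
               config: MTLConfig) -> list[np.ndarray]:
    from .alphabet import SS3_INDEX, SS8_INDEX, map_ss8_to_ss3
    out = []
    for rec in records:
        if rec.ss8 is None:
            raise ValueError(f"record {rec.id!r} has no ss8 labels")
        if config.n_classes_ss == 8:
            out.append(np.array([SS8_INDEX[c] for c in rec.ss8]))
        else:
            out.append(np.array([SS3_INDEX[c]
                                 for c in map_ss8_to_ss3(rec.ss8)]))
    return out


def rsa_targets(records: Sequence[ProteinRecord]) -> list[np.ndarray]:
    out = []
    for rec in records:
        if rec.rsa is None:
            raise ValueError(f"record {rec.id!r} has no RSA track")
        out.append((rec.rsa > RSA_THRESHOLD).astype(np.int64))
    return out


# ----------------------------------------------------------- training

def train_mtl(records: Sequence[ProteinRecord],
              features: Sequence[np.ndarray],
              config: MTLConfig,
              train_config: Optional[TrainConfig] = None,
              validation: Optional[tuple] = None,
              n_epochs: Optional[int] = None,
              ) -> tuple["PSSPMTL", dict]:
    """Train the multi-task model; returns (best model, history).

    ``validation`` is an optional (records, features) pair monitored by
    the early stopper (secondary-structure Q accuracy, higher-better);
    without it the stopper watches training loss (lower-better).
    """
    tc = train_config or TrainConfig()
    n_epochs = n_epochs if n_epochs is not None else tc.max_epochs
    rng = np.random.default_rng(tc.seed)
    model = PSSPMTL(config, rng)
    opt = AdamW(model.parameters(), lr=tc.initial_lr,
                weight_decay=tc.weight_decay)
    ss_lab = ss_targets(records, config)
    rsa_lab = rsa_targets(records)
    # the monitor is Q accuracy with validation, negated loss without:
    # higher is better either way
    stopper = EarlyStopper(tc.patience, higher_better=True)
    history = {"loss": [], "lr": [], "monitor": []}
    best_state = model.state_dict()
    for epoch in range(n_epochs):
        opt.lr = lr_schedule(epoch, tc)
        model.train()
        epoch_loss, n_batches = 0.0, 0
        for batch in make_batches(features, tc.batch_size, rng=rng,
                                  labels={"ss": ss_lab, "rsa": rsa_lab}):
            ss_logits, rsa_logits = model(Tensor(batch.features), batch.mask)
            loss = multitask_loss(ss_logits, rsa_logits, batch.labels["ss"],
                                  batch.labels["rsa"], batch.mask,
                                  tc.loss_weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        epoch_loss /= n_batches
        history["loss"].append(epoch_loss)
        history["lr"].append(opt.lr)
        if validation is not None:
            val_records, val_features = validation
            outputs = predict(model, val_features)
            monitor = np.mean([
                q_accuracy(o.ss_string,
                           _obs_string(r, config))
                for o, r in zip(outputs, val_records)])
        else:
            monitor = -epoch_loss  # higher-better convention internally
        history["monitor"].append(float(monitor))
        if monitor == max(history["monitor"]):
            best_state = model.state_dict()
        if stopper.update(float(monitor)):
            break
    model.load_state_dict(best_state)
    model.eval()
    history["best_epoch"] = int(np.argmax(history["monitor"]))
    return model, history


def _obs_string(record: ProteinRecord, config: MTLConfig) -> str:
    from .alphabet import map_ss8_to_ss3
    return record.ss8 if config.n_classes_ss == 8 else map_ss8_to_ss3(record.ss8)


def predict(model: PSSPMTL, features: Sequence[np.ndarray],
            batch_size: int = 32) -> list[MTLOutput]:
    """Evaluation-mode per-record class probabilities for both tasks."""
    model.eval()
    out: list[Optional[MTLOutput]] = [None] * len(features)
    for batch in make_batches(features, batch_size):
        ss_logits, rsa_logits = model(Tensor(batch.features), batch.mask)
        ss_p = ag.softmax(ss_logits, axis=1).data
        rsa_p = ag.softmax(rsa_logits, axis=1).data
        for row, i in enumerate(batch.indices):
            L = batch.lengths[row]
            out[i] = MTLOutput(ss_probs=ss_p[row, :, :L].T.copy(),
                               rsa_probs=rsa_p[row, :, :L].T.copy())
    return out


def majority_class_q(records: Sequence[ProteinRecord],
                     config: MTLConfig) -> float:
    """Q accuracy of always predicting the corpus's most common category."""
    from collections import Counter
    counts: Counter = Counter()
    for rec in records:
        counts.update(_obs_string(rec, config))
    total = sum(counts.values())
    return 100.0 * max(counts.values()) / total


# --------------------------------------------------------- checkpoints

def save_mtl(model: PSSPMTL, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"config": model.config,
                     "state": model.state_dict()}, fh)


def load_mtl(path) -> PSSPMTL:
    with open(Path(path), "rb") as fh:
        payload = pickle.load(fh)
    model = PSSPMTL(payload["config"], np.random.default_rng(0))
    model.load_state_dict(payload["state"])
    model.eval()
    return model
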