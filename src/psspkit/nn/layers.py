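"""Layers for masked, variable-length sequence batches.

All sequence layers operate on (N, C, L) arrays with an accompanying
(N, L) validity mask; padded positions are excluded from batch-norm
statistics and from losses.  Recurrent layers consume (N, C, L) and
return (N, H, L).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter discovery plus train/eval mode switching."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj) -> None:
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]

        def collect(obj) -> None:
            if isinstance(obj, Module):
                mods.extend(obj.modules())
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    collect(item)

        for v in vars(self).values():
            collect(v)
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def state_dict(self) -> dict:
        buffers = []
        for m in self.modules():
            if hasattr(m, "running_mean"):
                buffers.append((m.running_mean.copy(), m.running_var.copy()))
        return {"params": [p.data.copy() for p in self.parameters()],
                "bn_buffers": buffers}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(params) != len(state["params"]):
            raise ValueError("checkpoint parameter count mismatch")
        for p, d in zip(params, state["params"]):
            if p.data.shape != d.shape:
                raise ValueError(
                    f"checkpoint shape {d.shape} != parameter {p.data.shape}")
            p.data = np.asarray(d, dtype=np.float64).copy()
        bns = [m for m in self.modules() if hasattr(m, "running_mean")]
        buffers = state.get("bn_buffers", [])
        if len(bns) != len(buffers):
            raise ValueError("checkpoint batch-norm buffer count mismatch")
        for m, (mean, var) in zip(bns, buffers):
            m.running_mean = np.asarray(mean, dtype=np.float64).copy()
            m.running_var = np.asarray(var, dtype=np.float64).copy()


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    t = Tensor(rng.uniform(-scale, scale, size=shape))
    t.requires_grad = True
    return t


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        k = 1.0 / np.sqrt(in_features)
        self.weight = _param(rng, (in_features, out_features), k)
        self.bias = _param(rng, (out_features,), k)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.weight), self.bias)


class Conv1d(Module):
    """Shared-filter 1-D convolution; "same" or "causal" padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dilation: int = 1,
                 padding: str = "same", bias: bool = True):
        if padding == "same" and kernel_size % 2 == 0:
            raise ValueError("same padding requires an odd kernel")
        k = 1.0 / np.sqrt(in_channels * kernel_size)
        self.weight = _param(rng, (out_channels, in_channels, kernel_size), k)
        self.bias = _param(rng, (out_channels,), k) if bias else None
        self.dilation = dilation
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1d(x, self.weight, self.bias,
                         dilation=self.dilation, padding=self.padding)


class MaskedBatchNorm1d(Module):
    """Per-channel batch normalization over valid (non-padded) positions."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones((1, channels, 1)))
        self.gamma.requires_grad = True
        self.beta = Tensor(np.zeros((1, channels, 1)))
        self.beta.requires_grad = True
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros((1, channels, 1))
        self.running_var = np.ones((1, channels, 1))

    def __call__(self, x: Tensor, mask: Optional[np.ndarray] = None) -> Tensor:
        if mask is None:
            mask = np.ones((x.shape[0], x.shape[2]))
        m3 = mask[:, None, :].astype(float)
        count = float(m3.sum())
        if self.training:
            mean = ag.mul(ag.tsum(ag.mul(x, m3), axis=(0, 2), keepdims=True),
                          1.0 / count)
            diff = ag.add(x, ag.mul(mean, -1.0))
            var = ag.mul(ag.tsum(ag.mul(ag.mul(diff, diff), m3),
                                 axis=(0, 2), keepdims=True), 1.0 / count)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
        else:
            mean = Tensor(self.running_mean)
            diff = ag.add(x, ag.mul(mean, -1.0))
            var = Tensor(self.running_var)
        inv = ag.power(ag.add(var, self.eps), -0.5)
        xhat = ag.mul(diff, inv)
        return ag.add(ag.mul(xhat, self.gamma), self.beta)


class _RecurrentBase(Module):
    def __init__(self, input_size: int, hidden_size: int, gates: int,
                 rng: np.random.Generator):
        k = 1.0 / np.sqrt(hidden_size)
        self.W = _param(rng, (hidden_size + input_size, gates * hidden_size), k)
        self.b = _param(rng, (gates * hidden_size,), k)
        self.hidden_size = hidden_size


class LSTMCellLayer(_RecurrentBase):
    """One direction of LSTM over (N, C, L); gates f, i, o and candidate."""

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator):
        super().__init__(input_size, hidden_size, 4, rng)

    def __call__(self, x: Tensor, reverse: bool = False,
                 mask: Optional[np.ndarray] = None) -> Tensor:
        N, _, L = x.shape
        H = self.hidden_size
        h = Tensor(np.zeros((N, H)))
        c = Tensor(np.zeros((N, H)))
        steps = range(L - 1, -1, -1) if reverse else range(L)
        outs: list[Optional[Tensor]] = [None] * L
        for t in steps:
            xt = x[:, :, t]
            z = ag.add(ag.matmul(ag.concat([h, xt], axis=1), self.W), self.b)
            f = ag.sigmoid(z[:, 0 * H:1 * H])
            i = ag.sigmoid(z[:, 1 * H:2 * H])
            o = ag.sigmoid(z[:, 2 * H:3 * H])
            g = ag.tanh(z[:, 3 * H:4 * H])
            c_new = ag.add(ag.mul(f, c), ag.mul(i, g))
            h_new = ag.mul(o, ag.tanh(c_new))
            if mask is not None:
                m = mask[:, t:t + 1].astype(float)  # (N, 1)
                c = ag.add(ag.mul(c_new, m), ag.mul(c, 1.0 - m))
                h = ag.add(ag.mul(h_new, m), ag.mul(h, 1.0 - m))
            else:
                c, h = c_new, h_new
            outs[t] = h
        return ag.stack(outs, axis=2)  # (N, H, L)


class GRUCellLayer(_RecurrentBase):
    """One direction of GRU over (N, C, L); reset/update gates.

    h_t = z_t * h_{t-1} + (1 - z_t) * tanh(W_h [r_t * h_{t-1}, x_t] + b_h)
    """

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator):
        super().__init__(input_size, hidden_size, 2, rng)
        k = 1.0 / np.sqrt(hidden_size)
        self.W_h = _param(rng, (hidden_size + input_size, hidden_size), k)
        self.b_h = _param(rng, (hidden_size,), k)

    def __call__(self, x: Tensor, reverse: bool = False,
                 mask: Optional[np.ndarray] = None) -> Tensor:
        N, _, L = x.shape
        H = self.hidden_size
        h = Tensor(np.zeros((N, H)))
        steps = range(L - 1, -1, -1) if reverse else range(L)
        outs: list[Optional[Tensor]] = [None] * L
        for t in steps:
            xt = x[:, :, t]
            z_in = ag.add(ag.matmul(ag.concat([h, xt], axis=1), self.W), self.b)
            r = ag.sigmoid(z_in[:, 0 * H:1 * H])
            z = ag.sigmoid(z_in[:, 1 * H:2 * H])
            cand = ag.tanh(ag.add(
                ag.matmul(ag.concat([ag.mul(r, h), xt], axis=1), self.W_h),
                self.b_h))
            h_new = ag.add(ag.mul(z, h),
                           ag.mul(ag.add(1.0, ag.mul(z, -1.0)), cand))
            if mask is not None:
                m = mask[:, t:t + 1].astype(float)
                h = ag.add(ag.mul(h_new, m), ag.mul(h, 1.0 - m))
            else:
                h = h_new
            outs[t] = h
        return ag.stack(outs, axis=2)


class BiRecurrent(Module):
    """Bidirectional, optionally multi-layer recurrent stack.

    Each layer runs a forward and a backward cell and concatenates the
    two hidden tracks channel-wise (output channels = 2 * hidden).
    """

    def __init__(self, cell_type: str, input_size: int, hidden_size: int,
                 num_layers: int, rng: np.random.Generator,
                 bidirectional: bool = True):
        cls = {"lstm": LSTMCellLayer, "gru": GRUCellLayer}[cell_type]
        self.layers = []
        self.bidirectional = bidirectional
        d_in = input_size
        for _ in range(num_layers):
            fwd = cls(d_in, hidden_size, rng)
            bwd = cls(d_in, hidden_size, rng) if bidirectional else None
            self.layers.append((fwd, bwd))
            d_in = hidden_size * (2 if bidirectional else 1)
        self.out_channels = d_in

    def __call__(self, x: Tensor,
                 mask: Optional[np.ndarray] = None) -> Tensor:
        out = x
        for fwd, bwd in self.layers:
            tracks = [fwd(out, mask=mask)]
            if bwd is not None:
                tracks.append(bwd(out, reverse=True, mask=mask))
            out = ag.concat(tracks, axis=1) if len(tracks) > 1 else tracks[0]
        return out
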