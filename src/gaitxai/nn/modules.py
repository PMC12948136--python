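"""Neural network layers on top of the autodiff engine.

Every layer is a :class:`Module`. Parameters are ``Tensor`` objects with
``requires_grad=True``; sharing a layer instance between two parents shares
its weights (parameter collection de-duplicates by identity), which is how
the fusion architecture ties its per-stream embedding projections.

Layers used by relevance propagation additionally retain, when the model is
run through ``gaitxai.lrp.forward_trace``, their last input/output arrays;
that bookkeeping lives in the tracer, not here.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor, concat, conv1d

__all__ = [
    "Module", "Dense", "Conv1d", "ReLU", "Dropout", "Flatten",
    "GlobalAvgPool1d", "MaxPool1d", "BatchNorm1d", "LayerNorm",
    "Sequential", "LSTMLast", "GRU", "TransformerBlock", "softmax",
]


def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int,
           dtype=np.float32) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(dtype),
                  requires_grad=True)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self):
        """All trainable tensors, de-duplicated (shared weights once)."""
        seen, out = set(), []

        def walk(m):
            for p in m._params.values():
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
            for c in m._modules.values():
                walk(c)

        walk(self)
        return out

    def modules(self):
        yield self
        for c in self._modules.values():
            yield from c.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state):
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.w = glorot(rng, (in_dim, out_dim), in_dim, out_dim)
        self.b = Tensor(np.zeros(out_dim, np.float32), requires_grad=True) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = as_tensor(x) @ self.w
        return out + self.b if self.b is not None else out


class Conv1d(Module):
    """Temporal convolution over (N, T, C) inputs.

    padding: 'valid', 'same' (centred, output length ceil(T/stride)) or
    'causal' (left pad only, for dilated TCN blocks).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, dilation: int = 1,
                 padding: str = "same", bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.dilation = kernel, stride, dilation
        self.padding = padding
        fan_in, fan_out = kernel * in_ch, kernel * out_ch
        self.w = glorot(rng, (kernel, in_ch, out_ch), fan_in, fan_out)
        self.b = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) \
            if bias else None

    def _pads(self, t_in: int):
        span = (self.kernel - 1) * self.dilation + 1
        if self.padding == "valid":
            return (0, 0)
        if self.padding == "causal":
            return (span - 1, 0)
        # same: output length ceil(T / stride)
        t_out = -(-t_in // self.stride)
        total = max(0, (t_out - 1) * self.stride + span - t_in)
        return (total // 2, total - total // 2)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        return conv1d(x, self.w, self.b, stride=self.stride,
                      dilation=self.dilation, padding=self._pads(x.shape[1]))


class ReLU(Module):
    def forward(self, x) -> Tensor:
        return as_tensor(x).relu()


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)


class Flatten(Module):
    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        return x.reshape(x.shape[0], -1)


class GlobalAvgPool1d(Module):
    """Mean over the temporal axis of (N, T, C)."""

    def forward(self, x) -> Tensor:
        return as_tensor(x).mean(axis=1)


class MaxPool1d(Module):
    def __init__(self, width: int):
        super().__init__()
        self.width = width

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        n, t, c = x.shape
        t_trim = (t // self.width) * self.width
        return x[:, :t_trim, :].reshape(n, t_trim // self.width,
                                        self.width, c).max(axis=2)


class BatchNorm1d(Module):
    """Per-channel normalization over (N, T, C) or (N, C) batches."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
            # normalize with batch stats, treated as constants (a simplification
            # that keeps the graph light; adequate for the small nets here)
            mean_c, var_c = mu, var
        else:
            mean_c, var_c = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var_c + self.eps)).astype(x.dtype)
        xn = (x - Tensor(mean_c.astype(x.dtype))) * Tensor(inv)
        return xn * self.gamma + self.beta

    def eval_scale_shift(self):
        """Eval-mode affine y = a*x + c, used by the relevance tracer."""
        a = self.gamma.data / np.sqrt(self.running_var + self.eps)
        c = self.beta.data - a * self.running_mean
        return a, c


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps) ** 0.5 * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)


class LSTMLast(Module):
    """Single-layer LSTM returning the last hidden state (N, H)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.in_dim, self.hidden = in_dim, hidden
        self.wx = glorot(rng, (in_dim, 4 * hidden), in_dim, hidden)
        self.wh = glorot(rng, (hidden, 4 * hidden), hidden, hidden)
        self.b = Tensor(np.zeros(4 * hidden, np.float32), requires_grad=True)

    def step(self, x_t: Tensor, h: Tensor, c: Tensor):
        z = x_t @ self.wx + h @ self.wh + self.b
        H = self.hidden
        i = z[:, :H].sigmoid()
        f = z[:, H:2 * H].sigmoid()
        g = z[:, 2 * H:3 * H].tanh()
        o = z[:, 3 * H:].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new, (i, f, g, o)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        n, t, _ = x.shape
        h = Tensor(np.zeros((n, self.hidden), x.data.dtype))
        c = Tensor(np.zeros((n, self.hidden), x.data.dtype))
        for ti in range(t):
            h, c, _ = self.step(x[:, ti, :], h, c)
        return h


class GRU(Module):
    """GRU layer; optionally bidirectional, returning sequences or last state."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 bidirectional: bool = False, return_sequences: bool = True):
        super().__init__()
        self.in_dim, self.hidden = in_dim, hidden
        self.bidirectional = bidirectional
        self.return_sequences = return_sequences
        self.wx = glorot(rng, (in_dim, 3 * hidden), in_dim, hidden)
        self.wh = glorot(rng, (hidden, 3 * hidden), hidden, hidden)
        self.b = Tensor(np.zeros(3 * hidden, np.float32), requires_grad=True)
        if bidirectional:
            self.wx_r = glorot(rng, (in_dim, 3 * hidden), in_dim, hidden)
            self.wh_r = glorot(rng, (hidden, 3 * hidden), hidden, hidden)
            self.b_r = Tensor(np.zeros(3 * hidden, np.float32),
                              requires_grad=True)

    def _run(self, x: Tensor, wx, wh, b, reverse: bool):
        n, t, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((n, H), x.data.dtype))
        outs = []
        order = range(t - 1, -1, -1) if reverse else range(t)
        for ti in order:
            x_t = x[:, ti, :]
            zx = x_t @ wx + b
            zh = h @ wh
            r = (zx[:, :H] + zh[:, :H]).sigmoid()
            u = (zx[:, H:2 * H] + zh[:, H:2 * H]).sigmoid()
            cand = (zx[:, 2 * H:] + r * zh[:, 2 * H:]).tanh()
            h = u * h + (1.0 - u) * cand
            outs.append(h)
        if reverse:
            outs = outs[::-1]
        return outs

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        fwd = self._run(x, self.wx, self.wh, self.b, reverse=False)
        if self.bidirectional:
            bwd = self._run(x, self.wx_r, self.wh_r, self.b_r, reverse=True)
            steps = [concat([f, bk], axis=-1) for f, bk in zip(fwd, bwd)]
        else:
            steps = fwd
        if self.return_sequences:
            stacked = concat([s.reshape(s.shape[0], 1, s.shape[1])
                              for s in steps], axis=1)
            return stacked
        return steps[-1]


class TransformerBlock(Module):
    """Pre-activation encoder block: MHA + FFN with residuals and layer norm."""

    def __init__(self, d_model: int, heads: int, d_ff: int,
                 rng: np.random.Generator, dropout: float = 0.1):
        super().__init__()
        assert d_model % heads == 0
        self.d_model, self.heads = d_model, heads
        self.d_head = d_model // heads
        self.wq = Dense(d_model, d_model, rng)
        self.wk = Dense(d_model, d_model, rng)
        self.wv = Dense(d_model, d_model, rng)
        self.wo = Dense(d_model, d_model, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Dense(d_model, d_ff, rng)
        self.ff2 = Dense(d_ff, d_model, rng)
        self.drop = Dropout(dropout, np.random.default_rng(rng.integers(2**31)))

    def _attention(self, x: Tensor) -> Tensor:
        n, t, _ = x.shape
        h, dh = self.heads, self.d_head

        def split(z):  # (N, T, D) -> (N, h, T, dh)
            return z.reshape(n, t, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        shift = scores - Tensor(scores.data.max(axis=-1, keepdims=True))
        e = shift.exp()
        attn = e / e.sum(axis=-1, keepdims=True)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, self.d_model)
        return self.wo(ctx)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        x = x + self.drop(self._attention(self.ln1(x)))
        x = x + self.drop(self.ff2(self.ff1(self.ln2(x)).relu()))
        return x
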