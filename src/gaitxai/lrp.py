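"""Layer-wise relevance propagation and gradient-family analyzers.

LRP redistributes the (pre-softmax) class-c logit backward through the
network so that, for bias-free linear/convolutional ReLU stacks under the
plain z-rule, relevance is conserved at every layer:

    sum_i R_i = sum_j R_j = sum_k R_k = f_c(x).

Rules implemented: ``z`` (plain), ``epsilon`` (stabilized denominator),
``alpha_beta`` (positive/negative split with alpha - beta = 1), ``flat``
(uniform redistribution over the receptive field) and the composite
``preset_a_flat`` (epsilon on dense layers, alpha1-beta0 on convolutions,
flat on each stream's input layer).

Propagation through a linear layer uses the standard gradient trick: with
s = R / stabilized(z), the input relevance is x * (d<z, s>/dx), which equals
the element-wise redistribution formula but reuses the layer's forward
machinery. Pooling layers propagate proportionally (average) or
winner-takes-all (max) through the same mechanism. Biases keep their share
of relevance (conservation then holds exactly only for bias-free layers).

Traceable families: the multi-stream CNNs, the TCN, plain sequential
CNN/MLP stacks, and the CNN+LSTM (whose recurrent readout uses an additive
cell decomposition: cell-state relevance is split between the forget-path
and the input-path proportionally to their contribution, and the input
path's share is redistributed through the candidate preactivation).
GRU and transformer models are not traced and raise
:class:`UnsupportedArchitectureError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.autograd import Tensor, conv1d
from .nn.modules import (
    BatchNorm1d, Conv1d, Dense, Dropout, Flatten, GlobalAvgPool1d, LSTMLast,
    MaxPool1d, ReLU, Sequential,
)
from .models import CNNLSTM, MultiStreamCNN, NetModel, TCN

__all__ = [
    "RuleConfig", "RelevanceMap", "LayerTrace", "LayerRecord",
    "forward_trace", "lrp_backward", "baseline_analyzer",
    "UnsupportedArchitectureError",
]


class UnsupportedArchitectureError(TypeError):
    pass


@dataclass(frozen=True)
class RuleConfig:
    rule: str = "epsilon"          # epsilon | z | alpha_beta | flat | preset_a_flat
    epsilon: float = 1e-7
    alpha: float = 2.0
    beta: float = 1.0

    def __post_init__(self):
        if self.rule not in ("epsilon", "z", "alpha_beta", "flat",
                             "preset_a_flat"):
            raise ValueError(f"unknown LRP rule '{self.rule}'")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.rule == "alpha_beta":
            if self.alpha < 1:
                raise ValueError("alpha must be >= 1")
            if abs(self.alpha - self.beta - 1.0) > 1e-9:
                raise ValueError("alpha - beta must equal 1")


@dataclass
class RelevanceMap:
    relevance: dict[str, np.ndarray]    # modality -> relevance, input-shaped
    target_class: int
    rule: str
    logit: float                        # f_c(x)

    def total(self) -> float:
        return float(sum(r.sum() for r in self.relevance.values()))

    def single(self) -> np.ndarray:
        """The relevance array of a single-input model."""
        if len(self.relevance) != 1:
            raise ValueError("model has multiple input streams")
        return next(iter(self.relevance.values()))


@dataclass
class LayerRecord:
    layer: object
    x: np.ndarray
    y: np.ndarray


@dataclass
class LayerTrace:
    model: object
    modalities: tuple[str, ...]
    streams: dict[str, list[LayerRecord]]
    head: list[LayerRecord]
    widths: list[int]                   # per-stream embedding widths
    logits: np.ndarray                  # (N, n_classes), softmax removed
    inputs: dict[str, np.ndarray]

    def replay_error(self) -> float:
        """Max |replayed - recorded| over every traced layer output."""
        err = 0.0
        for records in list(self.streams.values()) + [self.head]:
            for rec in records:
                y = rec.layer(Tensor(rec.x)).data
                err = max(err, float(np.abs(y - rec.y).max()))
        return err


def _run_recorded(layers, x: np.ndarray) -> tuple[list[LayerRecord], np.ndarray]:
    records = []
    for layer in layers:
        y = layer(Tensor(np.asarray(x))).data
        records.append(LayerRecord(layer, np.asarray(x), y))
        x = y
    return records, x


def forward_trace(model, inputs) -> LayerTrace:
    """Run ``model`` in eval mode recording every layer's input/output.

    ``inputs``: dict modality -> (N, T, C) array, or a single array for
    single-input models. The softmax is never part of the trace; the head
    ends at the logits.
    """
    if isinstance(model, Sequential):
        x = np.asarray(inputs)
        records, out = _run_recorded(list(model), x)
        return LayerTrace(model, ("input",), {"input": records}, [],
                          [records[-1].y.shape[-1]], out, {"input": x})
    if not isinstance(model, NetModel):
        raise UnsupportedArchitectureError(
            f"cannot trace object of type {type(model).__name__}")
    model.eval()
    inputs = model._coerce(inputs)
    inputs = {m: (v.data if isinstance(v, Tensor) else np.asarray(v))
              for m, v in inputs.items()}

    if isinstance(model, MultiStreamCNN):
        streams, embeds = {}, []
        for m in model.modalities:
            recs, e = _run_recorded(list(model.encoders[m]), inputs[m])
            streams[m] = recs
            embeds.append(e)
        fused = np.concatenate(embeds, axis=-1) if len(embeds) > 1 else embeds[0]
        head, logits = _run_recorded(list(model.head), fused)
        widths = [e.shape[-1] for e in embeds]
        return LayerTrace(model, model.modalities, streams, head, widths,
                          logits, inputs)
    if isinstance(model, TCN):
        m = model.modalities[0]
        x = inputs[m]
        if model.input_stride > 1:
            x = x[:, ::model.input_stride, :]
        recs, h = _run_recorded(list(model.blocks) + [model.pool], x)
        head, logits = _run_recorded(list(model.head), h)
        return LayerTrace(model, (m,), {m: recs}, head, [h.shape[-1]],
                          logits, inputs)
    if isinstance(model, CNNLSTM):
        streams, states = {}, []
        for m in model.modalities:
            recs, seq = _run_recorded(list(model.encoders[m]), inputs[m])
            lstm = model.lstms[m]
            h = lstm(Tensor(seq)).data
            recs.append(LayerRecord(lstm, seq, h))
            streams[m] = recs
            states.append(h)
        fused = np.concatenate(states, axis=-1) if len(states) > 1 else states[0]
        head, logits = _run_recorded(list(model.head), fused)
        widths = [s.shape[-1] for s in states]
        return LayerTrace(model, model.modalities, streams, head, widths,
                          logits, inputs)
    raise UnsupportedArchitectureError(
        f"{type(model).__name__} does not support relevance tracing "
        "(recurrent gates / attention are outside the traced families)")


# --------------------------------------------------------------------- rules

def _stabilize(z: np.ndarray, eps: float) -> np.ndarray:
    sign = np.where(z >= 0, 1.0, -1.0)
    if eps > 0:
        return z + eps * sign
    guard = np.where(np.abs(z) < 1e-12, 1e-12 * sign, 0.0)
    return z + guard


def _vjp(forward, x: np.ndarray, upstream: np.ndarray) -> np.ndarray:
    xt = Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)
    out = forward(xt)
    out.backward(upstream)
    return xt.grad


def _layer_forward(layer, xt: Tensor, w=None, b="keep") -> Tensor:
    """Forward ``layer`` on ``xt`` with optionally substituted parameters."""
    if isinstance(layer, Dense):
        wt = Tensor(layer.w.data if w is None else w)
        out = xt @ wt
        if b == "keep" and layer.b is not None:
            out = out + Tensor(layer.b.data)
        elif isinstance(b, np.ndarray):
            out = out + Tensor(b)
        return out
    if isinstance(layer, Conv1d):
        wt = Tensor(layer.w.data if w is None else w)
        bias = None
        if b == "keep" and layer.b is not None:
            bias = Tensor(layer.b.data)
        elif isinstance(b, np.ndarray):
            bias = Tensor(b)
        return conv1d(xt, wt, bias, stride=layer.stride,
                      dilation=layer.dilation,
                      padding=layer._pads(xt.shape[1]))
    return layer(xt)


def _linear_lrp(layer, x: np.ndarray, R: np.ndarray, rule: str,
                cfg: RuleConfig) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if rule in ("z", "epsilon"):
        eps = 0.0 if rule == "z" else cfg.epsilon
        xt = Tensor(x, requires_grad=True)
        z = _layer_forward(layer, xt)
        s = R / _stabilize(z.data, eps)
        z.backward(s)
        return x * xt.grad
    if rule == "flat":
        ones_x = np.ones_like(x)
        w1 = np.ones_like(layer.w.data)
        xt = Tensor(ones_x, requires_grad=True)
        z = _layer_forward(layer, xt, w=w1, b=None)
        s = R / _stabilize(z.data, 0.0)
        z.backward(s)
        return ones_x * xt.grad
    if rule == "alpha_beta":
        wp = np.maximum(layer.w.data, 0.0)
        wn = np.minimum(layer.w.data, 0.0)
        xp = np.maximum(x, 0.0)
        xn = np.minimum(x, 0.0)
        out = np.zeros_like(x)
        for coef, pairs in ((cfg.alpha, ((xp, wp), (xn, wn))),
                            (-cfg.beta, ((xp, wn), (xn, wp)))):
            if coef == 0.0:
                continue
            tensors = [Tensor(xx, requires_grad=True) for xx, _ in pairs]
            zs = [_layer_forward(layer, t, w=ww, b=None)
                  for t, (_, ww) in zip(tensors, pairs)]
            z_total = zs[0].data + zs[1].data
            s = R / _stabilize(z_total, cfg.epsilon)
            for t, z in zip(tensors, zs):
                z.backward(s)
            out += coef * sum(t.data * t.grad for t in tensors)
        return out
    raise ValueError(rule)


def _pool_lrp(layer, x: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Proportional (average) or winner-takes-all (max) redistribution."""
    x64 = np.asarray(x, dtype=np.float64)
    xt = Tensor(x64, requires_grad=True)
    z = layer(xt)
    s = R / _stabilize(z.data, 0.0)
    z.backward(s)
    return x64 * xt.grad


def _batchnorm_lrp(layer: BatchNorm1d, x: np.ndarray,
                   R: np.ndarray) -> np.ndarray:
    a, _ = layer.eval_scale_shift()
    x64 = np.asarray(x, dtype=np.float64)
    z = x64 * a + (layer.beta.data - a * layer.running_mean)
    s = R / _stabilize(z, 1e-9)
    return x64 * a * s


def _lstm_lrp(layer: LSTMLast, x_seq: np.ndarray, R_h: np.ndarray,
              cfg: RuleConfig) -> np.ndarray:
    """Additive cell decomposition for the last-state LSTM readout."""
    eps = max(cfg.epsilon, 1e-7)
    x64 = np.asarray(x_seq, dtype=np.float64)
    n, t, _ = x64.shape
    H = layer.hidden
    wx, wh, b = (layer.wx.data.astype(np.float64),
                 layer.wh.data.astype(np.float64),
                 layer.b.data.astype(np.float64))
    h = np.zeros((n, H))
    c = np.zeros((n, H))
    cache = []
    for ti in range(t):
        z = x64[:, ti] @ wx + h @ wh + b
        i = 1 / (1 + np.exp(-z[:, :H]))
        f = 1 / (1 + np.exp(-z[:, H:2 * H]))
        g = np.tanh(z[:, 2 * H:3 * H])
        o = 1 / (1 + np.exp(-z[:, 3 * H:]))
        c_new = f * c + i * g
        cache.append((x64[:, ti].copy(), h.copy(), c.copy(), i, f, g, c_new))
        h = o * np.tanh(c_new)
        c = c_new
    R_x = np.zeros_like(x64)
    R_c = R_h.astype(np.float64)      # output gate treated as pass-through
    wx_g = wx[:, 2 * H:3 * H]
    wh_g = wh[:, 2 * H:3 * H]
    for ti in range(t - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, c_new = cache[ti]
        denom = _stabilize(c_new, eps)
        R_from_input = R_c * (i * g) / denom
        R_keep = R_c * (f * c_prev) / denom
        # redistribute the input-path share over the candidate preactivation
        z_g = x_t @ wx_g + h_prev @ wh_g
        s = R_from_input / _stabilize(z_g, eps)
        R_x[:, ti] = x_t * (s @ wx_g.T)
        R_hprev = h_prev * (s @ wh_g.T)
        R_c = R_keep + R_hprev        # fold hidden-path share into the cell
    return R_x


def _rule_for(layer, cfg: RuleConfig, is_first_linear: bool) -> str:
    if cfg.rule != "preset_a_flat":
        return cfg.rule
    if is_first_linear:
        return "flat"
    if isinstance(layer, Conv1d):
        return "alpha_beta_10"
    return "epsilon"


def _propagate_records(records, R: np.ndarray, cfg: RuleConfig,
                       first_linear_flat: bool) -> np.ndarray:
    """Walk a recorded layer list backward, redistributing relevance."""
    linear_ids = [i for i, rec in enumerate(records)
                  if isinstance(rec.layer, (Dense, Conv1d))]
    first_linear = linear_ids[0] if linear_ids else None
    for i in range(len(records) - 1, -1, -1):
        rec = records[i]
        layer = rec.layer
        if isinstance(layer, (ReLU, Dropout)):
            continue
        if isinstance(layer, Flatten):
            R = R.reshape(rec.x.shape)
        elif isinstance(layer, (GlobalAvgPool1d, MaxPool1d)):
            R = _pool_lrp(layer, rec.x, R)
        elif isinstance(layer, BatchNorm1d):
            R = _batchnorm_lrp(layer, rec.x, R)
        elif isinstance(layer, (Dense, Conv1d)):
            is_first = first_linear_flat and i == first_linear
            rule = _rule_for(layer, cfg, is_first)
            if rule == "alpha_beta_10":
                sub = RuleConfig("alpha_beta", cfg.epsilon, 1.0, 0.0)
                R = _linear_lrp(layer, rec.x, R, "alpha_beta", sub)
            else:
                R = _linear_lrp(layer, rec.x, R, rule, cfg)
        elif isinstance(layer, LSTMLast):
            R = _lstm_lrp(layer, rec.x, R, cfg)
        else:
            raise UnsupportedArchitectureError(
                f"no relevance rule for layer {type(layer).__name__}")
    return R


def lrp_backward(trace: LayerTrace, target_class: int,
                 config: RuleConfig | None = None) -> RelevanceMap:
    """Propagate the class-``target_class`` logit back to the inputs."""
    config = config or RuleConfig()
    logits = trace.logits
    n_out = logits.shape[-1]
    if not 0 <= target_class < n_out:
        raise ValueError(f"class {target_class} outside 0..{n_out - 1}")
    fc = logits[..., target_class]
    if np.allclose(logits, 0.0):
        warnings.warn("dead network (all logits zero); relevance map is zero")
    R = np.zeros_like(logits, dtype=np.float64)
    R[..., target_class] = fc
    R = _propagate_records(trace.head, R, config, first_linear_flat=False)
    if len(trace.widths) > 1:
        pieces = np.split(R, np.cumsum(trace.widths)[:-1], axis=-1)
    else:
        pieces = [R]
    flat_first = config.rule == "preset_a_flat"
    relevance = {}
    for m, piece in zip(trace.modalities, pieces):
        r = _propagate_records(trace.streams[m], piece, config,
                               first_linear_flat=flat_first)
        if isinstance(trace.model, TCN) and trace.model.input_stride > 1:
            full = np.zeros_like(
                np.asarray(trace.inputs[m], dtype=np.float64))
            full[:, ::trace.model.input_stride, :] = r
            r = full
        relevance[m] = r
    if not all(np.isfinite(r).all() for r in relevance.values()):
        raise FloatingPointError("non-finite relevance encountered")
    logit_val = float(fc) if np.ndim(fc) == 0 else float(np.asarray(fc).ravel()[0])
    return RelevanceMap(relevance, target_class, config.rule, logit_val)


# ------------------------------------------------------- gradient baselines

def _grad_records(records, g: np.ndarray, mode: str) -> np.ndarray:
    for i in range(len(records) - 1, -1, -1):
        rec = records[i]
        layer = rec.layer
        if isinstance(layer, Dropout):
            continue
        if isinstance(layer, ReLU):
            if mode == "guided_backprop":
                g = g * (rec.x > 0) * (g > 0)
            elif mode == "deconvnet":
                g = g * (g > 0)
            else:
                g = g * (rec.x > 0)
        elif isinstance(layer, Flatten):
            g = g.reshape(rec.x.shape)
        elif isinstance(layer, LSTMLast):
            g = _vjp(lambda t: layer(t), rec.x, g)
        else:
            g = _vjp(lambda t, ly=layer: _layer_forward(ly, t), rec.x, g)
    return g


def baseline_analyzer(model, inputs, method: str = "gradient",
                      target_class: int | None = None) -> RelevanceMap:
    """Gradient-family reference analyzers.

    ``gradient``: d f_c / dx. ``input``: the input itself (trivial
    reference). ``guided_backprop``: ReLU backward zeroes gradients where
    the forward activation or the gradient is negative. ``deconvnet``:
    zeroes negative gradients regardless of the forward sign.
    """
    if method not in ("gradient", "input", "guided_backprop", "deconvnet"):
        raise ValueError(f"unknown analyzer '{method}'")
    trace = forward_trace(model, inputs)
    logits = trace.logits
    if target_class is None:
        target_class = int(logits.argmax(axis=-1).ravel()[0])
    fc = float(np.asarray(logits[..., target_class]).ravel()[0])
    if method == "input":
        rel = {m: np.asarray(x, dtype=np.float64)
               for m, x in trace.inputs.items()}
        return RelevanceMap(rel, target_class, "input", fc)
    g = np.zeros_like(logits, dtype=np.float64)
    g[..., target_class] = 1.0
    g = _grad_records(trace.head, g, method)
    if len(trace.widths) > 1:
        pieces = np.split(g, np.cumsum(trace.widths)[:-1], axis=-1)
    else:
        pieces = [g]
    relevance = {}
    for m, piece in zip(trace.modalities, pieces):
        gm = _grad_records(trace.streams[m], piece, method)
        if isinstance(trace.model, TCN) and trace.model.input_stride > 1:
            full = np.zeros_like(np.asarray(trace.inputs[m], dtype=np.float64))
            full[:, ::trace.model.input_stride, :] = gm
            gm = full
        relevance[m] = gm
    return RelevanceMap(relevance, target_class, method, fc)
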