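"""Model families for gait-speed classification under one contract.

Deep families (built on :mod:`gaitxai.nn`):

* ``single_cnn`` / ``dual_cnn`` / ``quads_cnn`` — one convolutional encoder
  per modality stream, feature-level fusion by concatenating per-stream
  embeddings, MLP softmax head;
* ``fusion_cnn`` — the four-stream architecture with the embedding
  projection weights *shared* across streams and a deeper fusion MLP;
* ``cnn_lstm`` — per-stream convolutional feature extractors feeding an
  LSTM whose last state is read out into the MLP head;
* ``tcn`` — four dilated-causal blocks with 12/24/48/96 filters, batch norm
  and dropout, dense 100, softmax;
* ``gru`` — three stacked bidirectional GRU layers (128/256/256) with dense
  512/256/128 head;
* ``transformer`` — encoder blocks (multi-head self-attention +
  feed-forward, residual + layer norm), global average pooling, dense head.

Statistical baselines (``lda``, ``qda``, ``svm``) operate on flattened 1-D
vectors of a single modality, via scikit-learn.

Filter counts, kernel sizes and head widths for the CNN families are not
architectural constants of the study design; the defaults here are modest
(documented in the methods note) and everything is overridable through
``ModelSpec.hyper``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.autograd import Tensor, concat

__all__ = [
    "ModelSpec", "build_model", "predict_proba", "fit_baseline",
    "MultiStreamCNN", "CNNLSTM", "TCN", "GRUNet", "TransformerNet",
    "BaselineClassifier",
]

MODALITY_COUNT = {"single_cnn": 1, "dual_cnn": 2, "quads_cnn": 4,
                  "fusion_cnn": 4}
DEEP_FAMILIES = ("single_cnn", "dual_cnn", "quads_cnn", "fusion_cnn",
                 "cnn_lstm", "tcn", "gru", "transformer")
BASELINE_FAMILIES = ("lda", "qda", "svm")


@dataclass
class ModelSpec:
    family: str
    modalities: tuple[str, ...]
    hyper: dict = field(default_factory=dict)

    def __post_init__(self):
        self.modalities = tuple(self.modalities)
        if self.family not in DEEP_FAMILIES + BASELINE_FAMILIES:
            raise ValueError(f"unknown model family '{self.family}'")
        want = MODALITY_COUNT.get(self.family)
        if want is not None and len(self.modalities) != want:
            raise ValueError(
                f"{self.family} takes exactly {want} modalities, "
                f"got {len(self.modalities)}")
        if self.family in ("tcn", "gru", "transformer") + BASELINE_FAMILIES \
                and len(self.modalities) != 1:
            raise ValueError(f"{self.family} operates on a single modality")


def _conv_encoder(in_ch: int, filters, kernel: int, strides, dropout: float,
                  rng, use_batchnorm: bool = False) -> nn.Sequential:
    layers = []
    prev = in_ch
    for f, s in zip(filters, strides):
        layers.append(nn.Conv1d(prev, f, kernel, rng, stride=s,
                                padding="same"))
        if use_batchnorm:
            layers.append(nn.BatchNorm1d(f))
        layers.append(nn.ReLU())
        if dropout > 0:
            layers.append(nn.Dropout(dropout,
                                     np.random.default_rng(rng.integers(2**31))))
        prev = f
    return nn.Sequential(*layers)


def _stream_strides(temporal: int, n_blocks: int) -> tuple[int, ...]:
    # high-rate streams (EMG / F&M at 1500 Hz) get a stronger first stride
    first = 8 if temporal > 2000 else 2
    return (first,) + (2,) * (n_blocks - 1)


class NetModel(nn.Module):
    """Common surface of the deep families."""

    modalities: tuple[str, ...]
    n_classes: int

    def _coerce(self, inputs):
        if isinstance(inputs, np.ndarray) or isinstance(inputs, Tensor):
            if len(self.modalities) != 1:
                raise ValueError("multi-stream model needs a dict of inputs")
            return {self.modalities[0]: inputs}
        missing = [m for m in self.modalities if m not in inputs]
        if missing:
            raise ValueError(f"missing modalities {missing}")
        return inputs

    def predict_proba(self, inputs) -> np.ndarray:
        self.eval()
        logits = self.forward(inputs).data
        return nn.softmax(logits)

    def predict(self, inputs) -> np.ndarray:
        return self.predict_proba(inputs).argmax(axis=1)


class MultiStreamCNN(NetModel):
    def __init__(self, modalities, channels: dict[str, int],
                 temporal: dict[str, int], n_classes: int = 4,
                 filters=(32, 64, 96), kernel: int = 7, dropout: float = 0.3,
                 embed_dim: int = 128, head_hidden: int = 64,
                 share_embedding: bool = False, use_batchnorm: bool = False,
                 strides: dict | None = None, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.modalities = tuple(modalities)
        self.n_classes = n_classes
        self.share_embedding = share_embedding
        self.encoders = {}
        shared_embed = nn.Dense(filters[-1], embed_dim, rng) \
            if share_embedding else None
        for m in self.modalities:
            st = (strides or {}).get(m) or _stream_strides(temporal[m],
                                                           len(filters))
            enc = _conv_encoder(channels[m], filters, kernel, st, dropout,
                                rng, use_batchnorm)
            embed = shared_embed if share_embedding \
                else nn.Dense(filters[-1], embed_dim, rng)
            stream = nn.Sequential(*list(enc), nn.GlobalAvgPool1d(), embed,
                                   nn.ReLU())
            self.encoders[m] = stream
            setattr(self, f"enc_{m}", stream)
        fused = embed_dim * len(self.modalities)
        head_layers = [nn.Dense(fused, head_hidden, rng), nn.ReLU()]
        if share_embedding:   # deeper fusion MLP for the fusion family
            head_layers += [nn.Dense(head_hidden, head_hidden, rng), nn.ReLU()]
        head_layers.append(nn.Dense(head_hidden, n_classes, rng))
        self.head = nn.Sequential(*head_layers)

    def forward(self, inputs) -> Tensor:
        inputs = self._coerce(inputs)
        embeds = [self.encoders[m](inputs[m]) for m in self.modalities]
        fused = embeds[0] if len(embeds) == 1 else concat(embeds, axis=-1)
        return self.head(fused)


class CNNLSTM(NetModel):
    """Conv feature extractor per stream -> LSTM -> MLP softmax head."""

    def __init__(self, modalities, channels, temporal, n_classes: int = 4,
                 filters=(32, 64), kernel: int = 7, dropout: float = 0.3,
                 lstm_hidden: int = 128, head_hidden: int = 64, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.modalities = tuple(modalities)
        self.n_classes = n_classes
        self.encoders = {}
        self.lstms = {}
        for m in self.modalities:
            st = _stream_strides(temporal[m], len(filters))
            # extra stride-4 tail keeps the recurrent unroll short
            enc_layers = list(_conv_encoder(channels[m], filters, kernel, st,
                                            dropout, rng))
            enc_layers.append(nn.MaxPool1d(4))
            enc = nn.Sequential(*enc_layers)
            self.encoders[m] = enc
            setattr(self, f"enc_{m}", enc)
            lstm = nn.LSTMLast(filters[-1], lstm_hidden, rng)
            self.lstms[m] = lstm
            setattr(self, f"lstm_{m}", lstm)
        fused = lstm_hidden * len(self.modalities)
        self.head = nn.Sequential(nn.Dense(fused, head_hidden, rng), nn.ReLU(),
                                  nn.Dense(head_hidden, n_classes, rng))

    def forward(self, inputs) -> Tensor:
        inputs = self._coerce(inputs)
        states = [self.lstms[m](self.encoders[m](inputs[m]))
                  for m in self.modalities]
        fused = states[0] if len(states) == 1 else concat(states, axis=-1)
        return self.head(fused)


class TCN(NetModel):
    """Four dilated-causal blocks (12/24/48/96 filters) + dense 100 head."""

    def __init__(self, modality: str, in_ch: int, n_classes: int = 4,
                 filters=(12, 24, 48, 96), kernel: int = 5,
                 dropout: float = 0.3, dense_units: int = 100,
                 input_stride: int = 1, pool: str = "gap", seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.modalities = (modality,)
        self.n_classes = n_classes
        self.input_stride = input_stride
        layers = []
        prev = in_ch
        for i, f in enumerate(filters):
            layers.append(nn.Conv1d(prev, f, kernel, rng, dilation=2**i,
                                    padding="causal"))
            layers.append(nn.BatchNorm1d(f))
            layers.append(nn.ReLU())
            layers.append(nn.Dropout(dropout,
                                     np.random.default_rng(rng.integers(2**31))))
            prev = f
        self.blocks = nn.Sequential(*layers)
        self.pool = nn.GlobalAvgPool1d() if pool == "gap" else nn.Flatten()
        self.pool_kind = pool
        self.head = nn.Sequential(nn.Dense(filters[-1], dense_units, rng),
                                  nn.ReLU(),
                                  nn.Dropout(dropout, np.random.default_rng(
                                      rng.integers(2**31))),
                                  nn.Dense(dense_units, n_classes, rng))

    def forward(self, inputs) -> Tensor:
        inputs = self._coerce(inputs)
        x = nn.Tensor(np.asarray(inputs[self.modalities[0]])) \
            if not isinstance(inputs[self.modalities[0]], Tensor) \
            else inputs[self.modalities[0]]
        if self.input_stride > 1:
            x = x[:, ::self.input_stride, :]
        return self.head(self.pool(self.blocks(x)))


class GRUNet(NetModel):
    """Stacked bidirectional GRUs (128/256/256) with a 512/256/128 dense head."""

    def __init__(self, modality: str, in_ch: int, n_classes: int = 4,
                 units=(128, 256, 256), dense=(512, 256, 128),
                 dropout: float = 0.3, input_stride: int = 1, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.modalities = (modality,)
        self.n_classes = n_classes
        self.input_stride = input_stride
        self.grus = []
        prev = in_ch
        grus = []
        for i, u in enumerate(units):
            last = i == len(units) - 1
            grus.append(nn.GRU(prev, u, rng, bidirectional=True,
                               return_sequences=not last))
            prev = 2 * u
        self.grus = grus
        head_layers = []
        for d in dense:
            head_layers += [nn.Dense(prev, d, rng), nn.ReLU(),
                            nn.Dropout(dropout, np.random.default_rng(
                                rng.integers(2**31)))]
            prev = d
        head_layers.append(nn.Dense(prev, n_classes, rng))
        self.head = nn.Sequential(*head_layers)

    def forward(self, inputs) -> Tensor:
        inputs = self._coerce(inputs)
        x = inputs[self.modalities[0]]
        x = x if isinstance(x, Tensor) else nn.Tensor(np.asarray(x))
        if self.input_stride > 1:
            x = x[:, ::self.input_stride, :]
        for g in self.grus:
            x = g(x)
        return self.head(x)


class TransformerNet(NetModel):
    """Encoder blocks + global average pooling + dense softmax head."""

    def __init__(self, modality: str, in_ch: int, n_classes: int = 4,
                 d_model: int = 64, heads: int = 4, d_ff: int = 128,
                 n_blocks: int = 2, dropout: float = 0.1,
                 input_stride: int = 1, max_len: int = 16384, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.modalities = (modality,)
        self.n_classes = n_classes
        self.input_stride = input_stride
        self.proj = nn.Dense(in_ch, d_model, rng)
        self.blocks = [nn.TransformerBlock(d_model, heads, d_ff, rng, dropout)
                       for _ in range(n_blocks)]
        self.head = nn.Sequential(nn.Dense(d_model, d_model, rng), nn.ReLU(),
                                  nn.Dropout(dropout, np.random.default_rng(
                                      rng.integers(2**31))),
                                  nn.Dense(d_model, n_classes, rng))
        # sinusoidal positional encoding, computed once
        pos = np.arange(max_len)[:, None]
        i = np.arange(d_model // 2)[None, :]
        ang = pos / (10000.0 ** (2 * i / d_model))
        pe = np.zeros((max_len, d_model), np.float32)
        pe[:, 0::2] = np.sin(ang)
        pe[:, 1::2] = np.cos(ang)
        self.pe = pe

    def forward(self, inputs) -> Tensor:
        inputs = self._coerce(inputs)
        x = inputs[self.modalities[0]]
        x = x if isinstance(x, Tensor) else nn.Tensor(np.asarray(x))
        if self.input_stride > 1:
            x = x[:, ::self.input_stride, :]
        h = self.proj(x) + nn.Tensor(self.pe[: x.shape[1]])
        for b in self.blocks:
            h = b(h)
        pooled = h.mean(axis=1)
        return self.head(pooled)


def build_model(spec: ModelSpec, n_classes: int = 4,
                modality_specs=None, seed: int = 0):
    """Instantiate a deep model from its spec.

    ``modality_specs`` maps modality name -> object with ``temporal`` and
    ``spatial`` attributes (defaults to the full-size registry).
    """
    from .registry import MODALITY_SPECS

    mspecs = modality_specs or MODALITY_SPECS
    channels = {m: mspecs[m].spatial for m in spec.modalities}
    temporal = {m: mspecs[m].temporal for m in spec.modalities}
    h = dict(spec.hyper)
    h.setdefault("seed", seed)
    fam = spec.family
    if fam in ("single_cnn", "dual_cnn", "quads_cnn", "fusion_cnn"):
        h.setdefault("share_embedding", fam == "fusion_cnn")
        return MultiStreamCNN(spec.modalities, channels, temporal,
                              n_classes=n_classes, **h)
    if fam == "cnn_lstm":
        return CNNLSTM(spec.modalities, channels, temporal,
                       n_classes=n_classes, **h)
    if fam == "tcn":
        m = spec.modalities[0]
        return TCN(m, channels[m], n_classes=n_classes, **h)
    if fam == "gru":
        m = spec.modalities[0]
        return GRUNet(m, channels[m], n_classes=n_classes, **h)
    if fam == "transformer":
        m = spec.modalities[0]
        return TransformerNet(m, channels[m], n_classes=n_classes, **h)
    raise ValueError(f"build_model does not handle baseline family '{fam}'; "
                     "use fit_baseline")


def predict_proba(model, inputs) -> np.ndarray:
    """Class probability rows (non-negative, summing to one)."""
    if hasattr(model, "predict_proba") and not isinstance(model, NetModel):
        return model.predict_proba(inputs)
    return model.predict_proba(inputs)


class BaselineClassifier:
    """Flatten-and-fit wrapper around the scikit-learn baselines."""

    def __init__(self, kind: str, estimator):
        self.kind = kind
        self.estimator = estimator

    @staticmethod
    def flatten(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        return x.reshape(x.shape[0], -1) if x.ndim > 2 else x

    def predict(self, x):
        return self.estimator.predict(self.flatten(x))

    def predict_proba(self, x):
        return self.estimator.predict_proba(self.flatten(x))


def fit_baseline(kind: str, x: np.ndarray, y: np.ndarray,
                 seed: int = 0, **kwargs) -> BaselineClassifier:
    """Fit LDA / QDA / SVM on flattened single-modality vectors.

    Raises an actionable error when a discriminant fit hits a singular
    covariance (suggesting the regularization knob to turn).
    """
    from sklearn.discriminant_analysis import (
        LinearDiscriminantAnalysis, QuadraticDiscriminantAnalysis)
    from sklearn.svm import SVC

    if kind not in BASELINE_FAMILIES:
        raise ValueError(f"unknown baseline '{kind}'")
    xf = BaselineClassifier.flatten(x)
    if kind == "lda":
        est = LinearDiscriminantAnalysis(**kwargs)
    elif kind == "qda":
        est = QuadraticDiscriminantAnalysis(**kwargs)
    else:
        kwargs.setdefault("probability", True)
        kwargs.setdefault("random_state", seed)
        est = SVC(**kwargs)
    try:
        est.fit(xf, y)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"{kind} fit failed on a singular covariance ({err}); consider "
            "regularization (lda: shrinkage=..., qda: reg_param=...)"
        ) from err
    return BaselineClassifier(kind, est)
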