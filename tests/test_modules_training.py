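"""Layer modules and the training loop."""

import numpy as np
import pytest

from gaitxai import nn
from gaitxai.nn.training import TrainConfig, fit, evaluate_loss

RNG = np.random.default_rng(1)


def test_dense_shape_and_bias_free_option():
    d = nn.Dense(5, 3, RNG)
    assert d(np.zeros((2, 5))).shape == (2, 3)
    d0 = nn.Dense(5, 3, RNG, bias=False)
    assert d0.b is None


@pytest.mark.parametrize("padding,stride,expect", [
    ("same", 1, 12), ("same", 2, 6), ("causal", 1, 12), ("valid", 1, 8),
])
def test_conv_padding_lengths(padding, stride, expect):
    c = nn.Conv1d(3, 4, 5, RNG, stride=stride, padding=padding)
    assert c(np.zeros((2, 12, 3))).shape == (2, expect, 4)


def test_causal_conv_does_not_peek_ahead():
    c = nn.Conv1d(1, 1, 3, RNG, padding="causal")
    x = np.zeros((1, 10, 1), np.float32)
    base = c(x).data.copy()
    x2 = x.copy()
    x2[0, 7, 0] = 1.0     # future change must not affect outputs before t=7
    out = c(x2).data
    np.testing.assert_allclose(out[0, :7], base[0, :7])
    assert np.abs(out[0, 7:] - base[0, 7:]).max() > 0


def test_dropout_identity_in_eval():
    d = nn.Dropout(0.5, np.random.default_rng(0))
    x = RNG.normal(size=(4, 6)).astype(np.float32)
    d.train()
    assert np.abs(d(x).data - x).max() > 0
    d.eval()
    np.testing.assert_array_equal(d(x).data, x)


def test_batchnorm_train_vs_eval_statistics():
    bn = nn.BatchNorm1d(3)
    x = RNG.normal(2.0, 3.0, size=(8, 10, 3)).astype(np.float32)
    bn.train()
    out = bn(x).data
    assert abs(out.mean()) < 1e-5 and abs(out.std() - 1) < 1e-2
    bn.eval()
    out_eval = bn(x).data
    assert out_eval.shape == x.shape
    a, b = bn.eval_scale_shift()
    assert a.shape == (3,) and b.shape == (3,)


def test_pooling_shapes():
    assert nn.GlobalAvgPool1d()(np.zeros((2, 12, 5))).shape == (2, 5)
    assert nn.MaxPool1d(4)(np.zeros((2, 12, 5))).shape == (2, 3, 5)


def test_recurrent_and_transformer_shapes():
    x = np.zeros((3, 7, 4), np.float32)
    assert nn.LSTMLast(4, 6, RNG)(x).shape == (3, 6)
    assert nn.GRU(4, 6, RNG, bidirectional=True,
                  return_sequences=True)(x).shape == (3, 7, 12)
    assert nn.GRU(4, 6, RNG, bidirectional=True,
                  return_sequences=False)(x).shape == (3, 12)
    blk = nn.TransformerBlock(4, 2, 8, RNG, dropout=0.0)
    assert blk(x).shape == (3, 7, 4)


def test_parameter_registration_dedupes_shared_weights():
    rng = np.random.default_rng(0)
    shared = nn.Dense(4, 4, rng)
    seq = nn.Sequential(shared, nn.ReLU(), shared)
    ids = [id(p) for p in seq.parameters()]
    assert len(ids) == len(set(ids)) == 2   # one weight + one bias


def _toy_problem(n=120, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 10)).astype(np.float32)
    y = (x[:, 0] + 0.5 * x[:, 1] > 0).astype(int)
    return x, y


def test_training_loss_decreases_and_learns():
    x, y = _toy_problem()
    rng = np.random.default_rng(2)
    model = nn.Sequential(nn.Dense(10, 16, rng), nn.ReLU(),
                          nn.Dense(16, 2, rng))
    hist = fit(model, x[:100], y[:100], x[100:], y[100:],
               TrainConfig(max_epochs=150, patience=150, seed=0), n_classes=2)
    assert hist["loss"][-1] < hist["loss"][0]
    _, acc = evaluate_loss(model, x[:100], y[:100], 2)
    assert acc >= 0.9


def test_early_stopping_on_plateau_and_best_restore():
    x, y = _toy_problem()
    rng = np.random.default_rng(2)
    model = nn.Sequential(nn.Dense(10, 4, rng), nn.ReLU(), nn.Dense(4, 2, rng))
    # with an (artificially) huge min_delta only the very first epoch
    # registers as the best, so the loop runs patience more epochs and stops
    cfg = TrainConfig(max_epochs=100, patience=5, min_delta=1e9, seed=0)
    hist = fit(model, x[:100], y[:100], x[100:], y[100:], cfg, n_classes=2)
    assert hist["stopped_epoch"] == cfg.patience + 1
    assert hist["best_epoch"] == 1


def test_max_epochs_cap():
    with pytest.raises(ValueError):
        TrainConfig(max_epochs=1001)


def test_empty_partition_rejected():
    x, y = _toy_problem()
    rng = np.random.default_rng(2)
    model = nn.Sequential(nn.Dense(10, 2, rng))
    with pytest.raises(ValueError):
        fit(model, x[:0], y[:0], x, y, TrainConfig(max_epochs=1), n_classes=2)


def test_state_dict_roundtrip():
    rng = np.random.default_rng(3)
    a = nn.Sequential(nn.Dense(4, 3, rng), nn.ReLU(), nn.Dense(3, 2, rng))
    b = nn.Sequential(nn.Dense(4, 3, np.random.default_rng(9)), nn.ReLU(),
                      nn.Dense(3, 2, np.random.default_rng(10)))
    b.load_state_dict(a.state_dict())
    x = RNG.normal(size=(5, 4)).astype(np.float32)
    np.testing.assert_allclose(a(x).data, b(x).data)
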