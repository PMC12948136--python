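"""Layer-wise relevance propagation: rules, conservation, tracing."""

import numpy as np
import pytest

from gaitxai import nn
from gaitxai.lrp import (RuleConfig, UnsupportedArchitectureError,
                         baseline_analyzer, forward_trace, lrp_backward)
from gaitxai.models import ModelSpec, build_model
from gaitxai.registry import ModalitySpec

RNG = np.random.default_rng(0)

TINY = {
    "markers": ModalitySpec("markers", 100.0, 24, 3, 156),
    "grf": ModalitySpec("grf", 1500.0, 24, 3, 24),
    "emg": ModalitySpec("emg", 1500.0, 48, 1, 8),
    "fm": ModalitySpec("fm", 1500.0, 48, 3, 12),
}
MODS = ("markers", "grf", "emg", "fm")


def bias_free_cnn(seed=0):
    rng = np.random.default_rng(seed)
    return nn.Sequential(
        nn.Conv1d(6, 8, 5, rng, stride=2, padding="same", bias=False),
        nn.ReLU(),
        nn.Conv1d(8, 12, 5, rng, stride=2, padding="same", bias=False),
        nn.ReLU(),
        nn.GlobalAvgPool1d(),
        nn.Dense(12, 16, rng, bias=False), nn.ReLU(),
        nn.Dense(16, 4, rng, bias=False))


def test_rule_config_validation():
    with pytest.raises(ValueError):
        RuleConfig(rule="bogus")
    with pytest.raises(ValueError):
        RuleConfig(rule="epsilon", epsilon=-1.0)
    with pytest.raises(ValueError):
        RuleConfig(rule="alpha_beta", alpha=2.0, beta=0.5)
    with pytest.raises(ValueError):
        RuleConfig(rule="alpha_beta", alpha=0.5, beta=-0.5)


def test_trace_replays_forward_exactly():
    net = bias_free_cnn()
    net.eval()
    x = RNG.normal(size=(2, 20, 6))
    trace = forward_trace(net, x)
    assert trace.replay_error() == 0.0
    np.testing.assert_allclose(trace.logits, net(x).data)


def test_z_rule_conservation_bias_free():
    net = bias_free_cnn()
    net.eval()
    for i in range(10):
        x = np.random.default_rng(i).normal(size=(1, 20, 6))
        trace = forward_trace(net, x)
        c = int(np.abs(trace.logits).argmax())
        rm = lrp_backward(trace, c, RuleConfig(rule="z"))
        fc = float(trace.logits[0, c])
        assert abs(rm.total() - fc) <= 1e-10 * max(abs(fc), 1e-12) + 1e-12


def test_epsilon_close_to_z_for_small_epsilon():
    net = bias_free_cnn()
    net.eval()
    x = RNG.normal(size=(1, 20, 6))
    trace = forward_trace(net, x)
    rz = lrp_backward(trace, 0, RuleConfig(rule="z")).single()
    re = lrp_backward(trace, 0, RuleConfig(rule="epsilon",
                                           epsilon=1e-9)).single()
    np.testing.assert_allclose(re, rz, rtol=1e-4, atol=1e-8)


def test_alpha_beta_hand_example():
    """Single linear layer w = (2, -1), x = (1, 1), R = z = 1:
    alpha2beta1 gives R_in = (2, -1)."""
    rng = np.random.default_rng(0)
    layer = nn.Dense(2, 1, rng, bias=False)
    layer.w.data[:] = np.array([[2.0], [-1.0]], np.float32)
    net = nn.Sequential(layer)
    net.eval()
    trace = forward_trace(net, np.array([[1.0, 1.0]]))
    rm = lrp_backward(trace, 0, RuleConfig(rule="alpha_beta", alpha=2.0,
                                           beta=1.0))
    np.testing.assert_allclose(rm.single(), [[2.0, -1.0]], atol=1e-6)


def test_alpha1_beta0_keeps_only_positive_contributions():
    rng = np.random.default_rng(0)
    layer = nn.Dense(2, 1, rng, bias=False)
    layer.w.data[:] = np.array([[2.0], [-1.0]], np.float32)
    net = nn.Sequential(layer)
    net.eval()
    trace = forward_trace(net, np.array([[1.0, 1.0]]))
    rm = lrp_backward(trace, 0, RuleConfig(rule="alpha_beta", alpha=1.0,
                                           beta=0.0))
    np.testing.assert_allclose(rm.single(), [[1.0, 0.0]], atol=1e-6)


def test_flat_rule_uniform_over_receptive_field():
    rng = np.random.default_rng(0)
    layer = nn.Dense(4, 1, rng, bias=False)
    net = nn.Sequential(layer)
    net.eval()
    x = RNG.normal(size=(1, 4))
    trace = forward_trace(net, x)
    rm = lrp_backward(trace, 0, RuleConfig(rule="flat"))
    r = rm.single()[0]
    np.testing.assert_allclose(r, np.full(4, r[0]))
    assert rm.total() == pytest.approx(float(trace.logits[0, 0]), rel=1e-6)


def test_relevance_finite_and_input_shaped_multistream():
    hyper = {"filters": (4, 8), "embed_dim": 8, "head_hidden": 8,
             "dropout": 0.0}
    model = build_model(ModelSpec("quads_cnn", MODS, hyper),
                        modality_specs=TINY, seed=0)
    xs = {m: RNG.normal(size=(1, TINY[m].temporal,
                              TINY[m].spatial)).astype(np.float32)
          for m in MODS}
    trace = forward_trace(model, xs)
    for rule in ("z", "epsilon", "alpha_beta", "preset_a_flat"):
        rm = lrp_backward(trace, 1, RuleConfig(rule=rule))
        assert set(rm.relevance) == set(MODS)
        for m in MODS:
            assert rm.relevance[m].shape == xs[m].shape
            assert np.isfinite(rm.relevance[m]).all()


def test_softmax_never_in_trace():
    """The traced head ends at the logits, not at probabilities."""
    net = bias_free_cnn()
    net.eval()
    x = RNG.normal(size=(1, 20, 6))
    trace = forward_trace(net, x)
    assert not np.allclose(trace.logits.sum(), 1.0)
    assert (trace.logits < 0).any() or (trace.logits > 1).any()


def test_target_class_validation():
    net = bias_free_cnn()
    net.eval()
    trace = forward_trace(net, RNG.normal(size=(1, 20, 6)))
    with pytest.raises(ValueError):
        lrp_backward(trace, 7)


def test_tcn_traceable_lstm_traceable_gru_transformer_not():
    x = RNG.normal(size=(1, TINY["markers"].temporal,
                         156)).astype(np.float32)
    tcn = build_model(ModelSpec("tcn", ("markers",),
                                {"filters": (4, 4, 4, 4),
                                 "dense_units": 8}),
                      modality_specs=TINY)
    tcn.eval()
    trace = forward_trace(tcn, x)
    rm = lrp_backward(trace, 0, RuleConfig(rule="epsilon"))
    assert rm.relevance["markers"].shape == x.shape

    lstm = build_model(ModelSpec("cnn_lstm", MODS,
                                 {"filters": (4, 8), "lstm_hidden": 8,
                                  "head_hidden": 8, "dropout": 0.0}),
                       modality_specs=TINY)
    xs = {m: RNG.normal(size=(1, TINY[m].temporal,
                              TINY[m].spatial)).astype(np.float32)
          for m in MODS}
    rm = lrp_backward(forward_trace(lstm, xs), 0, RuleConfig(rule="epsilon"))
    assert rm.relevance["markers"].shape == xs["markers"].shape

    for family in ("gru", "transformer"):
        hyper = {"units": (4,), "dense": (8,)} if family == "gru" else \
            {"d_model": 8, "heads": 2, "d_ff": 16, "n_blocks": 1}
        model = build_model(ModelSpec(family, ("markers",), hyper),
                            modality_specs=TINY)
        with pytest.raises(UnsupportedArchitectureError):
            forward_trace(model, x)


def test_gradient_analyzer_matches_numeric_gradient():
    net = bias_free_cnn()
    net.eval()
    x = RNG.normal(size=(1, 20, 6))
    rm = baseline_analyzer(net, x, "gradient", target_class=2)
    g = rm.single()
    eps = 1e-5
    for idx in [(0, 3, 1), (0, 10, 4), (0, 19, 0)]:
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        num = (net(xp).data[0, 2] - net(xm).data[0, 2]) / (2 * eps)
        assert g[idx] == pytest.approx(num, rel=1e-3, abs=1e-7)


def test_input_and_guided_analyzers():
    net = bias_free_cnn()
    net.eval()
    x = RNG.normal(size=(1, 20, 6))
    inp = baseline_analyzer(net, x, "input")
    np.testing.assert_allclose(inp.single(), x)
    for method in ("guided_backprop", "deconvnet"):
        rm = baseline_analyzer(net, x, method, target_class=0)
        assert rm.single().shape == x.shape
        assert np.isfinite(rm.single()).all()
    with pytest.raises(ValueError):
        baseline_analyzer(net, x, "nonsense")
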