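"""Model family contracts on miniature inputs."""

import numpy as np
import pytest

from gaitxai.models import (BaselineClassifier, ModelSpec, build_model,
                            fit_baseline)
from gaitxai.registry import ModalitySpec

TINY = {
    "markers": ModalitySpec("markers", 100.0, 24, 3, 156),
    "grf": ModalitySpec("grf", 1500.0, 24, 3, 24),
    "emg": ModalitySpec("emg", 1500.0, 48, 1, 8),
    "fm": ModalitySpec("fm", 1500.0, 48, 3, 12),
}
MODS = ("markers", "grf", "emg", "fm")


def _inputs(n=3):
    rng = np.random.default_rng(0)
    return {m: rng.normal(size=(n, TINY[m].temporal,
                                TINY[m].spatial)).astype(np.float32)
            for m in MODS}


def test_spec_validates_modality_counts():
    with pytest.raises(ValueError):
        ModelSpec("quads_cnn", ("markers",))
    with pytest.raises(ValueError):
        ModelSpec("single_cnn", ("markers", "grf"))
    with pytest.raises(ValueError):
        ModelSpec("tcn", ("markers", "grf"))
    with pytest.raises(ValueError):
        ModelSpec("no_such_family", ("markers",))


@pytest.mark.parametrize("family,mods", [
    ("single_cnn", ("markers",)),
    ("dual_cnn", ("markers", "grf")),
    ("quads_cnn", MODS),
    ("fusion_cnn", MODS),
    ("cnn_lstm", MODS),
    ("tcn", ("markers",)),
    ("gru", ("emg",)),
    ("transformer", ("markers",)),
])
def test_deep_families_emit_probability_rows(family, mods):
    hyper = {}
    if family in ("single_cnn", "dual_cnn", "quads_cnn", "fusion_cnn"):
        hyper = {"filters": (4, 8), "embed_dim": 8, "head_hidden": 8}
    elif family == "cnn_lstm":
        hyper = {"filters": (4, 8), "lstm_hidden": 8, "head_hidden": 8}
    elif family == "tcn":
        hyper = {"filters": (4, 4, 4, 4), "dense_units": 8}
    elif family == "gru":
        hyper = {"units": (4, 4), "dense": (8,)}
    elif family == "transformer":
        hyper = {"d_model": 8, "heads": 2, "d_ff": 16, "n_blocks": 1}
    spec = ModelSpec(family, mods, hyper)
    model = build_model(spec, modality_specs=TINY, seed=0)
    xs = _inputs()
    inputs = xs if len(mods) > 1 else xs[mods[0]]
    proba = model.predict_proba(inputs)
    assert proba.shape == (3, 4)
    assert (proba >= 0).all()
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, rtol=1e-5)


def test_head_has_four_outputs_by_default():
    spec = ModelSpec("single_cnn", ("markers",),
                     {"filters": (4,), "embed_dim": 8, "head_hidden": 8})
    model = build_model(spec, modality_specs=TINY)
    assert model.n_classes == 4


def test_multistream_requires_all_modalities():
    spec = ModelSpec("dual_cnn", ("markers", "grf"),
                     {"filters": (4,), "embed_dim": 8, "head_hidden": 8})
    model = build_model(spec, modality_specs=TINY)
    with pytest.raises(ValueError, match="missing"):
        model.predict_proba({"markers": _inputs()["markers"]})
    with pytest.raises(ValueError, match="dict"):
        model.predict_proba(_inputs()["markers"])


def test_fusion_shares_embedding_weights_quads_does_not():
    hyper = {"filters": (4,), "embed_dim": 8, "head_hidden": 8}
    fusion = build_model(ModelSpec("fusion_cnn", MODS, dict(hyper)),
                         modality_specs=TINY)
    quads = build_model(ModelSpec("quads_cnn", MODS, dict(hyper)),
                        modality_specs=TINY)

    def embed_weight(model, m):
        return model.encoders[m].layers[-2].w

    f_ids = {id(embed_weight(fusion, m)) for m in MODS}
    q_ids = {id(embed_weight(quads, m)) for m in MODS}
    assert len(f_ids) == 1          # one shared projection
    assert len(q_ids) == 4          # independent projections


def test_deterministic_construction():
    hyper = {"filters": (4,), "embed_dim": 8, "head_hidden": 8}
    a = build_model(ModelSpec("single_cnn", ("markers",), dict(hyper)),
                    modality_specs=TINY, seed=7)
    b = build_model(ModelSpec("single_cnn", ("markers",), dict(hyper)),
                    modality_specs=TINY, seed=7)
    x = _inputs()["markers"]
    np.testing.assert_array_equal(a.predict_proba(x), b.predict_proba(x))


def test_baselines_fit_and_predict():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(80, 6, 2)).astype(np.float32)
    y = (x[:, 0, 0] > 0).astype(int)
    x[:, 1, 0] = y * 2.0            # make it separable
    for kind in ("lda", "svm"):
        clf = fit_baseline(kind, x, y)
        assert isinstance(clf, BaselineClassifier)
        proba = clf.predict_proba(x)
        assert proba.shape == (80, 2)
        assert (clf.predict(x) == y).mean() > 0.9
    with pytest.raises(ValueError):
        fit_baseline("forest", x, y)


def test_qda_singular_covariance_actionable_error():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(8, 50)).astype(np.float32)   # n << p
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    with pytest.raises(ValueError, match="reg_param"):
        fit_baseline("qda", x, y)
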