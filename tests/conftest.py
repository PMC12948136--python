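"""Shared fixtures.

The expensive fixtures (200-trial cohort, cross-validated four-stream CNN)
are session-scoped so the acceptance criteria that need a trained model
share a single training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import gaitxai as gx
from gaitxai.data import standardize
from gaitxai.lrp import RuleConfig, forward_trace, lrp_backward
from gaitxai.models import ModelSpec
from gaitxai.nn.training import TrainConfig
from gaitxai.pipeline import ExperimentConfig, run_experiment
from gaitxai.registry import scaled_modality_specs

MODS = ("markers", "grf", "emg", "fm")
QUADS_HYPER = {"filters": (8, 16, 24), "embed_dim": 32, "head_hidden": 32,
               "dropout": 0.1}


@pytest.fixture(scope="session")
def small_specs():
    """Temporal lengths divided by 10; channel layout untouched."""
    return scaled_modality_specs(10)


@pytest.fixture(scope="session")
def cohort(small_specs):
    """200-trial planted cohort: 10 subjects x 5 trials x 4 classes."""
    trials, manifest = gx.generate_cohort(
        10, 5, seed=11, config=gx.GeneratorConfig(specs=small_specs))
    xs = {m: gx.stack_modality(trials, m) for m in MODS}
    lengths = {m: np.array([t.true_length[m] for t in trials]) for m in MODS}
    y = np.array([t.speed_class for t in trials])
    return {"trials": trials, "manifest": manifest, "xs": xs,
            "lengths": lengths, "y": y}


@pytest.fixture(scope="session")
def cv_quads_lda(cohort, small_specs):
    """10-fold Experiment-1 CV of the four-stream CNN and the LDA baseline."""
    cfg = ExperimentConfig(
        experiment=1, seed=3,
        train=TrainConfig(max_epochs=60, patience=10, seed=3))
    specs = [ModelSpec("quads_cnn", MODS, dict(QUADS_HYPER)),
             ModelSpec("lda", ("markers",))]
    return run_experiment(cohort["trials"], specs, cfg,
                          modality_specs=small_specs, keep_models=True)


@pytest.fixture(scope="session")
def foldwise_relevance(cohort, cv_quads_lda):
    """Each sample explained (marker stream, epsilon rule) by the fold
    model that held it out; returns (maps, y, predictions)."""
    xs, lengths, y = cohort["xs"], cohort["lengths"], cohort["y"]
    n = len(y)
    maps = [None] * n
    pred = np.full(n, -1)
    rc = RuleConfig(rule="epsilon")
    for art in cv_quads_lda["artifacts"]["quads_cnn"]:
        for i in art.indices["test"]:
            xin = {m: standardize(xs[m][i], art.stats[m],
                                  int(lengths[m][i]))[None] for m in MODS}
            trace = forward_trace(art.model, xin)
            pred[i] = int(trace.logits.argmax())
            maps[i] = lrp_backward(trace, int(y[i]), rc) \
                .relevance["markers"][0]
    return maps, y, pred


@pytest.fixture(scope="session")
def fold0_quads(cohort, cv_quads_lda):
    """Fold-0 trained model with the whole cohort standardized by its
    training statistics; returns (model, xstd, y, predictions)."""
    art = cv_quads_lda["artifacts"]["quads_cnn"][0]
    xs, lengths, y = cohort["xs"], cohort["lengths"], cohort["y"]
    xstd = {m: np.stack([standardize(xs[m][i], art.stats[m],
                                     int(lengths[m][i]))
                         for i in range(len(y))]) for m in MODS}
    pred = art.model.predict_proba(xstd).argmax(1)
    return art.model, xstd, y, pred
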