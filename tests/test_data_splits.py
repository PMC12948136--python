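"""Standardization, padding and the three split protocols."""

import numpy as np
import pytest

from gaitxai.data import (ChannelStats, fit_channel_stats,
                          split_samples_kfold, split_subjects_kfold,
                          standardize, zero_pad)

RNG = np.random.default_rng(0)


def test_channel_stats_respect_true_lengths():
    x = np.zeros((10, 2))
    x[:4] = RNG.normal(5.0, 2.0, size=(4, 2))     # frames beyond 4 are pad
    st = fit_channel_stats([x], lengths=[4])
    np.testing.assert_allclose(st.mean, x[:4].mean(axis=0))


def test_standardize_zero_mean_unit_variance():
    x = RNG.normal(3.0, 2.5, size=(500, 4)).astype(np.float32)
    out = standardize(x, x)
    assert np.abs(out.mean(axis=0)).max() < 1e-3
    assert np.abs(out.std(axis=0) - 1).max() < 1e-3


def test_standardize_constant_channel_maps_to_zero():
    x = np.ones((50, 2), np.float32)
    x[:, 1] = RNG.normal(size=50)
    out = standardize(x, x)
    np.testing.assert_array_equal(out[:, 0], 0.0)


def test_standardize_keeps_padding_zero():
    x = RNG.normal(1.0, 1.0, size=(10, 3)).astype(np.float32)
    x[6:] = 0.0
    st = fit_channel_stats([x], lengths=[6])
    out = standardize(x, st, length=6)
    np.testing.assert_array_equal(out[6:], 0.0)
    assert np.abs(out[:6]).max() > 0


def test_standardize_uses_training_stats_not_test():
    train = RNG.normal(0.0, 1.0, size=(100, 2)).astype(np.float32)
    test = RNG.normal(10.0, 1.0, size=(100, 2)).astype(np.float32)
    st = fit_channel_stats([train])
    out = standardize(test, st)
    assert out.mean() > 5          # the shift survives: no test-set leakage


def test_zero_pad():
    x = np.ones((3, 2))
    out = zero_pad(x, 5)
    assert out.shape == (5, 2)
    np.testing.assert_array_equal(out[3:], 0.0)
    assert zero_pad(x, 3) is x
    with pytest.raises(ValueError):
        zero_pad(x, 2)


def test_sample_kfold_partitions_and_stratifies():
    y = np.repeat(np.arange(4), 25)
    plan = split_samples_kfold(y, k=10, seed=0)
    assert len(plan.folds) == 10
    all_test = np.concatenate([f["test"] for f in plan.folds])
    assert sorted(all_test) == list(range(100))     # tests partition samples
    for f in plan.folds:
        tr, va, te = (set(f["train"]), set(f["val"]), set(f["test"]))
        assert not (tr & va or tr & te or va & te)
        assert tr | va | te == set(range(100))
        # stratification: every class appears in every partition
        for part in (f["train"], f["val"], f["test"]):
            assert set(y[part]) == {0, 1, 2, 3}


def test_sample_kfold_seeded_reshuffle():
    y = np.repeat(np.arange(4), 25)
    a = split_samples_kfold(y, k=5, seed=1)
    b = split_samples_kfold(y, k=5, seed=1)
    c = split_samples_kfold(y, k=5, seed=2)
    np.testing.assert_array_equal(a.folds[0]["test"], b.folds[0]["test"])
    assert not np.array_equal(a.folds[0]["test"], c.folds[0]["test"])


def test_sample_kfold_k_exceeding_samples():
    with pytest.raises(ValueError):
        split_samples_kfold(np.array([0, 1]), k=10)


def _subjects(n_subjects, trials_each=4):
    return np.repeat(np.arange(n_subjects), trials_each)


def test_subject_kfold_no_subject_straddles_partitions():
    subjects = _subjects(50)
    plan = split_subjects_kfold(subjects, n_test_subjects=5, k=5, seed=0)
    for f in plan.folds:
        parts = {k: {int(s) for s in subjects[f[k]]}
                 for k in ("train", "val", "test")}
        assert not parts["train"] & parts["test"]
        assert not parts["train"] & parts["val"]
        assert not parts["val"] & parts["test"]
        assert len(f["test"]) == 5 * 4


def test_subject_kfold_disjoint_test_sets():
    subjects = _subjects(50)
    plan = split_subjects_kfold(subjects, n_test_subjects=5, k=5, seed=0)
    seen = set()
    for f in plan.folds:
        ts = {int(s) for s in f["test_subjects"]}
        assert not ts & seen
        seen |= ts
    assert len(seen) == 25


def test_subject_kfold_exp3_partitions_all_subjects():
    subjects = _subjects(50)
    plan = split_subjects_kfold(subjects, n_test_subjects=10, k=5, seed=0)
    seen = sorted(int(s) for f in plan.folds for s in f["test_subjects"])
    assert seen == list(range(50))
    assert plan.experiment == 3


def test_subject_kfold_overcommit_raises_unless_overlap():
    subjects = _subjects(10)
    with pytest.raises(ValueError):
        split_subjects_kfold(subjects, n_test_subjects=5, k=5, seed=0)
    plan = split_subjects_kfold(subjects, n_test_subjects=5, k=5, seed=0,
                                allow_overlap=True)
    assert len(plan.folds) == 5


def test_split_plan_json_roundtrip(tmp_path):
    y = np.repeat(np.arange(4), 10)
    plan = split_samples_kfold(y, k=4, seed=0)
    path = tmp_path / "plan.json"
    plan.to_json(path)
    import json
    loaded = json.loads(path.read_text())
    assert loaded["experiment"] == 1 and len(loaded["folds"]) == 4
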