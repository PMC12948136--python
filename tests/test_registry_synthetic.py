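"""Marker registry and synthetic cohort generator."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import cross_val_score

import gaitxai as gx
from gaitxai.registry import (MODALITY_SPECS, MarkerRegistry,
                              scaled_modality_specs)
from gaitxai.synthetic import (GeneratorConfig, _subject_profile,
                               channel_power_features, generate_cohort,
                               generate_trial)

REG = MarkerRegistry()


def test_registry_has_52_markers_156_channels():
    assert len(REG.entries) == 52
    assert REG.n_channels == 156


def test_channel_marker_bijection():
    for ch in range(156):
        m, d = REG.marker_of_channel(ch)
        assert REG.channel_of(m, d) == ch
    # 1-based marker 42 owns zero-based channels 123..125
    assert REG.channels_of_markers([42]) == [123, 124, 125]


def test_registry_bounds():
    with pytest.raises(IndexError):
        REG.channel_of(0, 0)
    with pytest.raises(IndexError):
        REG.channel_of(53, 0)
    with pytest.raises(IndexError):
        REG.marker_of_channel(156)


def test_full_size_modality_shapes():
    assert MODALITY_SPECS["markers"].shape == (585, 156)
    assert MODALITY_SPECS["grf"].shape == (585, 24)
    assert MODALITY_SPECS["emg"].shape == (8985, 8)
    assert MODALITY_SPECS["fm"].shape == (8985, 12)


def test_scaled_specs_keep_channels():
    s = scaled_modality_specs(10)
    assert s["markers"].shape == (58, 156)
    assert s["emg"].shape == (898, 8)
    with pytest.raises(ValueError):
        scaled_modality_specs(0)


def test_cohort_arithmetic_and_balance(cohort):
    trials, y = cohort["trials"], cohort["y"]
    assert len(trials) == 200
    assert len({t.subject_id for t in trials}) == 10
    assert all(int((y == c).sum()) == 50 for c in range(4))


def test_padding_is_exact_zero_beyond_true_length(cohort):
    tr = cohort["trials"][0]
    for m in ("markers", "grf", "emg", "fm"):
        x = tr.modality(m)
        n = tr.true_length[m]
        assert 0 < n <= x.shape[0]
        assert np.all(x[n:] == 0.0)
        assert np.abs(x[:n]).max() > 0


def test_same_seed_bit_identical(small_specs):
    cfg = GeneratorConfig(specs=small_specs)
    a, _ = generate_cohort(2, 1, seed=123, config=cfg)
    b, _ = generate_cohort(2, 1, seed=123, config=cfg)
    for ta, tb in zip(a, b):
        for m in ("markers", "grf", "emg", "fm"):
            np.testing.assert_array_equal(ta.modality(m), tb.modality(m))


def test_different_seed_differs(small_specs):
    cfg = GeneratorConfig(specs=small_specs)
    a, _ = generate_cohort(2, 1, seed=123, config=cfg)
    b, _ = generate_cohort(2, 1, seed=124, config=cfg)
    assert np.abs(a[0].markers - b[0].markers).max() > 0


def test_degenerate_noise_same_speed_identical(small_specs):
    """sigma = 0, multiplier 1: equal speed + subject -> equal tensors."""
    cfg = GeneratorConfig(specs=small_specs, noise_sigma=0.0,
                          planted_multiplier=1.0, length_jitter=0.0)
    prof = _subject_profile(0, np.random.SeedSequence(5))
    t1 = generate_trial(prof, 2, np.random.default_rng(1), cfg, speed=1.0)
    t2 = generate_trial(prof, 2, np.random.default_rng(2), cfg, speed=1.0)
    for m in ("markers", "grf", "fm"):
        np.testing.assert_array_equal(t1.modality(m), t2.modality(m))


def test_speed_outside_class_range_rejected(small_specs):
    cfg = GeneratorConfig(specs=small_specs)
    prof = _subject_profile(0, np.random.SeedSequence(5))
    with pytest.raises(ValueError):
        generate_trial(prof, 0, np.random.default_rng(1), cfg, speed=1.5)
    with pytest.raises(ValueError):
        generate_trial(prof, 9, np.random.default_rng(1), cfg)


def test_cohort_validation_errors(small_specs):
    cfg = GeneratorConfig(specs=small_specs)
    with pytest.raises(ValueError):
        generate_cohort(1, 1, seed=0, config=cfg)
    with pytest.raises(ValueError):
        generate_cohort(2, 0, seed=0, config=cfg)


def test_planted_channel_power_separates_classes(cohort):
    """A linear classifier on planted-channel power reaches >= 90%."""
    trials, y = cohort["trials"], cohort["y"]
    planted = sorted({ch for chans in trials[0].planted_channels.values()
                      for ch in chans})
    feats = channel_power_features(trials)[:, planted]
    acc = cross_val_score(LinearDiscriminantAnalysis(), feats, y,
                          cv=5).mean()
    assert acc >= 0.9


def test_dataset_roundtrip_csv_and_hdf5(tmp_path, small_specs):
    cfg = GeneratorConfig(specs=small_specs)
    trials, manifest = generate_cohort(2, 1, seed=9, config=cfg)
    for fmt in ("csv", "hdf5"):
        out = tmp_path / fmt
        gx.write_dataset(trials, out, manifest, fmt=fmt)
        loaded, man2 = gx.load_dataset(out)
        assert len(loaded) == len(trials)
        for ta, tb in zip(trials, loaded):
            assert ta.speed_class == tb.speed_class
            assert ta.subject_id == tb.subject_id
            assert ta.true_length == tb.true_length
            for m in ("markers", "grf", "emg", "fm"):
                np.testing.assert_array_equal(ta.modality(m), tb.modality(m))


def test_load_rejects_shape_mismatch(tmp_path, small_specs):
    from gaitxai.data import DatasetValidationError

    cfg = GeneratorConfig(specs=small_specs)
    trials, manifest = generate_cohort(2, 1, seed=9, config=cfg)
    out = tmp_path / "bad"
    gx.write_dataset(trials, out, manifest, fmt="csv")
    # truncate one tensor file
    path = out / "trial_0000_grf.csv"
    lines = path.read_text().splitlines()
    path.write_text("\n".join(lines[:10]) + "\n")
    with pytest.raises(DatasetValidationError, match="grf"):
        gx.load_dataset(out)
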