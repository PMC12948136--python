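"""Relevance aggregation: normalization, smoothing, selection, markers."""

import numpy as np
import pytest

from gaitxai.aggregation import (aggregate_class_relevance, build_profile,
                                 marker_scores, planted_recovery,
                                 rescale_unit, smooth, top_k_cells)
from gaitxai.registry import MarkerRegistry

RNG = np.random.default_rng(0)
REG = MarkerRegistry()


def test_impulse_response_single_pass():
    imp = np.zeros(11)
    imp[5] = 1.0
    out = smooth(imp, passes=1)
    np.testing.assert_allclose(out[4:7], [0.25, 0.5, 0.25], atol=1e-15)
    np.testing.assert_allclose(out[:4], 0.0)


def test_triple_pass_interior_center_value():
    """Three passes of (1/4, 1/2, 1/4) give center weight 20/64 = 0.3125."""
    imp = np.zeros(21)
    imp[10] = 1.0
    out = smooth(imp, passes=3)
    assert out[10] == pytest.approx(20 / 64)
    assert out[9] == out[11] == pytest.approx(15 / 64)


def test_smoothing_preserves_mass():
    for shape in [(50,), (40, 7)]:
        x = RNG.normal(size=shape)
        for passes in (1, 3, 10):
            out = smooth(x, passes=passes)
            assert abs(out.sum() - x.sum()) <= 1e-10 * max(1.0,
                                                           abs(x.sum()))


def test_smoothing_2d_smooths_time_only():
    x = np.zeros((9, 3))
    x[4, 1] = 1.0
    out = smooth(x, passes=1)
    assert out[:, 0].sum() == 0.0 and out[:, 2].sum() == 0.0
    np.testing.assert_allclose(out[3:6, 1], [0.25, 0.5, 0.25])


def test_smoothing_edge_cases():
    np.testing.assert_allclose(smooth(np.array([3.0]), passes=5), [3.0])
    with pytest.raises(ValueError):
        smooth(np.zeros(5), passes=-1)


def test_rescale_unit():
    x = np.array([2.0, 4.0, 6.0])
    np.testing.assert_allclose(rescale_unit(x), [0.0, 0.5, 1.0])
    with pytest.warns(UserWarning):
        np.testing.assert_array_equal(rescale_unit(np.full(4, 7.0)),
                                      np.zeros(4))


def test_top_k_deterministic_tie_break():
    x = np.array([[1.0, 1.0], [1.0, 0.5]])
    rows, cols, vals = top_k_cells(x, k=3)
    # all three ones selected in row-major order
    assert list(zip(rows.tolist(), cols.tolist())) == [(0, 0), (0, 1), (1, 0)]
    np.testing.assert_allclose(vals, 1.0)
    with pytest.raises(ValueError):
        top_k_cells(x, k=0)
    with pytest.raises(ValueError):
        top_k_cells(x, k=5)


def test_aggregate_uses_only_correct_samples_of_class():
    maps = np.zeros((4, 3, 2))
    maps[0] += 1.0            # class 0, correct
    maps[1] += 100.0          # class 0, misclassified -> excluded
    maps[2] += 3.0            # class 1 -> excluded
    maps[3] += 2.0            # class 0, correct
    y = np.array([0, 0, 1, 0])
    pred = np.array([0, 1, 1, 0])
    agg = aggregate_class_relevance(maps, y, pred, 0)
    # both contributing maps normalize to all-ones
    np.testing.assert_allclose(agg, 1.0)


def test_aggregate_normalizes_per_map_scale():
    maps = np.stack([np.full((2, 2), 10.0), np.full((2, 2), 0.1)])
    y = pred = np.zeros(2, dtype=int)
    agg = aggregate_class_relevance(maps, y, pred, 0)
    np.testing.assert_allclose(agg, 1.0)   # scale-free average


def test_aggregate_errors():
    maps = np.ones((2, 2, 2))
    with pytest.raises(ValueError):
        aggregate_class_relevance(maps, [0, 0], [1, 1], 0)
    with pytest.raises(ValueError):
        aggregate_class_relevance(maps, [0], [0, 0], 0)


def test_marker_scores_fold_channels():
    scores = np.zeros(156)
    scores[123:126] = [1.0, 2.0, 3.0]     # marker 42's channels
    ms = marker_scores(scores, REG)
    assert ms[42] == pytest.approx(6.0)
    assert ms[1] == 0.0


def test_planted_recovery_boundaries():
    scores = np.zeros(20)
    scores[[3, 4, 5]] = [5.0, 4.0, 3.0]
    assert planted_recovery(scores, [3, 4, 5]) == 1.0
    assert planted_recovery(scores, [10, 11, 12], k=3) == 0.0
    assert planted_recovery(scores, [3, 10], k=2) == 0.5
    with pytest.raises(ValueError):
        planted_recovery(scores, [])


def test_build_profile_end_to_end():
    rng = np.random.default_rng(1)
    maps = rng.normal(size=(6, 30, 10))
    maps[:3, 10:14, 4] += 25.0            # hot region for class 0
    y = np.array([0, 0, 0, 1, 1, 1])
    pred = y.copy()
    prof = build_profile(maps, y, pred, 0, k=50)
    assert prof.profile.shape == (30, 10)
    assert prof.profile.min() >= 0.0 and prof.profile.max() == 1.0
    assert prof.n_samples == 3
    assert len(prof.top_values) == 50
    # the hot channel dominates
    assert prof.channel_scores().argmax() == 4
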