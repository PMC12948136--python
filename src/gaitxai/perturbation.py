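"""MoRF perturbation analysis and the AOPC faithfulness score.

Most-relevant-first (MoRF): the input is partitioned into time x channel
tiles (7 x 7 by default, partial tiles at the edges), tiles are ranked by
the summed relevance inside them (descending, ties broken by row-major
tile index), and the top tiles are destroyed one at a time by replacing
every cell with a uniform random draw from that channel's observed value
range in the sample. After each step the model is re-evaluated.

With f(x^k) the class score after k perturbation steps and L the number of
steps, the area over the perturbation curve is

    AOPC = 1/(L+1) * sum_{k=0..L} ( f(x^0) - f(x^k) ).

A faithful explanation ranks truly important regions first, so its curve
drops faster and its AOPC is larger than that of a random tile order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import TTestResult, paired_t_test

__all__ = [
    "PerturbationOrder", "PerturbationCurve", "tile_slices", "morf_order",
    "random_order", "perturb_tiles", "morf_curve", "modality_predict_fn",
    "compare_analyzers",
]

DEFAULT_TILE = (7, 7)


def tile_slices(shape: tuple[int, int],
                tile_shape: tuple[int, int] = DEFAULT_TILE):
    """Row-major list of (time-slice, channel-slice) tiles covering a map."""
    t, c = shape
    th, cw = tile_shape
    if th <= 0 or cw <= 0:
        raise ValueError("tile dimensions must be positive")
    out = []
    for t0 in range(0, t, th):
        for c0 in range(0, c, cw):
            out.append((slice(t0, min(t0 + th, t)),
                        slice(c0, min(c0 + cw, c))))
    return out


@dataclass
class PerturbationOrder:
    tile_shape: tuple[int, int]
    slices: list                      # tiles in perturbation order
    heats: np.ndarray                 # summed relevance per ordered tile


def morf_order(heatmap: np.ndarray,
               tile_shape: tuple[int, int] = DEFAULT_TILE) -> PerturbationOrder:
    """Tiles sorted by descending summed heat; ties keep row-major order."""
    h = np.asarray(heatmap, dtype=np.float64)
    if h.ndim != 2:
        raise ValueError("heatmap must be 2-D (time x channels)")
    tiles = tile_slices(h.shape, tile_shape)
    heats = np.array([h[ts, cs].sum() for ts, cs in tiles])
    order = np.lexsort((np.arange(len(tiles)), -heats))
    return PerturbationOrder(tile_shape,
                             [tiles[i] for i in order], heats[order])


def random_order(shape: tuple[int, int], rng: np.random.Generator,
                 tile_shape: tuple[int, int] = DEFAULT_TILE) -> PerturbationOrder:
    """Uniformly shuffled tile order (the faithfulness control)."""
    tiles = tile_slices(shape, tile_shape)
    perm = rng.permutation(len(tiles))
    return PerturbationOrder(tile_shape, [tiles[i] for i in perm],
                             np.zeros(len(tiles)))


def perturb_tiles(x: np.ndarray, slices, rng: np.random.Generator,
                  low: np.ndarray, high: np.ndarray) -> np.ndarray:
    """Replace the given tiles with uniform noise from per-channel ranges."""
    out = np.array(x, dtype=np.float64, copy=True)
    for ts, cs in slices:
        block_shape = out[ts, cs].shape
        out[ts, cs] = rng.uniform(low[cs], high[cs], size=block_shape)
    return out


@dataclass
class PerturbationCurve:
    scores: np.ndarray                # f(x^0) .. f(x^L)
    target_class: int

    @property
    def n_steps(self) -> int:
        return len(self.scores) - 1

    @property
    def aopc(self) -> float:
        return float(np.mean(self.scores[0] - self.scores))


def modality_predict_fn(model, inputs: dict, modality: str):
    """Score function over one modality tensor, other streams held fixed.

    Returns ``fn(x_mod) -> (n_classes,) probability vector`` for a single
    (T, C) array.
    """
    fixed = {m: np.asarray(v) for m, v in inputs.items() if m != modality}

    def fn(x_mod: np.ndarray) -> np.ndarray:
        batch = {m: v[None] if v.ndim == 2 else v for m, v in fixed.items()}
        batch[modality] = np.asarray(x_mod, dtype=np.float32)[None]
        return model.predict_proba(batch)[0]

    return fn


def morf_curve(predict_fn, x: np.ndarray, order: PerturbationOrder,
               rng: np.random.Generator, n_steps: int | None = None,
               target_class: int | None = None,
               replace_low: np.ndarray | None = None,
               replace_high: np.ndarray | None = None) -> PerturbationCurve:
    """Evaluate the MoRF curve for one sample.

    Replacement ranges default to the sample's own per-channel min/max.
    ``target_class`` defaults to the class predicted on the unperturbed
    input, so the curve tracks the score the explanation was computed for.
    """
    x = np.asarray(x, dtype=np.float64)
    if n_steps is None:
        n_steps = len(order.slices)
    if not 1 <= n_steps <= len(order.slices):
        raise ValueError(f"n_steps must be in 1..{len(order.slices)}")
    low = x.min(axis=0) if replace_low is None else np.asarray(replace_low)
    high = x.max(axis=0) if replace_high is None else np.asarray(replace_high)
    p0 = np.asarray(predict_fn(x), dtype=np.float64)
    if target_class is None:
        target_class = int(p0.argmax())
    scores = [p0[target_class]]
    current = x
    for k in range(n_steps):
        current = perturb_tiles(current, [order.slices[k]], rng, low, high)
        scores.append(float(np.asarray(
            predict_fn(current))[target_class]))
    return PerturbationCurve(np.asarray(scores), target_class)


def compare_analyzers(curves_a, curves_b) -> tuple[dict, TTestResult]:
    """Paired comparison of per-sample AOPC values from two analyzers."""
    a = np.array([c.aopc for c in curves_a], dtype=float)
    b = np.array([c.aopc for c in curves_b], dtype=float)
    test = paired_t_test(a, b)
    summary = {
        "aopc_a_mean": float(a.mean()), "aopc_b_mean": float(b.mean()),
        "n": int(a.size),
    }
    return summary, test
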