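"""Preprocessing and cross-validation protocols.

Three split protocols are supported, matching the study design:

* Experiment 1 — stratified sample-wise 10-fold cross-validation with
  seeded reshuffling;
* Experiment 2 — subject-wise k-fold (default 5) with 5 held-out test
  subjects per fold;
* Experiment 3 — subject-wise 5-fold with 10 held-out test subjects.

Standardization is per channel to zero mean / unit variance, with statistics
computed on the *training* partition only and over unpadded frames, so the
zero-padding tail neither biases the statistics nor stops being zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .registry import MODALITY_SPECS
from .synthetic import GaitTrial

__all__ = [
    "ChannelStats", "SplitPlan", "fit_channel_stats", "standardize",
    "zero_pad", "split_samples_kfold", "split_subjects_kfold", "load_dataset",
    "stack_modality",
]

_EPS = 1e-8


@dataclass(frozen=True)
class ChannelStats:
    mean: np.ndarray   # (C,)
    std: np.ndarray    # (C,), zero-variance channels flagged by std < eps

    @property
    def scale(self) -> np.ndarray:
        # constant channels map to zero via the epsilon guard
        return np.where(self.std > _EPS, 1.0 / np.maximum(self.std, _EPS), 0.0)


def fit_channel_stats(tensors, lengths=None) -> ChannelStats:
    """Per-channel mean/std over the unpadded frames of one or more tensors.

    ``tensors``: (T, C) array, (N, T, C) array or a sequence of (T, C)
    arrays; ``lengths`` gives each tensor's true (unpadded) frame count.
    """
    if isinstance(tensors, np.ndarray) and tensors.ndim == 2:
        tensors = [tensors]
    rows = []
    for i, x in enumerate(tensors):
        n = x.shape[0] if lengths is None else int(lengths[i])
        rows.append(np.asarray(x[:n], dtype=np.float64))
    if not rows or sum(r.shape[0] for r in rows) == 0:
        raise ValueError("cannot fit statistics on zero frames")
    flat = np.concatenate(rows, axis=0)
    return ChannelStats(mean=flat.mean(axis=0), std=flat.std(axis=0))


def standardize(tensor: np.ndarray, stats_source,
                length: int | None = None) -> np.ndarray:
    """Standardize a (T, C) or (N, T, C) tensor with training-partition stats.

    ``stats_source`` is either a :class:`ChannelStats` (fitted on the
    training partition — the caller's leakage guard) or an array to fit on.
    When ``length`` is given, only rows below it are transformed; padded
    rows stay exactly zero.
    """
    if np.asarray(tensor).shape[-1] == 0 or np.asarray(tensor).size == 0:
        raise ValueError("cannot standardize an empty tensor")
    stats = stats_source if isinstance(stats_source, ChannelStats) \
        else fit_channel_stats(stats_source)
    x = np.asarray(tensor, dtype=np.float32)
    out = (x - stats.mean.astype(np.float32)) * stats.scale.astype(np.float32)
    if length is not None:
        out = out.copy()
        out[..., length:, :] = 0.0
    return out


def zero_pad(tensor: np.ndarray, target_length: int) -> np.ndarray:
    """Append zero rows so the temporal axis reaches ``target_length``."""
    tensor = np.asarray(tensor)
    t = tensor.shape[0]
    if target_length < t:
        raise ValueError(
            f"target length {target_length} shorter than input length {t}")
    if target_length == t:
        return tensor
    pad = np.zeros((target_length - t,) + tensor.shape[1:], tensor.dtype)
    return np.concatenate([tensor, pad], axis=0)


@dataclass
class SplitPlan:
    experiment: int                  # 1, 2 or 3
    unit: str                        # "sample" or "subject"
    seed: int
    folds: list[dict]                # each: train/val/test index arrays
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.folds)

    def to_json(self, path):
        payload = {
            "experiment": self.experiment, "unit": self.unit,
            "seed": self.seed, "meta": self.meta,
            "folds": [{k: np.asarray(v).tolist() for k, v in f.items()}
                      for f in self.folds],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def split_samples_kfold(y: np.ndarray, k: int = 10, seed: int = 0,
                        val_fraction: float = 0.1) -> SplitPlan:
    """Experiment 1: stratified sample-wise k-fold with seeded reshuffling.

    A validation slice (default 10%, stratified) is carved from each fold's
    training portion; one seed fixes the whole plan, fold-wise shuffles are
    derived sub-streams.
    """
    y = np.asarray(y)
    if k > len(y):
        raise ValueError(f"k={k} exceeds number of samples {len(y)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    n_classes = len(np.unique(y))
    for i, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        # the stratified carve-out needs at least one sample per class
        n_val = max(n_classes, int(round(val_fraction * len(train_idx))))
        fold_seed = (seed * 1000 + i) % (2**32)  # sklearn's seed range
        try:
            tr, va = train_test_split(
                train_idx, test_size=n_val, stratify=y[train_idx],
                random_state=fold_seed)
        except ValueError:
            warnings.warn("validation carve-out could not be stratified; "
                          "falling back to a plain shuffle")
            tr, va = train_test_split(train_idx, test_size=n_val,
                                      random_state=fold_seed)
        folds.append({"train": np.sort(tr), "val": np.sort(va),
                      "test": np.sort(test_idx)})
    return SplitPlan(experiment=1, unit="sample", seed=seed, folds=folds,
                     meta={"k": k, "val_fraction": val_fraction})


def split_subjects_kfold(subjects: np.ndarray, n_test_subjects: int,
                         k: int = 5, seed: int = 0,
                         val_fraction: float = 0.1,
                         allow_overlap: bool = False,
                         experiment: int | None = None) -> SplitPlan:
    """Experiments 2 & 3: subject-wise k-fold splitting.

    All trials of a subject stay on one side of every split. By default the
    k test sets use disjoint subjects (requires ``n_test_subjects * k <=
    n_subjects``); ``allow_overlap`` instead redraws test subjects
    independently per fold.
    """
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    rng = np.random.default_rng(seed)
    if not allow_overlap and n_test_subjects * k > len(uniq):
        raise ValueError(
            f"{n_test_subjects} test subjects x {k} folds exceeds "
            f"{len(uniq)} subjects; pass allow_overlap=True to redraw")
    order = rng.permutation(uniq)
    folds = []
    for i in range(k):
        if allow_overlap:
            test_subj = rng.choice(uniq, size=n_test_subjects, replace=False)
        else:
            test_subj = order[i * n_test_subjects:(i + 1) * n_test_subjects]
        rest = np.array([s for s in uniq if s not in set(test_subj.tolist())])
        fold_rng = np.random.default_rng(seed * 1000 + i)
        rest = fold_rng.permutation(rest)
        n_val = max(1, int(round(val_fraction * len(rest))))
        val_subj, train_subj = rest[:n_val], rest[n_val:]
        folds.append({
            "train": np.flatnonzero(np.isin(subjects, train_subj)),
            "val": np.flatnonzero(np.isin(subjects, val_subj)),
            "test": np.flatnonzero(np.isin(subjects, test_subj)),
            "test_subjects": np.sort(test_subj),
        })
    exp = experiment if experiment is not None else (3 if n_test_subjects >= 10 else 2)
    return SplitPlan(experiment=exp, unit="subject", seed=seed, folds=folds,
                     meta={"k": k, "n_test_subjects": n_test_subjects,
                           "val_fraction": val_fraction,
                           "allow_overlap": allow_overlap})


def stack_modality(trials, name: str) -> np.ndarray:
    """Stack one modality across trials into (N, T, C) float32."""
    return np.stack([tr.modality(name) for tr in trials]).astype(np.float32)


class DatasetValidationError(ValueError):
    pass


def load_dataset(directory):
    """Load a cohort written by :func:`gaitxai.synthetic.write_dataset`.

    Validates every tensor against the manifest's modality registry and
    raises :class:`DatasetValidationError` naming the modality and the
    expected/actual shape on mismatch. Returns (trials, manifest).
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    specs = manifest.get("modalities") or {
        name: {"temporal": s.temporal, "spatial": s.spatial}
        for name, s in MODALITY_SPECS.items()
    }
    planted = {int(kk): tuple(vv) for kk, vv in
               manifest.get("planted_channels", {}).items()}

    labels = {}
    with open(directory / "labels.csv") as fh:
        header = fh.readline().strip().split(",")
        for line in fh:
            row = dict(zip(header, line.strip().split(",")))
            labels[int(row["trial_id"])] = row

    fmt = manifest.get("format", "csv")
    h5 = None
    if fmt == "hdf5":
        import h5py

        h5 = h5py.File(directory / "cohort.h5", "r")

    trials = []
    try:
        for rec in manifest["trials"]:
            tid = rec["trial_id"]
            tensors = {}
            for name in ("markers", "grf", "emg", "fm"):
                if fmt == "hdf5":
                    arr = np.asarray(h5[f"trial_{tid:04d}"][name],
                                     dtype=np.float32)
                else:
                    arr = np.loadtxt(directory / f"trial_{tid:04d}_{name}.csv",
                                     delimiter=",", skiprows=1,
                                     dtype=np.float32, ndmin=2)
                expected = (specs[name]["temporal"], specs[name]["spatial"])
                if arr.shape != expected:
                    raise DatasetValidationError(
                        f"trial {tid} modality '{name}': expected shape "
                        f"{expected}, found {arr.shape}")
                tensors[name] = arr
            row = labels[tid]
            trials.append(GaitTrial(
                trial_id=tid, markers=tensors["markers"], grf=tensors["grf"],
                emg=tensors["emg"], fm=tensors["fm"],
                speed_class=int(row["class"]),
                subject_id=int(row["subject_id"]),
                speed=float(row.get("speed", "nan")),
                true_length={k: int(v) for k, v in rec["true_length"].items()},
                planted_channels=planted,
            ))
    finally:
        if h5 is not None:
            h5.close()
    return trials, manifest
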