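"""End-to-end orchestration: splits -> standardize -> train -> evaluate.

The fold loop enforces the leakage rules: channel statistics are fitted on
the training partition only (over unpadded frames) and then applied to the
validation and test partitions; subject-wise experiments never let a
subject's trials straddle a split boundary (that guarantee lives in
:func:`gaitxai.data.split_subjects_kfold`).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import (SplitPlan, fit_channel_stats, split_samples_kfold,
                   split_subjects_kfold, stack_modality, standardize)
from .evaluation import MetricsReport, TTestResult, paired_t_test
from .models import (BASELINE_FAMILIES, ModelSpec, build_model, fit_baseline)
from .nn.training import TrainConfig, fit
from .registry import MODALITY_SPECS

__all__ = [
    "ExperimentConfig", "FoldArtifacts", "make_plan", "prepare_fold",
    "cross_validate", "compare_models", "run_experiment",
]


@dataclass
class ExperimentConfig:
    experiment: int = 1                 # 1: sample-wise, 2/3: subject-wise
    k: int | None = None                # folds (default 10 / 5 / 5)
    n_test_subjects: int | None = None  # default 5 (exp 2) / 10 (exp 3)
    val_fraction: float = 0.1
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if self.experiment not in (1, 2, 3):
            raise ValueError("experiment must be 1, 2 or 3")
        if self.k is None:
            self.k = 10 if self.experiment == 1 else 5
        if self.n_test_subjects is None:
            self.n_test_subjects = {1: 0, 2: 5, 3: 10}[self.experiment]


def make_plan(cfg: ExperimentConfig, y: np.ndarray,
              subjects: np.ndarray | None = None) -> SplitPlan:
    if cfg.experiment == 1:
        return split_samples_kfold(y, k=cfg.k, seed=cfg.seed,
                                   val_fraction=cfg.val_fraction)
    if subjects is None:
        raise ValueError("subject-wise experiments need subject ids")
    return split_subjects_kfold(subjects, cfg.n_test_subjects, k=cfg.k,
                                seed=cfg.seed, val_fraction=cfg.val_fraction,
                                experiment=cfg.experiment)


def prepare_fold(xs: dict[str, np.ndarray], fold: dict,
                 lengths: dict[str, np.ndarray] | None = None):
    """Standardize each modality with training-partition statistics.

    Returns (train, val, test) dicts of float32 tensors plus the fitted
    per-modality statistics.
    """
    parts = {"train": {}, "val": {}, "test": {}}
    stats = {}
    for m, x in xs.items():
        ln = None if lengths is None else lengths[m]
        tr_idx = fold["train"]
        st = fit_channel_stats([x[i] for i in tr_idx],
                               None if ln is None else ln[tr_idx])
        stats[m] = st
        for part in ("train", "val", "test"):
            idx = fold[part]
            out = np.stack([
                standardize(x[i], st,
                            None if ln is None else int(ln[i]))
                for i in idx]).astype(np.float32)
            parts[part][m] = out
    return parts["train"], parts["val"], parts["test"], stats


def _fit_deep(spec: ModelSpec, train, val, y_tr, y_va, cfg: ExperimentConfig,
              n_classes: int, modality_specs, fold_seed: int):
    model = build_model(spec, n_classes=n_classes,
                        modality_specs=modality_specs, seed=fold_seed)
    tc = TrainConfig(**{**cfg.train.__dict__, "seed": fold_seed})
    history = fit(model, train, y_tr, val, y_va, tc, n_classes=n_classes)
    return model, history


@dataclass
class FoldArtifacts:
    fold: int
    model: object
    history: dict | None
    stats: dict
    indices: dict


def cross_validate(xs: dict[str, np.ndarray], y: np.ndarray,
                   spec: ModelSpec, plan: SplitPlan,
                   cfg: ExperimentConfig, n_classes: int = 4,
                   modality_specs=None,
                   lengths: dict[str, np.ndarray] | None = None,
                   keep_models: bool = False):
    """Run one model through every fold of a split plan.

    Returns (MetricsReport, list[FoldArtifacts]); artifacts keep the
    trained model only when ``keep_models`` is set (memory).
    """
    y = np.asarray(y, dtype=int)
    report = MetricsReport(model=spec.family)
    artifacts = []
    mspecs = modality_specs or MODALITY_SPECS
    xs = {m: xs[m] for m in spec.modalities}
    for fi, fold in enumerate(plan.folds):
        t0 = time.time()
        train, val, test, stats = prepare_fold(xs, fold, lengths)
        y_tr, y_va, y_te = (y[fold["train"]], y[fold["val"]],
                            y[fold["test"]])
        fold_seed = (cfg.seed * 10007 + fi * 101) % (2**31)
        if spec.family in BASELINE_FAMILIES:
            m = spec.modalities[0]
            x_fit = np.concatenate([train[m], val[m]])
            y_fit = np.concatenate([y_tr, y_va])
            model = fit_baseline(spec.family, x_fit, y_fit,
                                 seed=fold_seed, **spec.hyper)
            proba = model.predict_proba(test[m])
            history = None
        else:
            model, history = _fit_deep(spec, train, val, y_tr, y_va, cfg,
                                       n_classes, mspecs, fold_seed)
            inputs = test if len(spec.modalities) > 1 \
                else test[spec.modalities[0]]
            proba = model.predict_proba(inputs)
        report.add_fold(y_te, proba, n_classes)
        artifacts.append(FoldArtifacts(
            fold=fi, model=model if keep_models else None, history=history,
            stats=stats, indices=fold))
        report.folds[-1]["wall_seconds"] = time.time() - t0
    return report, artifacts


def compare_models(report_a: MetricsReport, report_b: MetricsReport,
                   key: str = "f1_macro") -> TTestResult:
    """Paired t-test on per-fold metric values of two models."""
    return paired_t_test(report_a.fold_values(key),
                         report_b.fold_values(key))


def run_experiment(trials, specs, cfg: ExperimentConfig,
                   modality_specs=None, n_classes: int = 4,
                   keep_models: bool = False) -> dict:
    """Cross-validate several model specs under one split plan.

    Returns {"plan": SplitPlan, "reports": {name: MetricsReport},
    "artifacts": {name: [FoldArtifacts]}, "comparisons": {(a, b):
    TTestResult}} with all models sharing the identical folds so the
    per-fold scores are genuinely paired.
    """
    y = np.array([t.speed_class for t in trials], dtype=int)
    subjects = np.array([t.subject_id for t in trials])
    plan = make_plan(cfg, y, subjects)
    modalities = sorted({m for s in specs for m in s.modalities})
    xs = {m: stack_modality(trials, m) for m in modalities}
    lengths = {m: np.array([t.true_length[m] for t in trials])
               for m in modalities}
    reports, artifacts = {}, {}
    for spec in specs:
        name = spec.family
        if name in reports:
            name = f"{name}_{len(reports)}"
        rep, art = cross_validate(xs, y, spec, plan, cfg,
                                  n_classes=n_classes,
                                  modality_specs=modality_specs,
                                  lengths=lengths, keep_models=keep_models)
        rep.model = name
        reports[name] = rep
        artifacts[name] = art
    comparisons = {}
    names = list(reports)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                comparisons[(a, b)] = compare_models(reports[a], reports[b])
            except ValueError as err:
                warnings.warn(f"comparison {a} vs {b} skipped: {err}")
    return {"plan": plan, "reports": reports, "artifacts": artifacts,
            "comparisons": comparisons}
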