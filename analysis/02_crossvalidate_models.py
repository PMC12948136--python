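"""Cross-validate model families on a synthetic cohort (Experiments 1-3).

Writes per-fold metrics (CSV), per-model summaries and the pairwise paired
t-tests (JSON) under --out.

Example:
    python analysis/02_crossvalidate_models.py --data runs/cohort \
        --experiment 1 --models quads_cnn lda --epochs 60 --seed 3 \
        --out runs/cv_exp1
"""

from __future__ import annotations

import argparse
import csv
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import (ALL_MODALITIES, add_cohort_args, default_quads_spec,
                    load_or_make_cohort, write_json)

from gaitxai.models import BASELINE_FAMILIES, ModelSpec
from gaitxai.nn.training import TrainConfig
from gaitxai.pipeline import ExperimentConfig, run_experiment

LIGHT_HYPER = {"filters": (8, 16, 24), "embed_dim": 32, "head_hidden": 32,
               "dropout": 0.1}


def make_spec(name: str) -> ModelSpec:
    if name in BASELINE_FAMILIES:
        # flattened high-dimensional inputs need a regularized QDA
        hyper = {"reg_param": 0.5} if name == "qda" else {}
        return ModelSpec(name, ("markers",), hyper)
    if name in ("quads_cnn", "fusion_cnn"):
        return ModelSpec(name, ALL_MODALITIES, dict(LIGHT_HYPER))
    if name == "dual_cnn":
        return ModelSpec(name, ("markers", "grf"), dict(LIGHT_HYPER))
    if name == "single_cnn":
        return ModelSpec(name, ("markers",), dict(LIGHT_HYPER))
    if name == "cnn_lstm":
        return ModelSpec(name, ALL_MODALITIES,
                         {"filters": (8, 16), "lstm_hidden": 32,
                          "head_hidden": 32, "dropout": 0.1})
    if name == "tcn":
        return ModelSpec(name, ("markers",),
                         {"filters": (8, 12, 16, 24), "dense_units": 48})
    if name in ("gru", "transformer"):
        return ModelSpec(name, ("markers",), {"input_stride": 4})
    raise SystemExit(f"unknown model '{name}'")


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    add_cohort_args(ap)
    ap.add_argument("--data", help="dataset directory from 01_simulate_cohort")
    ap.add_argument("--experiment", type=int, default=1, choices=(1, 2, 3))
    ap.add_argument("--folds", type=int, default=None,
                    help="override the protocol's default fold count")
    ap.add_argument("--models", nargs="+", default=["quads_cnn", "lda"])
    ap.add_argument("--epochs", type=int, default=60)
    ap.add_argument("--patience", type=int, default=10)
    ap.add_argument("--out", required=True)
    args = ap.parse_args(argv)

    trials, _, specs = load_or_make_cohort(args)
    cfg = ExperimentConfig(
        experiment=args.experiment, seed=args.seed, k=args.folds,
        train=TrainConfig(max_epochs=args.epochs, patience=args.patience,
                          seed=args.seed))
    model_specs = [make_spec(n) for n in args.models]
    result = run_experiment(trials, model_specs, cfg, modality_specs=specs)

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "fold_metrics.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["model", "fold", "accuracy", "precision_macro",
                    "recall_macro", "f1_macro", "mcc", "n_test"])
        for name, rep in result["reports"].items():
            for i, f in enumerate(rep.folds):
                w.writerow([name, i] + [f[k] for k in (
                    "accuracy", "precision_macro", "recall_macro",
                    "f1_macro", "mcc", "n_test")])
    write_json(out / "summary.json",
               {n: r.summary() for n, r in result["reports"].items()})
    write_json(out / "ttests.json", {
        f"{a}_vs_{b}": {"t": t.t, "p": t.p, "df": t.df,
                        "mean_diff": t.mean_diff}
        for (a, b), t in result["comparisons"].items()})
    result["plan"].to_json(out / "split_plan.json")
    for name, rep in result["reports"].items():
        s = rep.summary()
        print(f"{name:12s} macro-F1 {s['f1_macro_mean']:.4f} "
              f"+/- {s['f1_macro_sd']:.4f}  accuracy {s['accuracy_mean']:.4f}")
    for (a, b), t in result["comparisons"].items():
        print(f"{a} vs {b}: t = {t.t:.3f}, p = {t.p:.2e}")


if __name__ == "__main__":
    main()
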