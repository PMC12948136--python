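"""MoRF perturbation curves and AOPC comparison of analyzers.

Trains one cross-validation fold of the four-stream CNN, explains held-in
samples with LRP and the gradient-family baselines, and compares the AOPC
of each analyzer's tile ordering against a random ordering with a paired
t-test.

Example:
    python analysis/05_perturbation_aopc.py --subjects 10 \
        --trials-per-class 5 --scale 10 --seed 11 --cv-seed 3 \
        --samples 24 --steps 20 --out runs/aopc
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from common import (ALL_MODALITIES, add_cohort_args, default_quads_spec,
                    load_or_make_cohort, write_json)

import gaitxai as gx
from gaitxai.data import standardize
from gaitxai.lrp import RuleConfig, baseline_analyzer, forward_trace, \
    lrp_backward
from gaitxai.nn.training import TrainConfig
from gaitxai.perturbation import (compare_analyzers, modality_predict_fn,
                                  morf_curve, morf_order, random_order)
from gaitxai.pipeline import ExperimentConfig, cross_validate, make_plan


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    add_cohort_args(ap)
    ap.add_argument("--data", help="dataset directory from 01_simulate_cohort")
    ap.add_argument("--cv-seed", type=int, default=3)
    ap.add_argument("--folds", type=int, default=None)
    ap.add_argument("--epochs", type=int, default=60)
    ap.add_argument("--patience", type=int, default=10)
    ap.add_argument("--samples", type=int, default=24)
    ap.add_argument("--steps", type=int, default=20)
    ap.add_argument("--stream", default="markers")
    ap.add_argument("--out", required=True)
    args = ap.parse_args(argv)

    trials, _, specs = load_or_make_cohort(args)
    mods = ALL_MODALITIES
    xs = {m: gx.stack_modality(trials, m) for m in mods}
    lengths = {m: np.array([t.true_length[m] for t in trials]) for m in mods}
    y = np.array([t.speed_class for t in trials])
    cfg = ExperimentConfig(experiment=1, seed=args.cv_seed, k=args.folds,
                           train=TrainConfig(max_epochs=args.epochs,
                                             patience=args.patience,
                                             seed=args.cv_seed))
    plan = make_plan(cfg, y)
    plan.folds = plan.folds[:1]
    report, artifacts = cross_validate(
        xs, y, default_quads_spec(), plan, cfg, modality_specs=specs,
        lengths=lengths, keep_models=True)
    model, stats = artifacts[0].model, artifacts[0].stats
    print(f"fold-0 macro-F1 {report.folds[0]['f1_macro']:.4f}")

    xstd = {m: np.stack([standardize(xs[m][i], stats[m], int(lengths[m][i]))
                         for i in range(len(trials))]) for m in mods}
    pred = model.predict_proba(xstd).argmax(1)
    idx = np.flatnonzero(pred == y)[: args.samples]
    if len(idx) < args.samples:
        print(f"only {len(idx)} correctly classified samples available")

    analyzers = {"lrp_epsilon": None, "gradient": "gradient",
                 "guided_backprop": "guided_backprop"}
    curves = {name: [] for name in analyzers}
    curves["random"] = []
    rng = np.random.default_rng(args.cv_seed + 1)
    for i in idx:
        xin = {m: xstd[m][i:i + 1] for m in mods}
        fn = modality_predict_fn(model, {m: xstd[m][i] for m in mods},
                                 args.stream)
        noise_rng = np.random.default_rng(1000 + int(i))
        for name, method in analyzers.items():
            if method is None:
                tr = forward_trace(model, xin)
                hm = lrp_backward(tr, int(y[i]), RuleConfig(rule="epsilon")) \
                    .relevance[args.stream][0]
            else:
                hm = baseline_analyzer(model, xin, method,
                                       target_class=int(y[i])) \
                    .relevance[args.stream][0]
            order = morf_order(np.abs(hm))
            curves[name].append(morf_curve(
                fn, xstd[args.stream][i], order,
                np.random.default_rng(noise_rng.integers(2**31)),
                n_steps=args.steps, target_class=int(y[i])))
        curves["random"].append(morf_curve(
            fn, xstd[args.stream][i], random_order(
                xstd[args.stream][i].shape, rng),
            np.random.default_rng(noise_rng.integers(2**31)),
            n_steps=args.steps, target_class=int(y[i])))

    results = {}
    for name in analyzers:
        summ, ttest = compare_analyzers(curves[name], curves["random"])
        results[name] = {"aopc": summ["aopc_a_mean"],
                         "aopc_random": summ["aopc_b_mean"],
                         "t": ttest.t, "p": ttest.p, "n": summ["n"]}
        print(f"{name:16s} AOPC {summ['aopc_a_mean']:+.4f} vs random "
              f"{summ['aopc_b_mean']:+.4f}  t = {ttest.t:.3f}  "
              f"p = {ttest.p:.3e}")
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    for name, cs in curves.items():
        np.savetxt(out / f"curves_{name}.csv",
                   np.stack([c.scores for c in cs]), delimiter=",",
                   fmt="%.6g")
    write_json(out / "aopc_summary.json",
               {"stream": args.stream, "steps": args.steps,
                "analyzers": results})


if __name__ == "__main__":
    main()
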