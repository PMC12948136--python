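"""Pairwise paired t-tests across cross-validation runs.

Reads one or more fold_metrics.csv files produced by
02_crossvalidate_models.py and computes the full pairwise paired t-test
matrix on a chosen per-fold metric (models from different runs are paired
by fold index, which is valid when the runs share a split plan seed).

Example:
    python analysis/03_compare_models_ttests.py \
        runs/cv_exp1/fold_metrics.csv --metric f1_macro \
        --out runs/cv_exp1/ttest_matrix.json
"""

from __future__ import annotations

import argparse
import csv
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from common import write_json

from gaitxai.evaluation import paired_t_test


def read_folds(paths, metric):
    series: dict[str, list[tuple[int, float]]] = {}
    for p in paths:
        run = Path(p).parent.name
        with open(p) as fh:
            for row in csv.DictReader(fh):
                key = f"{run}/{row['model']}" if len(paths) > 1 \
                    else row["model"]
                series.setdefault(key, []).append(
                    (int(row["fold"]), float(row[metric])))
    return {k: np.array([v for _, v in sorted(vs)]) for k, vs in
            series.items()}


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("csvs", nargs="+", help="fold_metrics.csv paths")
    ap.add_argument("--metric", default="f1_macro")
    ap.add_argument("--out", required=True)
    args = ap.parse_args(argv)

    series = read_folds(args.csvs, args.metric)
    names = sorted(series)
    matrix = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if len(series[a]) != len(series[b]):
                print(f"skip {a} vs {b}: fold counts differ")
                continue
            t = paired_t_test(series[a], series[b])
            matrix[f"{a}_vs_{b}"] = {
                "t": t.t, "p": t.p, "df": t.df, "mean_diff": t.mean_diff,
                "significant_0.05": bool(t.significant)}
            print(f"{a} vs {b}: mean diff {t.mean_diff:+.4f}  "
                  f"t = {t.t:.3f}  p = {t.p:.3e}")
    write_json(args.out, {"metric": args.metric, "pairs": matrix})


if __name__ == "__main__":
    main()
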