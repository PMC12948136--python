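"""Simulate a synthetic multimodal gait cohort and write it to disk.

Example:
    python analysis/01_simulate_cohort.py --subjects 10 --trials-per-class 5 \
        --scale 10 --seed 11 --out runs/cohort
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import add_cohort_args, make_cohort

import gaitxai as gx


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    add_cohort_args(ap)
    ap.add_argument("--out", required=True, help="output dataset directory")
    ap.add_argument("--format", choices=("csv", "hdf5"), default="hdf5")
    args = ap.parse_args(argv)

    trials, manifest, specs = make_cohort(args)
    path = gx.write_dataset(trials, args.out, manifest, fmt=args.format)
    counts = {}
    for t in trials:
        counts[t.speed_class] = counts.get(t.speed_class, 0) + 1
    print(f"wrote {len(trials)} trials "
          f"({args.subjects} subjects, class counts {counts}) -> {path}")


if __name__ == "__main__":
    main()
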