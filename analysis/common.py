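"""Shared helpers for the numbered analysis scripts."""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

import gaitxai as gx
from gaitxai.registry import MODALITY_SPECS, scaled_modality_specs

ALL_MODALITIES = ("markers", "grf", "emg", "fm")


def add_cohort_args(ap: argparse.ArgumentParser):
    ap.add_argument("--subjects", type=int, default=10,
                    help="number of synthetic subjects")
    ap.add_argument("--trials-per-class", type=int, default=5,
                    help="trials per subject per speed class")
    ap.add_argument("--scale", type=int, default=10,
                    help="temporal downscale divisor (1 = full size)")
    ap.add_argument("--seed", type=int, default=0)


def modality_specs(scale: int):
    return dict(MODALITY_SPECS) if scale == 1 else scaled_modality_specs(scale)


def make_cohort(args):
    specs = modality_specs(args.scale)
    cfg = gx.GeneratorConfig(specs=specs)
    trials, manifest = gx.generate_cohort(
        args.subjects, args.trials_per_class, seed=args.seed, config=cfg)
    return trials, manifest, specs


def load_or_make_cohort(args):
    """Load --data if given, else simulate from the cohort arguments."""
    if getattr(args, "data", None):
        trials, manifest = gx.load_dataset(args.data)
        specs = modality_specs(args.scale)
        return trials, manifest, specs
    return make_cohort(args)


def default_quads_spec():
    from gaitxai.models import ModelSpec

    return ModelSpec("quads_cnn", ALL_MODALITIES,
                     {"filters": (8, 16, 24), "embed_dim": 32,
                      "head_hidden": 32, "dropout": 0.1})


def write_json(path, payload):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def clean(o):
        if isinstance(o, dict):
            return {str(k): clean(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [clean(v) for v in o]
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return o

    with open(path, "w") as fh:
        json.dump(clean(payload), fh, indent=1)
    return path
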