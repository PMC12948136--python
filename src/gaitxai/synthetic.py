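"""Synthetic multimodal gait-trial generator.

Emulates the structure of an instrumented-walkway cohort: per trial a
full-body marker-trajectory tensor (585 x 156 at 100 Hz), a force-plate
tensor (585 x 24), a surface-EMG tensor (8985 x 8 at 1500 Hz) and a
foot-on-plate forces-and-moments tensor (8985 x 12), a speed class in
{0, 1, 2, 3} and a subject identifier.

The generator is built so every downstream stage is testable without the
external recordings:

* walking speed ``v`` is drawn uniformly within the trial's class range and
  drives stride frequency ``f = c0 + c1 v`` (defaults 0.5 + 0.5 v Hz), the
  trial's true (unpadded) length, ground-reaction peak force and EMG burst
  duty cycle;
* subject random effects (stature, amplitude, phase, cadence offset) are
  drawn once per subject, making subject-wise splits meaningful;
* each class has a planted set of anatomically named marker channels whose
  oscillation amplitude is multiplied (default x2) only in trials of that
  class. The groups default to the shoulder/spine markers for the slow
  classes, calcaneus/metatarsal markers for the moderate class and the
  malleolus markers for the fast class, giving explanation-recovery tests a
  known ground truth;
* frames at or beyond the true length are exactly zero (pre-standardization
  zero-padding).

All randomness flows from one cohort seed through ``numpy`` SeedSequence
spawning, so identical (config, seed) pairs produce bit-identical cohorts.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .registry import (
    MODALITY_SPECS, MarkerRegistry, ModalitySpec, SpeedClass,
    default_marker_registry, speed_classes,
)

__all__ = [
    "SubjectProfile", "GaitTrial", "GeneratorConfig",
    "generate_cohort", "generate_trial", "write_dataset",
    "default_planted_markers", "channel_power_features",
]

# Cohort-level "anatomy": per-channel base amplitudes/phases are shared by
# all subjects and drawn from this fixed stream so that cohorts with
# different seeds still describe the same measurement apparatus.
_ANATOMY_SEED = 0x5EED


def default_planted_markers() -> dict[int, tuple[int, ...]]:
    """Class -> 1-based marker indices carrying the class signature.

    Slow classes load on the shoulder girdle and spine root (right side for
    class 0, left for class 1), the moderate class on left calcaneus and
    metatarsal heads, the fast class on both malleoli.
    """
    return {
        0: (42, 43, 44),        # R_SIA, R_SRS, R_SAA
        1: (16, 17, 18),        # L_SIA, L_SRS, L_SAA
        2: (10, 11, 12),        # L_FCC, L_FM1, L_FM2
        3: (8, 9, 34, 35),      # L_FAL, L_TAM, R_FAL, R_TAM
    }


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: int
    height_factor: float      # scales lever arms / offsets
    amplitude_factor: float   # scales oscillation amplitudes
    phase_offset: float       # rad, shifts the gait cycle
    base_cadence: float       # Hz, additive cadence offset
    channel_seed: int         # derives this subject's per-channel offsets


@dataclass
class GaitTrial:
    trial_id: int
    markers: np.ndarray       # (585, 156) float32, mm-scale
    grf: np.ndarray           # (585, 24)
    emg: np.ndarray           # (8985, 8)
    fm: np.ndarray            # (8985, 12)
    speed_class: int
    subject_id: int
    speed: float              # m/s
    true_length: dict[str, int]
    planted_channels: dict[int, tuple[int, ...]]   # class -> marker channels

    def modality(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class GeneratorConfig:
    """Knobs of the synthesis model (see module docstring for semantics)."""

    cadence_intercept: float = 0.5    # c0, Hz
    cadence_slope: float = 0.5        # c1, Hz per (m/s)
    n_cycles: float = 2.0             # gait cycles per trial
    noise_sigma: float = 0.25         # additive Gaussian noise, signal units
    planted_multiplier: float = 2.0   # amplitude gain on planted channels
    length_jitter: float = 0.10       # relative within-class duration jitter
    fast_range: tuple[float, float] = (1.2, 1.8)
    # optional global marker-amplitude trend with speed; the default keeps
    # marker amplitude speed-independent so class identity is carried by the
    # planted channel groups, stride frequency and trial duration
    speed_amplitude_gain: float = 0.0
    planted_markers: dict[int, tuple[int, ...]] = field(
        default_factory=default_planted_markers)
    specs: dict[str, ModalitySpec] = field(
        default_factory=lambda: dict(MODALITY_SPECS))

    def classes(self) -> tuple[SpeedClass, ...]:
        return speed_classes(self.fast_range)


def _planted_channel_map(config: GeneratorConfig,
                         registry: MarkerRegistry) -> dict[int, tuple[int, ...]]:
    return {
        cls: tuple(registry.channels_of_markers(markers))
        for cls, markers in config.planted_markers.items()
    }


def _anatomy(n_channels: int):
    rng = np.random.default_rng(_ANATOMY_SEED)
    amp = rng.uniform(0.5, 1.5, n_channels).astype(np.float32)
    phase = rng.uniform(0, 2 * np.pi, n_channels).astype(np.float32)
    # all channels oscillate at the stride frequency itself, so the
    # frequency cue is spread evenly instead of concentrating in a few
    # high-harmonic channels
    harmonic = np.ones(n_channels, np.float32)
    emg_phase = rng.uniform(0, 1, 8).astype(np.float32)
    return amp, phase, harmonic, emg_phase


def generate_trial(subject: SubjectProfile, speed_class: int,
                   rng: np.random.Generator,
                   config: GeneratorConfig | None = None,
                   registry: MarkerRegistry | None = None,
                   trial_id: int = 0,
                   speed: float | None = None) -> GaitTrial:
    """Synthesize one trial for ``subject`` at the given speed class.

    ``speed`` overrides the uniform class-range draw (used by degenerate-noise
    tests); it must lie inside the class range.
    """
    config = config or GeneratorConfig()
    registry = registry or default_marker_registry()
    classes = config.classes()
    if not 0 <= speed_class < len(classes):
        raise ValueError(f"speed class {speed_class} outside 0..3")
    lo, hi = classes[speed_class].speed_range
    v = float(rng.uniform(lo, hi)) if speed is None else float(speed)
    if not lo <= v <= hi:
        raise ValueError(f"speed {v} outside class range ({lo}, {hi}]")

    specs = config.specs
    f = config.cadence_intercept + config.cadence_slope * v \
        + subject.base_cadence
    duration = config.n_cycles / f
    duration *= 1.0 + config.length_jitter * float(rng.uniform(-1, 1))

    marker_spec, grf_spec = specs["markers"], specs["grf"]
    emg_spec, fm_spec = specs["emg"], specs["fm"]
    n_mark = min(marker_spec.temporal, max(8, round(marker_spec.rate * duration)))
    n_fast = min(emg_spec.temporal, max(8, round(emg_spec.rate * duration)))
    true_length = {"markers": n_mark, "grf": n_mark, "emg": n_fast,
                   "fm": n_fast}

    amp, phase, harmonic, emg_phase = _anatomy(marker_spec.spatial)
    sub_rng = np.random.default_rng(subject.channel_seed)
    offsets = sub_rng.normal(0.0, 0.5, marker_spec.spatial).astype(np.float32)
    sigma = config.noise_sigma
    gain = (1.0 + config.speed_amplitude_gain * v) * subject.amplitude_factor

    # ---- markers ---------------------------------------------------- 100 Hz
    t = np.arange(n_mark, dtype=np.float32) / marker_spec.rate
    theta = 2 * np.pi * f * t + subject.phase_offset
    chan_amp = amp * gain
    planted = _planted_channel_map(config, registry)
    idx = np.asarray(planted[speed_class], dtype=int)
    chan_amp = chan_amp.copy()
    chan_amp[idx] *= config.planted_multiplier
    markers_live = (
        offsets[None, :] * subject.height_factor
        + chan_amp[None, :] * np.sin(harmonic[None, :] * theta[:, None]
                                     + phase[None, :])
    )
    if sigma > 0:
        markers_live = markers_live + rng.normal(
            0, sigma, markers_live.shape).astype(np.float32)
    markers = np.zeros(marker_spec.shape, np.float32)
    markers[:n_mark] = markers_live

    # ---- ground reaction forces (two plates) ------------------------ 100 Hz
    def stance_waveforms(tt, shift):
        """Vertical double-hump plus shear/moment/COP channels for one foot."""
        cycle = (f * tt + subject.phase_offset / (2 * np.pi) + shift) % 1.0
        u = cycle / 0.62                      # stance fraction ~62% of cycle
        in_stance = (u < 1.0).astype(np.float32)
        peak = (1.0 + 0.2 * v) * subject.amplitude_factor
        hump = (np.exp(-((u - 0.28) ** 2) / 0.012)
                + np.exp(-((u - 0.75) ** 2) / 0.012))
        fz = peak * hump * in_stance
        fx = 0.2 * peak * np.sin(2 * np.pi * u) * in_stance
        fy = 0.1 * peak * np.sin(4 * np.pi * u) * in_stance
        lever = 0.3 * subject.height_factor
        cop = np.stack([lever * u * in_stance,
                        0.05 * np.sin(2 * np.pi * u) * in_stance,
                        np.zeros_like(u)], axis=1)
        force = np.stack([fx, fy, fz], axis=1)
        moment = np.stack([cop[:, 1] * fz, -cop[:, 0] * fz,
                           cop[:, 0] * fy - cop[:, 1] * fx], axis=1)
        return force, moment, cop

    fl, ml, cl = stance_waveforms(t, 0.0)
    fr, mr, cr = stance_waveforms(t, 0.5)
    grf_live = np.concatenate(
        [fl, ml, cl, fr, mr, cr, fl + fr, ml + mr], axis=1
    ).astype(np.float32)
    if sigma > 0:
        grf_live = grf_live + rng.normal(
            0, 0.3 * sigma, grf_live.shape).astype(np.float32)
    grf = np.zeros(grf_spec.shape, np.float32)
    grf[:n_mark] = grf_live

    # ---- EMG bursts ------------------------------------------------ 1500 Hz
    tf = np.arange(n_fast, dtype=np.float32) / emg_spec.rate
    cycle_f = (f * tf + subject.phase_offset / (2 * np.pi)) % 1.0
    duty = np.clip(0.55 - 0.15 * v, 0.15, 0.9)   # bursts shorten as v grows
    width = duty / 4.0
    d = np.abs(cycle_f[:, None] - emg_phase[None, :])
    d = np.minimum(d, 1.0 - d)                   # circular phase distance
    env = np.exp(-(d ** 2) / (2 * width ** 2)).astype(np.float32)
    env *= (0.5 + 0.5 * v) * subject.amplitude_factor
    burst_noise = np.abs(rng.normal(0, 1, env.shape)).astype(np.float32)
    emg_live = env * (1.0 + 1.5 * sigma * burst_noise)
    if sigma > 0:
        emg_live = emg_live + rng.normal(
            0, 0.1 * sigma, emg_live.shape).astype(np.float32)
    emg = np.zeros(emg_spec.shape, np.float32)
    emg[:n_fast] = emg_live

    # ---- foot-on-plate forces & moments ---------------------------- 1500 Hz
    flf, mlf, _ = stance_waveforms(tf, 0.0)
    frf, mrf, _ = stance_waveforms(tf, 0.5)
    lever = subject.height_factor
    fm_live = np.concatenate(
        [-flf, lever * mlf, -frf, lever * mrf], axis=1
    ).astype(np.float32)
    if sigma > 0:
        fm_live = fm_live + rng.normal(
            0, 0.3 * sigma, fm_live.shape).astype(np.float32)
    fm = np.zeros(fm_spec.shape, np.float32)
    fm[:n_fast] = fm_live

    return GaitTrial(trial_id=trial_id, markers=markers, grf=grf, emg=emg,
                     fm=fm, speed_class=speed_class,
                     subject_id=subject.subject_id, speed=v,
                     true_length=true_length, planted_channels=planted)


def _subject_profile(subject_id: int, seq: np.random.SeedSequence) -> SubjectProfile:
    rng = np.random.default_rng(seq)
    return SubjectProfile(
        subject_id=subject_id,
        height_factor=float(rng.uniform(0.9, 1.1)),
        amplitude_factor=float(rng.uniform(0.8, 1.2)),
        phase_offset=float(rng.uniform(0, 2 * np.pi)),
        base_cadence=float(rng.uniform(-0.05, 0.05)),
        channel_seed=int(rng.integers(2**31)),
    )


def generate_cohort(n_subjects: int, trials_per_subject_per_class: int,
                    seed: int, config: GeneratorConfig | None = None,
                    registry: MarkerRegistry | None = None):
    """Generate a balanced cohort; returns (trials, manifest).

    Emits ``n_subjects * 4 * trials_per_subject_per_class`` trials; the
    manifest records shapes, rates, seed, config and planted channels.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if trials_per_subject_per_class < 1:
        raise ValueError("trials_per_subject_per_class must be positive")
    config = config or GeneratorConfig()
    registry = registry or default_marker_registry()
    root = np.random.SeedSequence(seed)
    subject_seqs = root.spawn(n_subjects)

    trials: list[GaitTrial] = []
    trial_id = 0
    for sid, sseq in enumerate(subject_seqs):
        profile_seq, trial_root = sseq.spawn(2)
        profile = _subject_profile(sid, profile_seq)
        n_classes = len(config.classes())
        trial_seqs = trial_root.spawn(n_classes * trials_per_subject_per_class)
        k = 0
        for cls in range(n_classes):
            for _ in range(trials_per_subject_per_class):
                rng = np.random.default_rng(trial_seqs[k])
                trials.append(generate_trial(profile, cls, rng, config,
                                             registry, trial_id=trial_id))
                trial_id += 1
                k += 1

    manifest = {
        "seed": seed,
        "n_subjects": n_subjects,
        "trials_per_subject_per_class": trials_per_subject_per_class,
        "n_trials": len(trials),
        "modalities": {
            name: {"rate_hz": s.rate, "temporal": s.temporal, "dim": s.dim,
                   "spatial": s.spatial}
            for name, s in config.specs.items()
        },
        "grf_channel_layout": (
            "plate1 F(xyz), plate1 M(xyz), plate1 COP(xyz), "
            "plate2 F(xyz), plate2 M(xyz), plate2 COP(xyz), "
            "total F(xyz), total M(xyz)"
        ),
        "fm_channel_layout": "plate1 F(xyz), plate1 M(xyz), plate2 F(xyz), plate2 M(xyz)",
        "planted_markers": {str(k): list(vv)
                            for k, vv in config.planted_markers.items()},
        "planted_channels": {str(k): list(vv)
                             for k, vv in
                             _planted_channel_map(config, registry).items()},
        "speed_classes": [
            {"index": c.index, "label": c.label, "range_m_s": list(c.speed_range)}
            for c in config.classes()
        ],
        "generator": {
            "cadence_intercept_hz": config.cadence_intercept,
            "cadence_slope_hz_per_m_s": config.cadence_slope,
            "n_cycles": config.n_cycles,
            "noise_sigma": config.noise_sigma,
            "planted_multiplier": config.planted_multiplier,
            "length_jitter": config.length_jitter,
        },
    }
    return trials, manifest


def channel_power_features(trials, modality: str = "markers") -> np.ndarray:
    """Per-channel mean signal power over unpadded frames, one row per trial."""
    feats = []
    for tr in trials:
        x = tr.modality(modality)[: tr.true_length[modality]]
        feats.append((x.astype(np.float64) ** 2).mean(axis=0))
    return np.asarray(feats)


def _channel_labels(name: str, registry: MarkerRegistry, spec: ModalitySpec):
    if name == "markers":
        return registry.channel_labels()
    if name == "emg":
        return [f"E{i+1}" for i in range(spec.spatial)]
    if name == "grf":
        base = [f"p{p}_{q}{c}" for p in (1, 2) for q in ("F", "M", "COP")
                for c in "xyz"]
        return base + [f"tot_{q}{c}" for q in ("F", "M") for c in "xyz"]
    if name == "fm":
        return [f"p{p}_{q}{c}" for p in (1, 2) for q in ("F", "M")
                for c in "xyz"]
    raise KeyError(name)


def write_dataset(trials, directory, manifest: dict | None = None,
                  fmt: str = "csv",
                  registry: MarkerRegistry | None = None) -> Path:
    """Write a cohort to ``directory``; returns the manifest path.

    ``fmt='csv'`` emits one matrix file per trial per modality with a header
    row of channel labels (values at 9 significant digits, lossless for
    float32); ``fmt='hdf5'`` stores all tensors in one ``cohort.h5``
    container. ``labels.csv`` (trial_id, subject_id, class) and
    ``manifest.json`` are written in both dialects.
    """
    directory = Path(directory)
    if not directory.parent.exists():
        raise FileNotFoundError(f"no such directory: {directory.parent}")
    directory.mkdir(exist_ok=True)
    registry = registry or default_marker_registry()
    if fmt not in ("csv", "hdf5"):
        raise ValueError(f"unknown dataset format: {fmt}")

    modality_names = ("markers", "grf", "emg", "fm")
    if fmt == "hdf5":
        import h5py

        with h5py.File(directory / "cohort.h5", "w") as h5:
            for tr in trials:
                g = h5.create_group(f"trial_{tr.trial_id:04d}")
                for name in modality_names:
                    g.create_dataset(name, data=tr.modality(name))
                g.attrs["subject_id"] = tr.subject_id
                g.attrs["class"] = tr.speed_class
                g.attrs["speed"] = tr.speed
                g.attrs["true_length"] = json.dumps(tr.true_length)
    else:
        for tr in trials:
            for name in modality_names:
                arr = tr.modality(name)
                spec = ModalitySpec(name, 0.0, arr.shape[0], 0, arr.shape[1])
                path = directory / f"trial_{tr.trial_id:04d}_{name}.csv"
                header = ",".join(_channel_labels(name, registry, spec))
                np.savetxt(path, arr, fmt="%.9g", delimiter=",",
                           header=header, comments="")

    with open(directory / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_id", "subject_id", "class", "speed"])
        for tr in trials:
            w.writerow([tr.trial_id, tr.subject_id, tr.speed_class,
                        f"{tr.speed:.6f}"])

    manifest = dict(manifest or {})
    manifest["format"] = fmt
    manifest["trials"] = [
        {"trial_id": tr.trial_id, "subject_id": tr.subject_id,
         "class": tr.speed_class,
         "true_length": tr.true_length,
         "modalities": {m: list(tr.modality(m).shape)
                        for m in modality_names}}
        for tr in trials
    ]
    if "planted_channels" not in manifest and trials:
        manifest["planted_channels"] = {
            str(k): list(v) for k, v in trials[0].planted_channels.items()}
    manifest_path = directory / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path
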