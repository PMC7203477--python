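"""Synthetic multi-subject, multi-class epoched EEG.

Real evoked (ERP) datasets mix a stereotyped class-specific response with
large subject-to-subject variability and heavy trial-to-trial noise, and a
fraction of trials carry essentially no class signal at all (attentional
lapses) while keeping their nominal label.  The generator reproduces that
statistical structure — which is what pair-comparison decoding exploits
and suffers from — without attempting biophysical realism:

* each class signal is a sum of ERP-like components: a fixed unit-norm
  channel topography times a Gaussian temporal bump, with per-class
  amplitudes on the microvolt scale;
* each subject gets a multiplicative gain, a latency shift, and a small
  random rotation of every component topography;
* trial noise is per-channel AR(1) Gaussian (``noise_sd`` is the
  innovation standard deviation, so the stationary noise variance is
  ``noise_sd**2 / (1 - noise_autocorr**2)``);
* with probability ``lapse_prob`` a trial omits the class signal entirely
  but keeps its label.

Defaults emulate the reference acquisition: 37 subjects, 60–70 trials per
class for 3 classes, 31 channels, 370 samples at 250 Hz (which bin down to
37 × 40 ms bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import DEFAULT_LABELS, EpochDataset


@dataclass
class ErpComponent:
    """One evoked component: topography × temporal bump × class amplitude.

    ``latency_bin`` and ``width_bins`` are expressed on the binned time
    axis (40 ms bins by default) for readability; the generator converts
    them to raw samples.  ``topography`` is normalized to unit L2 norm.
    """

    topography: np.ndarray
    latency_bin: int
    width_bins: int
    amplitude_per_class: np.ndarray  # µV, one entry per class

    def __post_init__(self) -> None:
        self.topography = np.asarray(self.topography, dtype=np.float64)
        norm = np.linalg.norm(self.topography)
        if norm == 0:
            raise ValueError("topography must be nonzero")
        self.topography = self.topography / norm
        self.amplitude_per_class = np.asarray(self.amplitude_per_class, dtype=np.float64)
        if self.width_bins < 1:
            raise ValueError("width_bins must be >= 1")


@dataclass
class SubjectEffect:
    """Realized per-subject deviations from the group-level signal."""

    gain: float
    latency_shift_bins: int
    topographies: list[np.ndarray]  # per component, rotated + renormalized

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")


def _default_components(n_channels: int, n_classes: int) -> list[ErpComponent]:
    """Three components loosely patterned on early / category-selective /
    late evoked responses, with smooth fixed topographies.

    Class amplitudes are chosen so that classes differ in a low-dimensional
    but noisy way, landing single-trial pair discrimination in an
    informative-but-imperfect regime after preprocessing.
    """
    ch = np.arange(n_channels)

    def bump_topo(center: float, spread: float) -> np.ndarray:
        return np.exp(-0.5 * ((ch - center) / spread) ** 2)

    def amps(base: list[float]) -> np.ndarray:
        a = np.asarray(base, dtype=np.float64)
        if n_classes <= len(a):
            return a[:n_classes]
        reps = int(np.ceil(n_classes / len(a)))
        return np.tile(a, reps)[:n_classes]

    return [
        # early sensory response, similar for all classes
        ErpComponent(bump_topo(n_channels * 0.5, n_channels / 6), 4, 2, amps([30.0, 28.0, 26.0])),
        # category-selective component (e.g. face-selective N170-like)
        ErpComponent(bump_topo(n_channels * 0.75, n_channels / 8), 7, 2, amps([36.0, 14.0, 6.0])),
        # late sustained component with a different class ordering
        ErpComponent(bump_topo(n_channels * 0.3, n_channels / 5), 16, 5, amps([8.0, 26.0, 38.0])),
    ]


@dataclass
class SyntheticConfig:
    """Study-scale defaults: 37 subjects, ~60–70 trials/class, 31 ch, 250 Hz."""

    n_subjects: int = 37
    trials_per_class_range: tuple[int, int] = (60, 70)
    n_channels: int = 31
    n_raw_timepoints: int = 370
    sampling_rate: float = 250.0
    n_classes: int = 3
    bin_factor: int = 10  # converts component bin timing to raw samples
    components: list[ErpComponent] | None = None
    noise_sd: float = 9.0  # µV, AR(1) innovation sd
    noise_autocorr: float = 0.7
    lapse_prob: float = 0.1
    gain_log_sd: float = 0.25  # subject gain ~ lognormal(0, gain_log_sd)
    latency_jitter_max_bins: int = 1  # subject latency shift ~ U{-max..max}
    topography_rotation_sd: float = 0.15  # subject topography perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_channels < 1:
            raise ValueError("n_classes and n_channels must be positive")
        if self.n_subjects < 1 or self.n_raw_timepoints < 1:
            raise ValueError("n_subjects and n_raw_timepoints must be positive")
        if not (0 <= self.noise_autocorr < 1):
            raise ValueError("noise_autocorr must be in [0, 1)")
        if not (0 <= self.lapse_prob <= 1):
            raise ValueError("lapse_prob must be in [0, 1]")
        lo, hi = self.trials_per_class_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid trials_per_class_range")
        if self.components is None:
            self.components = _default_components(self.n_channels, self.n_classes)

    @property
    def labels(self) -> tuple[str, ...]:
        if self.n_classes == len(DEFAULT_LABELS):
            return DEFAULT_LABELS
        return tuple(f"class{k}" for k in range(self.n_classes))

    @property
    def n_bins(self) -> int:
        return self.n_raw_timepoints // self.bin_factor


def subject_effects(cfg: SyntheticConfig) -> list[SubjectEffect]:
    """Per-subject gains, latency shifts and topography rotations.

    Drawn from a dedicated RNG stream keyed on ``cfg.seed`` only, so that
    :func:`generate_dataset` and :func:`class_template` agree on them.
    """
    rng = np.random.default_rng([cfg.seed, 7919])
    effects = []
    for _ in range(cfg.n_subjects):
        gain = float(np.exp(rng.normal(0.0, cfg.gain_log_sd)))
        shift = int(rng.integers(-cfg.latency_jitter_max_bins, cfg.latency_jitter_max_bins + 1))
        topos = []
        for comp in cfg.components:
            t = comp.topography + rng.normal(0.0, cfg.topography_rotation_sd, comp.topography.shape)
            topos.append(t / np.linalg.norm(t))
        effects.append(SubjectEffect(gain, shift, topos))
    return effects


def _raw_template(cfg: SyntheticConfig, class_k: int, eff: SubjectEffect) -> np.ndarray:
    """Noiseless class signal for one subject, channels × raw timepoints, µV."""
    t = np.arange(cfg.n_raw_timepoints, dtype=np.float64)
    out = np.zeros((cfg.n_channels, cfg.n_raw_timepoints))
    for comp, topo in zip(cfg.components, eff.topographies):
        mu = (comp.latency_bin + eff.latency_shift_bins + 0.5) * cfg.bin_factor
        sd = comp.width_bins * cfg.bin_factor / 2.0
        kernel = np.exp(-0.5 * ((t - mu) / sd) ** 2)
        out += comp.amplitude_per_class[class_k] * eff.gain * np.outer(topo, kernel)
    return out


def class_template(cfg: SyntheticConfig, class_k: int, subject: int) -> np.ndarray:
    """Deterministic (noiseless) signal for a class/subject, channels × bins.

    Exposes the ground truth that generated trials fluctuate around, for
    tests and signal-to-noise diagnostics.  Values are in µV on the binned
    time axis.
    """
    if not (0 <= class_k < cfg.n_classes):
        raise ValueError(f"class index {class_k} out of range [0, {cfg.n_classes})")
    if not (0 <= subject < cfg.n_subjects):
        raise ValueError(f"subject index {subject} out of range [0, {cfg.n_subjects})")
    eff = subject_effects(cfg)[subject]
    raw = _raw_template(cfg, class_k, eff)
    n_bins = cfg.n_bins
    trimmed = raw[:, : n_bins * cfg.bin_factor]
    return trimmed.reshape(cfg.n_channels, n_bins, cfg.bin_factor).mean(axis=2)


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float, a: float) -> np.ndarray:
    """Stationary AR(1) noise along the last axis; ``sd`` is innovation sd."""
    if sd == 0:
        return np.zeros(shape)
    innov = rng.normal(0.0, sd, shape)
    out = np.empty(shape)
    out[..., 0] = innov[..., 0] / np.sqrt(1.0 - a * a)
    for i in range(1, shape[-1]):
        out[..., i] = a * out[..., i - 1] + innov[..., i]
    return out


def generate_dataset(cfg: SyntheticConfig, seed: int | None = None) -> EpochDataset:
    """Draw a full multi-subject dataset at the raw sampling rate.

    Each trial is its subject/class template plus AR(1) channel noise;
    lapse trials (probability ``lapse_prob``) contain noise only but keep
    their class label.  Deterministic for a fixed seed.
    """
    if seed is not None:
        cfg = SyntheticConfig(**{**cfg.__dict__, "seed": seed, "components": cfg.components})
    effects = subject_effects(cfg)
    rng = np.random.default_rng([cfg.seed, 104729])
    labels = cfg.labels
    lo, hi = cfg.trials_per_class_range

    data_parts: list[np.ndarray] = []
    meta_rows: list[dict] = []
    for s, eff in enumerate(effects):
        templates = [_raw_template(cfg, k, eff) for k in range(cfg.n_classes)]
        counts = rng.integers(lo, hi + 1, size=cfg.n_classes)
        trial_id = 0
        for k in range((cfg.n_classes)):
            n_k = int(counts[k])
            noise = _ar1_noise(
                rng, (n_k, cfg.n_channels, cfg.n_raw_timepoints), cfg.noise_sd, cfg.noise_autocorr
            )
            lapses = rng.random(n_k) < cfg.lapse_prob
            trials = noise + np.where(lapses[:, None, None], 0.0, 1.0) * templates[k]
            data_parts.append(trials)
            for _ in range(n_k):
                meta_rows.append(
                    {"subject_id": f"S{s:02d}", "trial_id": trial_id, "class_label": labels[k]}
                )
                trial_id += 1
    data = np.concatenate(data_parts, axis=0)
    return EpochDataset(
        data=data,
        metadata=pd.DataFrame(meta_rows),
        sampling_rate=cfg.sampling_rate,
        label_set=labels,
    )
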