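"""Synthetic ECG beat generator.

Beats are modelled as a sum of Gaussian waves (P, Q, R, S, T) on a slow
sinusoidal baseline with additive white noise — the McSharry-style morphology
without the dynamical system.  The generator exists so that every downstream
stage (scalogram, network, feature reduction, classifier) can be exercised on
labelled data with controllable class separation.

The default class roster mirrors the 17-class arrhythmia taxonomy commonly
used for MIT-BIH derived fragment datasets (normal sinus rhythm plus sixteen
arrhythmias), with the same per-class imbalance (1000 beats total).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveParams",
    "ClassTemplate",
    "SynthDataset",
    "make_beat",
    "make_dataset",
    "well_separated_suite",
    "default_class_templates",
    "DEFAULT_CLASS_COUNTS",
    "write_csv",
]

DEFAULT_FS = 360.0
DEFAULT_BEAT_DURATION = 1.0

#: Per-class beat counts of the 17-class fragment dataset (1000 beats total).
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "NSR": 283,
    "APB": 66,
    "AFL": 20,
    "AFIB": 135,
    "SVTA": 13,
    "WPW": 21,
    "PVC": 133,
    "Bigeminy": 55,
    "Trigeminy": 13,
    "VT": 10,
    "IVR": 10,
    "VFL": 10,
    "Fusion": 11,
    "LBBBB": 103,
    "RBBBB": 62,
    "SDHB": 10,
    "PR": 45,
}


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian component of a beat.

    center is in seconds within the beat, width (Gaussian sigma) in seconds,
    amplitude in mV (signed: Q and S waves are negative).
    """

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"wave width must be > 0, got {self.width}")


@dataclass(frozen=True)
class ClassTemplate:
    """Morphology template for one beat class."""

    name: str
    waves: tuple[WaveParams, ...]
    rate_jitter: float = 0.0
    noise_sd: float = 0.0
    baseline_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.rate_jitter < 1:
            raise ValueError("rate_jitter must be in [0, 1)")
        object.__setattr__(self, "waves", tuple(self.waves))


@dataclass
class SynthDataset:
    """Labelled fixed-length beats at a common sampling rate."""

    beats: list[tuple[np.ndarray, str]]
    fs: float
    seed: int
    beat_duration: float = DEFAULT_BEAT_DURATION

    def __len__(self) -> int:
        return len(self.beats)

    @property
    def labels(self) -> list[str]:
        return [lab for _, lab in self.beats]

    @property
    def samples(self) -> np.ndarray:
        return np.stack([s for s, _ in self.beats])


BASELINE_FREQ_HZ = 0.3  # slow respiratory-scale baseline wander


def make_beat(
    template: ClassTemplate,
    fs: float = DEFAULT_FS,
    beat_duration: float = DEFAULT_BEAT_DURATION,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one beat from a template.

    s(t) = sum_w a_w exp(-(t - mu_w)^2 / (2 sigma_w^2))
           + baseline_amp * sin(2 pi 0.3 t) + N(0, noise_sd).

    With rate_jitter > 0 every wave centre is shifted by a common random
    offset drawn as N(0, rate_jitter * beat_duration), emulating beat-to-beat
    rhythm irregularity.  Deterministic given the rng state.
    """
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    if beat_duration <= 0:
        raise ValueError(f"beat_duration must be > 0, got {beat_duration}")
    rng = np.random.default_rng(0) if rng is None else rng
    n = int(round(fs * beat_duration))
    t = np.arange(n) / fs
    shift = 0.0
    if template.rate_jitter > 0:
        shift = rng.normal(0.0, template.rate_jitter * beat_duration)
    s = np.zeros(n)
    for w in template.waves:
        mu = w.center + shift
        s += w.amplitude * np.exp(-((t - mu) ** 2) / (2.0 * w.width**2))
    if template.baseline_amp != 0.0:
        s += template.baseline_amp * np.sin(2.0 * np.pi * BASELINE_FREQ_HZ * t)
    if template.noise_sd > 0:
        s += rng.normal(0.0, template.noise_sd, size=n)
    return s


def make_dataset(
    templates: list[ClassTemplate],
    counts: list[int],
    fs: float = DEFAULT_FS,
    beat_duration: float = DEFAULT_BEAT_DURATION,
    seed: int = 0,
) -> SynthDataset:
    """Generate ``counts[i]`` beats from ``templates[i]``, reproducibly."""
    if len(counts) != len(templates):
        raise ValueError(
            f"len(counts)={len(counts)} != len(templates)={len(templates)}"
        )
    if any(c < 1 for c in counts):
        raise ValueError("every class count must be >= 1")
    rng = np.random.default_rng(seed)
    beats: list[tuple[np.ndarray, str]] = []
    for tmpl, c in zip(templates, counts):
        for _ in range(c):
            beats.append((make_beat(tmpl, fs, beat_duration, rng), tmpl.name))
    return SynthDataset(beats=beats, fs=fs, seed=seed, beat_duration=beat_duration)


def _pqrst(
    r_amp: float,
    qrs_width: float,
    p_amp: float,
    t_amp: float = 0.30,
    r_center: float = 0.42,
) -> tuple[WaveParams, ...]:
    """Standard P-QRS-T layout around an R peak, widths in seconds."""
    waves = []
    if p_amp != 0.0:
        waves.append(WaveParams(r_center - 0.18, 0.025, p_amp))
    waves.append(WaveParams(r_center - 0.035, 0.012, -0.15 * r_amp))  # Q
    waves.append(WaveParams(r_center, qrs_width, r_amp))  # R
    waves.append(WaveParams(r_center + 0.035, 0.014, -0.25 * r_amp))  # S
    if t_amp != 0.0:
        waves.append(WaveParams(r_center + 0.22, 0.055, t_amp))  # T
    return tuple(waves)


def default_class_templates(
    noise_sd: float = 0.03, baseline_amp: float = 0.05
) -> list[ClassTemplate]:
    """Seventeen nameable class templates with distinct morphologies.

    Morphology differences are stylised (amplitudes, QRS widths, P-wave
    presence, extra ectopic humps, rhythm jitter), not physiologically
    validated waveforms; they give each class a distinct time-frequency
    signature.
    """
    mk = ClassTemplate
    common = dict(noise_sd=noise_sd, baseline_amp=baseline_amp)
    out = [
        mk("NSR", _pqrst(1.0, 0.018, 0.15), **common),
        mk("APB", _pqrst(0.9, 0.018, 0.22, r_center=0.30), rate_jitter=0.03, **common),
        mk("AFL", _pqrst(0.9, 0.018, 0.0) + (WaveParams(0.10, 0.03, 0.25),
                                             WaveParams(0.68, 0.03, 0.25)), **common),
        mk("AFIB", _pqrst(0.95, 0.018, 0.0), rate_jitter=0.05, **common),
        mk("SVTA", _pqrst(0.85, 0.014, 0.10, r_center=0.25) + (WaveParams(0.75, 0.014, 0.85),), **common),
        mk("WPW", _pqrst(1.0, 0.030, 0.15) + (WaveParams(0.38, 0.030, 0.35),), **common),
        mk("PVC", _pqrst(1.4, 0.045, 0.0, t_amp=-0.35), **common),
        mk("Bigeminy", _pqrst(1.0, 0.018, 0.15, r_center=0.25) + (WaveParams(0.70, 0.045, 1.3),), **common),
        mk("Trigeminy", _pqrst(0.9, 0.016, 0.12, r_center=0.18) + (WaveParams(0.50, 0.016, 0.9),
                                                                    WaveParams(0.82, 0.045, 1.2)), **common),
        mk("VT", _pqrst(1.3, 0.055, 0.0, t_amp=-0.4, r_center=0.25) + (WaveParams(0.65, 0.055, 1.3),), **common),
        mk("IVR", _pqrst(0.8, 0.060, 0.0, t_amp=-0.3), **common),
        mk("VFL", tuple(WaveParams(0.1 + 0.2 * i, 0.05, 0.8 * (-1) ** i) for i in range(5)), **common),
        mk("Fusion", _pqrst(1.1, 0.032, 0.08), **common),
        mk("LBBBB", _pqrst(1.0, 0.040, 0.12, t_amp=-0.3), **common),
        mk("RBBBB", _pqrst(0.9, 0.020, 0.12) + (WaveParams(0.47, 0.020, 0.55),), **common),
        mk("SDHB", _pqrst(0.9, 0.018, 0.25, r_center=0.55), **common),
        mk("PR", _pqrst(1.0, 0.018, 0.20, r_center=0.30), **common),
    ]
    assert [t.name for t in out] == list(DEFAULT_CLASS_COUNTS)
    return out


def well_separated_suite(
    n_classes: int,
    n_per_class: int,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    beat_duration: float = DEFAULT_BEAT_DURATION,
) -> SynthDataset:
    """Low-noise dataset with strongly distinct class morphologies.

    Classes differ pairwise in R amplitude, QRS width and P-wave presence, so
    the scalogram -> CNN -> CoF pipeline should separate them linearly.
    """
    if not 2 <= n_classes <= 17:
        raise ValueError("n_classes must be in [2, 17]")
    templates = []
    for i in range(n_classes):
        r_amp = 0.6 + 0.25 * i
        qrs_w = 0.012 + 0.014 * i
        p_amp = 0.25 if i % 2 == 0 else 0.0
        t_amp = 0.30 if i % 3 else -0.30
        r_center = 0.30 + 0.05 * (i % 4)
        waves = _pqrst(r_amp, qrs_w, p_amp, t_amp=t_amp, r_center=r_center)
        if i % 3 == 2:  # ectopic second hump for every third class
            waves = waves + (WaveParams(r_center + 0.35, qrs_w, 0.8 * r_amp),)
        templates.append(
            ClassTemplate(f"class{i}", waves, noise_sd=0.02, baseline_amp=0.04)
        )
    counts = [n_per_class] * n_classes
    return make_dataset(templates, counts, fs, beat_duration, seed)


def write_csv(dataset: SynthDataset, path) -> None:
    """Write beats as ``label,fs,s0,s1,...`` rows (the preprocess CSV dialect)."""
    n = dataset.samples.shape[1]
    header = "label,fs," + ",".join(f"s{i}" for i in range(n))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for samples, label in dataset.beats:
            fh.write(label + "," + repr(float(dataset.fs)) + ",")
            fh.write(",".join(repr(float(v)) for v in samples) + "\n")


def table_dataset(seed: int = 0, **kwargs) -> SynthDataset:
    """The default 17-class, 1000-beat imbalanced dataset."""
    templates = default_class_templates()
    counts = [DEFAULT_CLASS_COUNTS[t.name] for t in templates]
    return make_dataset(templates, counts, seed=seed, **kwargs)
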