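"""Continuous wavelet transform scalograms of ECG beats.

Each beat s(t) is expanded against a scaled/translated analytic Morlet
family,

    W(a, b) = a^{-1/2} * integral s(t) conj(Psi((t - b)/a)) dt,

with the scale grid derived from a logarithmic frequency grid (a fixed number
of voices per octave between ``freq_min`` and ``freq_max``).  The magnitude
|W| is rendered as a square image (bilinear resize, per-image min-max to
[0, 1]) — the 2-D representation the network consumes.

The transform itself is evaluated with PyWavelets; coefficients are reported
in continuous-time units (scale in seconds), i.e. PyWavelets' sample-unit
output divided by sqrt(fs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from skimage.transform import resize

from .preprocess import Beat

__all__ = [
    "WaveletConfig",
    "Scalogram",
    "cwt_transform",
    "to_scalogram",
    "beat_to_scalogram",
    "scale_grid",
    "inverse_diagnostic",
]

DEFAULT_WAVELET = "cmor1.5-1.0"  # analytic Morlet, bandwidth 1.5, centre 1 Hz


@dataclass(frozen=True)
class WaveletConfig:
    wavelet_name: str = DEFAULT_WAVELET
    voices_per_octave: int = 12
    freq_min: float = 0.5
    freq_max: float = 40.0
    output_side: int = 256

    def __post_init__(self) -> None:
        if not 0 < self.freq_min < self.freq_max:
            raise ValueError("need 0 < freq_min < freq_max")
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")
        if self.output_side < 8:
            raise ValueError("output_side must be >= 8")

    def validate_fs(self, fs: float) -> None:
        if self.freq_max > fs / 2:
            raise ValueError(
                f"freq_max={self.freq_max} Hz exceeds Nyquist {fs / 2} Hz"
            )


@dataclass
class Scalogram:
    pixels: np.ndarray  # output_side x output_side, in [0, 1]
    label: str | None = None
    beat_ref: tuple[str, int] = ("", 0)


def scale_grid(cfg: WaveletConfig, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Frequencies (Hz, increasing) and matching PyWavelets scales (samples).

    Log-spaced with ``voices_per_octave`` scales per octave from freq_min up
    to and including freq_max.
    """
    cfg.validate_fs(fs)
    n_oct = np.log2(cfg.freq_max / cfg.freq_min)
    n = int(np.ceil(n_oct * cfg.voices_per_octave)) + 1
    freqs = cfg.freq_min * 2.0 ** (np.arange(n) / cfg.voices_per_octave)
    freqs = np.minimum(freqs, cfg.freq_max)
    fc = pywt.central_frequency(cfg.wavelet_name)
    scales = fc * fs / freqs
    return freqs, scales


def cwt_transform(beat: Beat, cfg: WaveletConfig) -> np.ndarray:
    """Complex CWT coefficient matrix, one row per scale (low->high frequency),
    one column per sample instant."""
    s = np.asarray(beat.samples, dtype=float)
    if s.size < 2:
        raise ValueError("beat must have at least 2 samples")
    freqs, scales = scale_grid(cfg, beat.fs)
    coef, _ = pywt.cwt(s, scales, cfg.wavelet_name, sampling_period=1.0 / beat.fs)
    # PyWavelets evaluates the transform in sample units; /sqrt(fs) converts
    # the a^{-1/2} prefactor to continuous-time (seconds) units.
    return np.asarray(coef) / np.sqrt(beat.fs)


def to_scalogram(
    coeffs: np.ndarray,
    cfg: WaveletConfig,
    label: str | None = None,
    beat_ref: tuple[str, int] = ("", 0),
) -> Scalogram:
    """Magnitude image: |coeffs| -> bilinear resize to a square -> min-max
    rescale to [0, 1] (a constant image maps to all zeros)."""
    if coeffs.size == 0:
        raise ValueError("empty coefficient matrix")
    mag = np.abs(np.asarray(coeffs))
    side = cfg.output_side
    img = resize(mag, (side, side), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    lo, hi = img.min(), img.max()
    img = np.zeros_like(img) if hi - lo == 0 else (img - lo) / (hi - lo)
    return Scalogram(pixels=img, label=label, beat_ref=beat_ref)


def beat_to_scalogram(beat: Beat, cfg: WaveletConfig) -> Scalogram:
    return to_scalogram(
        cwt_transform(beat, cfg),
        cfg,
        label=beat.label,
        beat_ref=(beat.source_record, beat.index),
    )


def inverse_diagnostic(beat: Beat, cfg: WaveletConfig) -> float:
    """Round-trip diagnostic: correlation between the beat and a crude
    inverse-transform reconstruction (sum of real coefficients over scales,
    Morlet delta-reconstruction style).  Not part of the pipeline; returns
    the Pearson correlation as a sanity number."""
    coef = cwt_transform(beat, cfg)
    freqs, scales = scale_grid(cfg, beat.fs)
    # delta-function reconstruction: sum Re(W)/sqrt(a) over log-spaced scales
    rec = (coef.real / np.sqrt(scales / beat.fs)[:, None]).sum(axis=0)
    s = beat.samples - np.mean(beat.samples)
    r = rec - rec.mean()
    denom = np.linalg.norm(s) * np.linalg.norm(r)
    return float(np.dot(s, r) / denom) if denom > 0 else 0.0
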