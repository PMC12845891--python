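"""Seedable training-time signal/mask augmentations.

Seven transforms, each applied independently with its own probability:
amplitude scaling, amplitude offset, colored noise (Gaussian, pink or
brown), baseline wander, random spikes, crop-and-pad time warping, and
polarity inversion. Amplitude-only transforms leave the mask untouched;
crop-and-pad warps signal and mask identically (mask resampled
nearest-neighbor). Masking, temporal shifting, mixup and cutmix are
deliberately not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masks import LabelMask

__all__ = ["AugmentConfig", "augment_pair", "colored_noise"]


@dataclass(frozen=True)
class AugmentConfig:
    p_scale: float = 0.75
    scale_range: tuple[float, float] = (0.6, 1.4)
    p_offset: float = 0.75
    offset_range: tuple[float, float] = (-0.1, 0.1)
    p_noise: float = 0.75
    noise_rms_range: tuple[float, float] = (0.01, 0.1)
    p_wander: float = 0.75
    wander_freq_range: tuple[float, float] = (0.05, 0.5)
    wander_amp_range: tuple[float, float] = (0.05, 0.3)
    p_spikes: float = 0.25
    spike_amp_range: tuple[float, float] = (0.5, 2.0)
    p_croppad: float = 0.25
    crop_frac_range: tuple[float, float] = (0.8, 1.0)
    p_invert: float = 0.35

    def __post_init__(self) -> None:
        for f in ("p_scale", "p_offset", "p_noise", "p_wander",
                  "p_spikes", "p_croppad", "p_invert"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")
        if self.scale_range[0] <= 0:
            raise ValueError("scale factors must be positive")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(p_scale=0, p_offset=0, p_noise=0, p_wander=0,
                   p_spikes=0, p_croppad=0, p_invert=0)


def colored_noise(length: int, kind: str, rms: float, seed) -> np.ndarray:
    """Gaussian, pink (1/f) or brown (1/f^2) noise at a target RMS.

    Pink and brown noise are made by spectrally shaping white noise in the
    frequency domain (exact slope control), then rescaling to ``rms``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if rms == 0:
        rng.standard_normal(length)  # keep the stream position deterministic
        return np.zeros(length)
    white = rng.standard_normal(length)
    if kind == "gaussian":
        y = white
    elif kind in ("pink", "brown"):
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(length)
        shape = np.ones_like(freqs)
        nz = freqs > 0
        exponent = 0.5 if kind == "pink" else 1.0  # PSD 1/f resp. 1/f^2
        shape[nz] = freqs[nz] ** (-exponent)
        shape[0] = 0.0
        y = np.fft.irfft(spec * shape, n=length)
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    y = y - y.mean()
    cur = np.sqrt(np.mean(y**2))
    return y * (rms / cur) if cur > 0 else y


def _crop_and_pad(signal, labels, frac, fs):
    """Crop a leading fraction of the window, stretch back to full length."""
    n = len(signal)
    keep = max(int(round(frac * n)), 2)
    x_old = np.arange(keep)
    pos = np.linspace(0, keep - 1, n)
    sig = np.interp(pos, x_old, signal[:keep])
    nearest = np.clip(np.round(pos).astype(int), 0, keep - 1)
    lab = labels[:keep][nearest]
    return sig, lab


def augment_pair(
    signal: np.ndarray,
    mask: LabelMask,
    config: AugmentConfig = AugmentConfig(),
    seed=0,
) -> tuple[np.ndarray, LabelMask]:
    """Apply the augmentation stack to one (signal, mask) pair.

    Deterministic given ``seed``; output lengths equal input lengths.
    """
    signal = np.asarray(signal, dtype=np.float64)
    labels = np.asarray(mask.labels)
    if len(signal) != len(labels):
        raise ValueError("signal and mask lengths differ")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(signal)
    fs = mask.fs
    out = signal.copy()

    if rng.uniform() < config.p_scale:
        out = out * rng.uniform(*config.scale_range)
    if rng.uniform() < config.p_offset:
        out = out + rng.uniform(*config.offset_range)
    if rng.uniform() < config.p_noise:
        kind = ("gaussian", "pink", "brown")[rng.integers(3)]
        rms = rng.uniform(*config.noise_rms_range)
        out = out + colored_noise(n, kind, rms, rng)
    if rng.uniform() < config.p_wander:
        t = np.arange(n) / fs
        for _ in range(rng.integers(1, 4)):
            f = rng.uniform(*config.wander_freq_range)
            a = rng.uniform(*config.wander_amp_range)
            out = out + a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if rng.uniform() < config.p_spikes:
        for _ in range(rng.integers(1, 6)):
            pos = rng.integers(0, n)
            width = rng.integers(1, 4)
            amp = rng.uniform(*config.spike_amp_range) * rng.choice((-1.0, 1.0))
            out[pos : pos + width] += amp
    if rng.uniform() < config.p_croppad:
        frac = rng.uniform(*config.crop_frac_range)
        out, labels = _crop_and_pad(out, labels, frac, fs)
    if rng.uniform() < config.p_invert:
        out = -out
    return out, LabelMask(labels=labels, fs=fs)
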