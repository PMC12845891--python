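"""Model diagnostics: Grad-CAM saliency and first-layer kernel analyses.

``layer_gradcam`` adapts class-activation mapping to the segmentation
head: the scalar target is the time-summed logit of the chosen class, the
chosen layer's activations are weighted by their time-averaged gradients,
channel-summed, rectified, and linearly upsampled to the input length.

Kernel diagnostics treat each learned first-layer kernel as an FIR filter
(frequency response, -3 dB cutoff) and measure Pearson correlation between
flattened kernel weight vectors to check that the filters learned distinct
patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from . import _autograd as ag
from .network import UNet1d

__all__ = ["SaliencyMap", "layer_gradcam", "kernel_correlation",
           "kernel_frequency_response"]


@dataclass
class SaliencyMap:
    """Non-negative per-sample attribution over the input."""

    weights: np.ndarray
    layer_id: str
    target_class: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if (self.weights < 0).any():
            raise ValueError("saliency weights must be non-negative")


def layer_gradcam(
    model: UNet1d,
    signal: np.ndarray,
    target_class: int,
    layer_id: str = "dec3",
) -> SaliencyMap:
    """Grad-CAM over the input time series for one class.

    The attribution layer defaults to the final decoder convolution.
    """
    signal = np.asarray(signal, dtype=np.float32)
    if signal.ndim != 1:
        raise ValueError("layer_gradcam expects a single 1-D signal")
    capture: dict = {}
    logits = model.forward_batch(signal[None, :], capture=capture)
    if layer_id not in capture:
        raise KeyError(
            f"unknown layer {layer_id!r}; available: {sorted(capture)}"
        )
    if not 0 <= target_class < model.config.n_classes:
        raise ValueError(f"target_class must be in [0, {model.config.n_classes})")
    target = ag.tsum(logits[:, target_class, :])
    model.zero_grad()
    target.backward()
    act = capture[layer_id]
    if act.grad is None:
        raise RuntimeError(f"no gradient reached layer {layer_id!r}")
    alpha = act.grad.mean(axis=2, keepdims=True)  # (1, C, 1)
    cam = np.maximum((alpha * act.data).sum(axis=1)[0], 0.0)  # (L_layer,)
    n = len(signal)
    if len(cam) != n:
        x_old = np.linspace(0.0, 1.0, len(cam))
        x_new = np.linspace(0.0, 1.0, n)
        cam = np.interp(x_new, x_old, cam)
    return SaliencyMap(weights=cam, layer_id=layer_id, target_class=target_class)


def _layer_kernels(model: UNet1d, layer_id: str) -> np.ndarray:
    name = layer_id if layer_id in model.params else f"{layer_id}.w"
    if name not in model.params:
        raise KeyError(f"no convolutional layer named {layer_id!r}")
    w = model.params[name].data
    if w.ndim == 1:
        raise ValueError(f"{layer_id!r} is not a convolutional layer")
    return w.reshape(w.shape[0], -1).astype(np.float64)


def kernel_correlation(model: UNet1d, layer_id: str = "stem"):
    """Pearson correlation between flattened kernels of one layer.

    Returns ``(matrix, (hist, bin_edges))``. Zero-variance kernels get NaN
    (absent) correlations; the histogram covers finite off-diagonal values.
    """
    k = _layer_kernels(model, layer_id)
    if k.shape[0] < 2:
        raise ValueError("kernel_correlation needs at least two kernels")
    std = k.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(k)
    mat[std == 0, :] = np.nan
    mat[:, std == 0] = np.nan
    np.fill_diagonal(mat, np.where(std > 0, 1.0, np.nan))
    off = mat[~np.eye(len(mat), dtype=bool)]
    off = off[np.isfinite(off)]
    hist, edges = np.histogram(off, bins=21, range=(-1.0, 1.0))
    return mat, (hist, edges)


def kernel_frequency_response(
    model: UNet1d, layer_id: str = "stem", fs: float = 125.0, n_freq: int = 512
):
    """FIR frequency response of each kernel in a layer.

    Returns a dict with ``freqs_hz`` (n_freq,), ``magnitude_db`` and
    ``phase_rad`` (n_kernels, n_freq), and the -3 dB cutoff per kernel
    (NaN when the response never drops 3 dB below its maximum).
    """
    kernels = _layer_kernels(model, layer_id)
    freqs = None
    mags, phases, cutoffs = [], [], []
    for taps in kernels:
        w, h = scipy.signal.freqz(taps, worN=n_freq, fs=fs)
        freqs = w
        mag_db = 20.0 * np.log10(np.maximum(np.abs(h), 1e-12))
        mags.append(mag_db)
        phases.append(np.unwrap(np.angle(h)))
        below = np.flatnonzero(mag_db <= mag_db.max() - 3.0)
        cutoffs.append(float(w[below[0]]) if below.size else np.nan)
    return {
        "freqs_hz": freqs,
        "magnitude_db": np.array(mags),
        "phase_rad": np.array(phases),
        "cutoff_3db_hz": np.array(cutoffs),
    }
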