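"""Fully convolutional 1D U-Net with a ConvNeXt V2 encoder.

Encoder: a stem (conv k=4, stride 4, then LayerNorm) followed by three
downsampling layers (LayerNorm, conv k=2 stride 2), with ConvNeXt V2
blocks at each of the four stages (depthwise conv k=7, LayerNorm, a
pointwise expansion, GELU, Global Response Normalization, a pointwise
reduction, residual). Filters start at ``base_filters`` and double per
stage. The bottleneck uses two depthwise-separable k=7 convolutions.
Decoder blocks upsample (linear, x2; x4 in the last block to undo the
stem), fuse the matching encoder stage by channel concatenation, and apply
conv k=3, LayerNorm and LeakyReLU. A 1x1 head plus per-sample softmax
yields an L x C probability mask, so arbitrary input lengths >= 400
samples are supported (inputs are right-padded internally to a multiple
of 32 and the output cropped back to L).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor

__all__ = ["ModelConfig", "ProbMask", "UNet1d", "build_model", "forward", "grn",
           "save_checkpoint", "load_checkpoint"]

#: total temporal downsampling of the encoder (stem x4, three x2 stages)
_DOWN_TOTAL = 32


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults follow the small model)."""

    base_filters: int = 16
    n_stages: int = 4
    blocks_per_stage: tuple[int, ...] = (2, 2, 2, 2)
    block_kernel: int = 7
    block_dilation: int = 1
    stem_kernel: int = 4
    stem_stride: int = 4
    down_kernel: int = 2
    down_stride: int = 2
    expansion_ratio: int = 4
    decoder_kernel: int = 3
    leaky_slope: float = 0.01
    n_classes: int = 4
    min_input_samples: int = 400

    def __post_init__(self) -> None:
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if len(self.blocks_per_stage) != self.n_stages:
            raise ValueError("blocks_per_stage must list one count per stage")
        if self.decoder_kernel % 2 != 1:
            raise ValueError("decoder_kernel must be odd (symmetric same padding)")
        if self.block_dilation != 1:
            raise ValueError("only dilation 1 is supported")

    @property
    def stage_widths(self) -> tuple[int, ...]:
        return tuple(self.base_filters * 2**s for s in range(self.n_stages))


@dataclass
class ProbMask:
    """Per-sample class probabilities, shape (time, n_classes)."""

    probs: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2:
            raise ValueError("probs must be 2-D (time, n_classes)")
        rows = self.probs.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-5):
            raise ValueError("probability rows must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]


def grn(features: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
        eps: float = 1e-6) -> np.ndarray:
    """Global Response Normalization on a (time, channels) array.

    ``g_c`` is the per-channel L2 norm over time; the output is
    ``gamma * (x * g_c / mean_c(g)) + beta + x``. With gamma = beta = 0 the
    residual term makes this the identity.
    """
    x = np.asarray(features, dtype=np.float64)
    g = np.sqrt((x**2).sum(axis=0))  # (channels,)
    nx = g / (g.mean() + eps)
    return gamma * (x * nx) + beta + x


def _grn_op(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """GRN over an (N, C, L) tensor, composed from autograd primitives."""
    g = ag.power(ag.add(ag.tsum(ag.mul(x, x), axis=2, keepdims=True), 1e-12), 0.5)
    c = x.data.shape[1]
    mean_g = ag.mul(ag.tsum(g, axis=1, keepdims=True), 1.0 / c)  # (N, 1, 1)
    nx = ag.mul(g, ag.power(ag.add(mean_g, eps), -1.0))  # (N, C, 1)
    return ag.add(ag.add(ag.mul(_reshape3(gamma), ag.mul(x, nx)), _reshape3(beta)), x)


def _reshape3(p: Tensor) -> Tensor:
    """View a (C,) parameter as (1, C, 1) while sharing the gradient."""
    out = ag.Tensor(p.data.reshape(1, -1, 1))
    out._prev = (p,) if (p.requires_grad or p._prev) else ()
    if out._prev:
        out._backward = lambda g: ag._accum(p, g.sum(axis=(0, 2)))
    return out


class _ParamStore:
    """Flat name -> Tensor parameter registry."""

    def __init__(self, seed: int):
        self.rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}

    def conv_w(self, name: str, shape: tuple, std: float = 0.02) -> Tensor:
        w = np.clip(self.rng.normal(0.0, std, size=shape), -2 * std, 2 * std)
        return self._add(name, w)

    def zeros(self, name: str, n: int) -> Tensor:
        return self._add(name, np.zeros(n))

    def ones(self, name: str, n: int) -> Tensor:
        return self._add(name, np.ones(n))

    def _add(self, name: str, value: np.ndarray) -> Tensor:
        if name in self.params:
            raise ValueError(f"duplicate parameter {name}")
        t = Tensor(value, requires_grad=True)
        self.params[name] = t
        return t


class UNet1d:
    """The segmentation network; parameters live in ``self.params``."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        store = _ParamStore(seed)
        c = config
        w = c.stage_widths
        k = c.block_kernel

        store.conv_w("stem.w", (w[0], 1, c.stem_kernel))
        store.zeros("stem.b", w[0])
        store.ones("stem.ln.g", w[0])
        store.zeros("stem.ln.b", w[0])
        for s in range(c.n_stages):
            if s > 0:
                store.ones(f"down{s}.ln.g", w[s - 1])
                store.zeros(f"down{s}.ln.b", w[s - 1])
                store.conv_w(f"down{s}.w", (w[s], w[s - 1], c.down_kernel))
                store.zeros(f"down{s}.b", w[s])
            for b in range(c.blocks_per_stage[s]):
                p = f"enc{s}.{b}"
                ch, hidden = w[s], w[s] * c.expansion_ratio
                store.conv_w(f"{p}.dw.w", (ch, k))
                store.zeros(f"{p}.dw.b", ch)
                store.ones(f"{p}.ln.g", ch)
                store.zeros(f"{p}.ln.b", ch)
                store.conv_w(f"{p}.pw1.w", (hidden, ch, 1))
                store.zeros(f"{p}.pw1.b", hidden)
                store.zeros(f"{p}.grn.g", hidden)
                store.zeros(f"{p}.grn.b", hidden)
                store.conv_w(f"{p}.pw2.w", (ch, hidden, 1))
                store.zeros(f"{p}.pw2.b", ch)
        top = w[-1]
        for i in range(2):
            p = f"bott.{i}"
            store.conv_w(f"{p}.dw.w", (top, k))
            store.zeros(f"{p}.dw.b", top)
            store.conv_w(f"{p}.pw.w", (top, top, 1))
            store.zeros(f"{p}.pw.b", top)
            store.ones(f"{p}.ln.g", top)
            store.zeros(f"{p}.ln.b", top)
        # decoder: three x2 blocks with skip fusion, one x4 block to undo the stem
        dec_in = [w[3], w[2], w[1], w[0]]
        dec_skip = [w[2], w[1], w[0], 0]
        dec_out = [w[2], w[1], w[0], w[0]]
        for d in range(4):
            p = f"dec{d}"
            cin = dec_in[d] + dec_skip[d]
            store.conv_w(f"{p}.w", (dec_out[d], cin, c.decoder_kernel))
            store.zeros(f"{p}.b", dec_out[d])
            store.ones(f"{p}.ln.g", dec_out[d])
            store.zeros(f"{p}.ln.b", dec_out[d])
        store.conv_w("head.w", (c.n_classes, w[0], 1))
        store.zeros("head.b", c.n_classes)
        self.params = store.params
        self._dec_out = dec_out

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            raise ValueError("state dict does not match the model's parameters")
        for k, v in state.items():
            if v.shape != self.params[k].data.shape:
                raise ValueError(f"shape mismatch for parameter {k}")
            self.params[k].data = np.asarray(v, dtype=np.float32).copy()

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    # -- forward ------------------------------------------------------------
    def _block(self, x: Tensor, prefix: str) -> Tensor:
        P = self.params
        k = self.config.block_kernel
        pad = (k // 2, k - 1 - k // 2)
        h = ag.dwconv1d(x, P[f"{prefix}.dw.w"], P[f"{prefix}.dw.b"], padding=pad)
        h = ag.layer_norm(h, P[f"{prefix}.ln.g"], P[f"{prefix}.ln.b"])
        h = ag.conv1d(h, P[f"{prefix}.pw1.w"], P[f"{prefix}.pw1.b"])
        h = ag.gelu(h)
        h = _grn_op(h, P[f"{prefix}.grn.g"], P[f"{prefix}.grn.b"])
        h = ag.conv1d(h, P[f"{prefix}.pw2.w"], P[f"{prefix}.pw2.b"])
        return ag.add(x, h)

    def forward_tensor(self, x: Tensor, capture: dict | None = None) -> Tensor:
        """Run the network on an (N, 1, L) tensor; L must be a multiple of 32.

        Returns pre-softmax logits (N, n_classes, L). When ``capture`` is a
        dict, named intermediate activation tensors are stored in it.
        """
        P, c = self.params, self.config
        k = c.block_kernel
        h = ag.conv1d(x, P["stem.w"], P["stem.b"], stride=c.stem_stride)
        h = ag.layer_norm(h, P["stem.ln.g"], P["stem.ln.b"])
        if capture is not None:
            capture["stem"] = h
        skips = []
        for s in range(c.n_stages):
            if s > 0:
                h = ag.layer_norm(h, P[f"down{s}.ln.g"], P[f"down{s}.ln.b"])
                h = ag.conv1d(h, P[f"down{s}.w"], P[f"down{s}.b"], stride=c.down_stride)
            for b in range(c.blocks_per_stage[s]):
                h = self._block(h, f"enc{s}.{b}")
            skips.append(h)
            if capture is not None:
                capture[f"enc{s}"] = h
        for i in range(2):
            p = f"bott.{i}"
            pad = (k // 2, k - 1 - k // 2)
            h = ag.dwconv1d(h, P[f"{p}.dw.w"], P[f"{p}.dw.b"], padding=pad)
            h = ag.conv1d(h, P[f"{p}.pw.w"], P[f"{p}.pw.b"])
            h = ag.layer_norm(h, P[f"{p}.ln.g"], P[f"{p}.ln.b"])
            h = ag.gelu(h)
        if capture is not None:
            capture["bottleneck"] = h
        kd = c.decoder_kernel
        dpad = (kd // 2, kd // 2)
        for d in range(4):
            factor = c.stem_stride if d == 3 else 2
            h = ag.upsample_linear(h, factor)
            if d < 3:
                h = ag.concat([h, skips[2 - d]], axis=1)
            h = ag.conv1d(h, P[f"dec{d}.w"], P[f"dec{d}.b"], padding=dpad)
            h = ag.layer_norm(h, P[f"dec{d}.ln.g"], P[f"dec{d}.ln.b"])
            h = ag.leaky_relu(h, c.leaky_slope)
            if capture is not None:
                capture[f"dec{d}"] = h
        logits = ag.conv1d(h, P["head.w"], P["head.b"])
        if capture is not None:
            capture["logits"] = logits
        return logits

    def forward_batch(self, signals: np.ndarray, capture: dict | None = None,
                      build_graph: bool = False) -> Tensor:
        """Forward a (N, L) float batch; pads L to a multiple of 32 and crops
        the logits back to L. Returns the logits tensor."""
        signals = np.atleast_2d(np.asarray(signals, dtype=np.float32))
        n, L = signals.shape
        if L < self.config.min_input_samples:
            raise ValueError(
                f"input length {L} is below the model's minimum of "
                f"{self.config.min_input_samples} samples (3.2 s at 125 Hz)"
            )
        pad = (-L) % _DOWN_TOTAL
        x = Tensor(signals[:, None, :], requires_grad=build_graph)
        if pad:
            x = ag.pad_time(x, 0, pad)
        logits = self.forward_tensor(x, capture=capture)
        if pad:
            logits = ag.crop_time(logits, 0, L)
        return logits

    def predict_proba(self, signal: np.ndarray, fs: float = 125.0) -> ProbMask:
        """Inference on a single 1-D signal; returns an L x C ProbMask."""
        signal = np.asarray(signal, dtype=np.float32)
        if signal.ndim != 1:
            raise ValueError("predict_proba expects a single 1-D signal")
        logits = self.forward_batch(signal[None, :])
        probs = ag.softmax_channels(logits).data[0].T  # (L, C)
        probs = probs / probs.sum(axis=1, keepdims=True)
        return ProbMask(probs=probs, fs=fs)


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0) -> UNet1d:
    """Construct the network with seeded parameter initialization."""
    return UNet1d(config, seed=seed)


def forward(model: UNet1d, signal: np.ndarray, fs: float = 125.0) -> ProbMask:
    """Functional inference wrapper over :meth:`UNet1d.predict_proba`."""
    return model.predict_proba(signal, fs=fs)


# -- checkpointing ----------------------------------------------------------

def _config_hash(config: ModelConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_checkpoint(model: UNet1d, path, metadata: dict | None = None) -> None:
    """Serialize config + parameters (+ metadata) to one .npz archive."""
    meta = {
        "config": asdict(model.config),
        "config_hash": _config_hash(model.config),
        "metadata": metadata or {},
    }
    np.savez(path, __meta__=json.dumps(meta, default=list), **model.state_dict())


def load_checkpoint(path) -> UNet1d:
    """Load a checkpoint, validating the stored config hash."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    cfg_dict = meta["config"]
    cfg_dict["blocks_per_stage"] = tuple(cfg_dict["blocks_per_stage"])
    config = ModelConfig(**cfg_dict)
    if _config_hash(config) != meta["config_hash"]:
        raise ValueError("checkpoint config hash mismatch")
    model = UNet1d(config)
    model.load_state_dict(state)
    return model
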