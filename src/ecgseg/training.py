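"""Dice-loss training with oversampling, one-cycle scheduling and
F1-based early stopping.

The loss is a soft Dice loss averaged (unweighted macro) over the four
classes including background, with the smoothing constant epsilon in both
numerator and denominator, so empty classes contribute a perfect ratio of
1. Optimization uses AdamW (beta1=0.9, beta2=0.999, no weight decay by
default) at an initial/maximum learning rate of 0.001 under a one-cycle
schedule. Validation Se/Pr/F1 are computed each epoch through the full
post-processing + matching path; the early-stopping metric is the mean of
the PVC and PAC F1 scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from .augment import AugmentConfig, augment_pair
from .evaluation import compute_metrics, match_beats, pool_matches
from .masks import LabelMask, MaskWindows, build_mask, mask_to_onehot
from .network import ProbMask, UNet1d
from .postprocess import PostprocessConfig, beats_from_mask
from .records import CLASS_NAMES, PAC, PVC

__all__ = ["TrainConfig", "dice_loss", "make_sampler", "train",
           "AdamW", "one_cycle_lr"]


@dataclass(frozen=True)
class TrainConfig:
    lr_init: float = 1e-3
    lr_max: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.0
    batch_size: int = 8
    epochs: int = 10
    dice_epsilon: float = 1.0
    oversample_factors: dict = field(default_factory=lambda: {PVC: 4.0, PAC: 4.0})
    early_stop_patience: int = 3
    seed: int = 0
    pct_start: float = 0.3
    div_factor: float = 25.0
    final_div_factor: float = 1e4
    tol_ms: float = 75.0
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if self.lr_init < 0 or self.lr_max < 0:
            raise ValueError("learning rates must be non-negative")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        for f in self.oversample_factors.values():
            if f < 1:
                raise ValueError("oversample factors must be >= 1")


# ---------------------------------------------------------------------------
# Dice loss


def _dice_from_sums(inter, psum, tsum_, eps):
    return (2.0 * inter + eps) / (psum + tsum_ + eps)


def dice_loss(pred, target, epsilon: float = 1.0) -> float:
    """Soft Dice loss between a probability mask and a label mask.

    ``loss = 1 - mean_c (2 sum(p_c t_c) + eps) / (sum p_c + sum t_c + eps)``
    over all classes (one-hot target). Returns a float in [0, 1]; exactly 0
    iff ``pred`` is the one-hot encoding of ``target``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    p = pred.probs if isinstance(pred, ProbMask) else np.asarray(pred, dtype=np.float64)
    if isinstance(target, LabelMask):
        t = mask_to_onehot(target, n_classes=p.shape[1]).astype(np.float64)
    else:
        t = np.asarray(target, dtype=np.float64)
        if t.ndim == 1:
            t = np.eye(p.shape[1])[t.astype(int)]
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    inter = (p * t).sum(axis=0)
    ratios = _dice_from_sums(inter, p.sum(axis=0), t.sum(axis=0), epsilon)
    return float(1.0 - ratios.mean())


def _dice_loss_op(probs: ag.Tensor, onehot: np.ndarray, epsilon: float) -> ag.Tensor:
    """Autograd Dice loss on (N, C, L) probabilities vs one-hot target."""
    t = ag.Tensor(onehot)
    inter = ag.tsum(ag.mul(probs, t), axis=(0, 2))
    psum = ag.tsum(probs, axis=(0, 2))
    tsum_ = onehot.sum(axis=(0, 2))
    ratio = ag.mul(
        ag.add(ag.mul(inter, 2.0), epsilon),
        ag.power(ag.add(ag.add(psum, tsum_), epsilon), -1.0),
    )
    n_classes = onehot.shape[1]
    return ag.add(1.0, ag.mul(ag.tsum(ratio), -1.0 / n_classes))


# ---------------------------------------------------------------------------
# Sampler & schedule


def make_sampler(dataset, oversample_factors: dict) -> np.ndarray:
    """Per-segment sampling weights, normalized to sum to 1.

    A segment containing at least one PVC (resp. PAC) gets its weight
    multiplied by the PVC (resp. PAC) factor; a segment containing both
    takes the larger of the two factors. No weight is ever zero.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    for f in oversample_factors.values():
        if f < 1:
            raise ValueError("oversample factors must be >= 1")
    weights = np.ones(len(dataset))
    for i, (_rec, anns) in enumerate(dataset):
        labels = {a.label for a in anns}
        factors = [oversample_factors.get(c, 1.0) for c in (PVC, PAC) if c in labels]
        if factors:
            weights[i] *= max(factors)
    return weights / weights.sum()


def one_cycle_lr(step: int, total_steps: int, lr_max: float,
                 pct_start: float = 0.3, div_factor: float = 25.0,
                 final_div_factor: float = 1e4) -> float:
    """Cosine-annealed one-cycle schedule (warmup then decay)."""
    if total_steps <= 1:
        return lr_max
    warm = max(int(round(pct_start * total_steps)), 1)
    lr_start = lr_max / div_factor
    lr_end = lr_max / final_div_factor
    if step < warm:
        frac = step / warm
        return lr_start + (lr_max - lr_start) * 0.5 * (1 - np.cos(np.pi * frac))
    frac = (step - warm) / max(total_steps - warm, 1)
    return lr_end + (lr_max - lr_end) * 0.5 * (1 + np.cos(np.pi * min(frac, 1.0)))


class AdamW:
    """AdamW with decoupled weight decay over a list of Tensors."""

    def __init__(self, params, betas=(0.9, 0.999), weight_decay=0.0, eps=1e-8):
        self.params = list(params)
        self.b1, self.b2 = betas
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if self.weight_decay:
                p.data -= lr * self.weight_decay * p.data
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# Training loop


def _prepare_segments(data, windows: MaskWindows):
    """(record, annotations) pairs -> (signal float32, LabelMask) pairs."""
    out = []
    for rec, anns in data:
        sig = rec.lead(0).astype(np.float32)
        mask = build_mask(anns, rec.n_samples, rec.fs, windows)
        out.append((sig, mask))
    return out


def validate(model: UNet1d, val_data, tol_ms: float = 75.0,
             post_config: PostprocessConfig = PostprocessConfig()):
    """Run the full inference + post-processing + matching path."""
    results = []
    for rec, anns in val_data:
        prob = model.predict_proba(rec.lead(0), fs=rec.fs)
        dets = beats_from_mask(prob, post_config)
        results.append(
            match_beats(anns, dets, fs=rec.fs, tol_ms=tol_ms,
                        record_length=rec.n_samples)
        )
    report = compute_metrics(pool_matches(results))
    return report, results


def train(model: UNet1d, train_data, val_data, config: TrainConfig = TrainConfig(),
          windows: MaskWindows = MaskWindows(), verbose: bool = False):
    """Train the model; returns ``(model, history)``.

    ``train_data``/``val_data`` are lists of ``(ECGRecord, annotations)``.
    The best checkpoint (highest mean of PVC and PAC F1 on validation) is
    restored into the model before returning. History is a list of
    per-epoch dicts (loss, lr, validation Se/Pr/F1 per class).
    """
    if not val_data or all(len(anns) == 0 for _r, anns in val_data):
        raise ValueError("val_data must contain annotations")
    rng = np.random.default_rng(config.seed)
    segments = _prepare_segments(train_data, windows)
    dataset_for_weights = list(train_data)
    weights = make_sampler(dataset_for_weights, config.oversample_factors)
    opt = AdamW(model.parameters(), betas=config.betas,
                weight_decay=config.weight_decay)
    n = len(segments)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = steps_per_epoch * config.epochs
    history: list[dict] = []
    best_metric = -np.inf
    best_state = model.state_dict()
    epochs_since_best = 0
    step = 0

    for epoch in range(config.epochs):
        order = rng.choice(n, size=n, replace=True, p=weights)
        losses = []
        for b0 in range(0, n, config.batch_size):
            batch_idx = order[b0 : b0 + config.batch_size]
            sigs, targets = [], []
            for i in batch_idx:
                sig, mask = segments[i]
                if config.augment is not None:
                    aug_seed = int(rng.integers(0, 2**31 - 1))
                    sig, mask = augment_pair(sig, mask, config.augment, aug_seed)
                sigs.append(np.asarray(sig, dtype=np.float32))
                targets.append(mask_to_onehot(mask).T)  # (C, L)
            x = np.stack(sigs)
            onehot = np.stack(targets).astype(np.float32)
            logits = model.forward_batch(x, build_graph=True)
            probs = ag.softmax_channels(logits)
            loss = _dice_loss_op(probs, onehot, config.dice_epsilon)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}: "
                    f"loss={float(loss.data)}, lr={one_cycle_lr(step, total_steps, config.lr_max)}"
                )
            model.zero_grad()
            loss.backward()
            lr = one_cycle_lr(step, total_steps, config.lr_max, config.pct_start,
                              config.div_factor, config.final_div_factor)
            opt.step(lr)
            losses.append(float(loss.data))
            step += 1

        report, _ = validate(model, val_data, tol_ms=config.tol_ms)
        f1s = []
        for c in (PVC, PAC):
            v = report.metrics[CLASS_NAMES[c]]["F1"]
            f1s.append(0.0 if v is None else v)
        val_metric = float(np.mean(f1s))
        entry = {
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "lr": one_cycle_lr(step - 1, total_steps, config.lr_max,
                               config.pct_start, config.div_factor,
                               config.final_div_factor),
            "val_metric": val_metric,
        }
        for key, m in report.metrics.items():
            for stat in ("Se", "Pr", "F1"):
                entry[f"{key}_{stat}"] = m[stat]
        history.append(entry)
        if verbose:
            print(f"epoch {epoch}: loss={entry['loss']:.4f} "
                  f"val(F1 PVC,PAC)={val_metric:.3f}", flush=True)
        if val_metric > best_metric + 1e-9:
            best_metric = val_metric
            best_state = model.state_dict()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.early_stop_patience:
                break

    model.load_state_dict(best_state)
    return model, history
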