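"""Per-sample segmentation targets from beat annotations.

Each beat paints its class over a window around the R-peak: Normal and PAC
from 100 ms before to 100 ms after, PVC from 100 ms before to 150 ms after
(the wider QRS). Offsets in samples are ``round(ms * fs / 1000)`` (ties
half up), intervals half-open. Overlapping windows resolve to the nearest
R-peak; exact ties go PVC > PAC > Normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import BACKGROUND, NORMAL, PAC, PVC, BeatAnnotation

__all__ = ["MaskWindows", "LabelMask", "build_mask", "mask_to_onehot"]

#: tie-break priority when a sample is equidistant from two R-peaks
_PRIORITY = {PVC: 2, PAC: 1, NORMAL: 0}


@dataclass(frozen=True)
class MaskWindows:
    """Per-class mask extents in ms around the R-peak."""

    normal_pre_ms: float = 100.0
    normal_post_ms: float = 100.0
    pvc_pre_ms: float = 100.0
    pvc_post_ms: float = 150.0
    pac_pre_ms: float = 100.0
    pac_post_ms: float = 100.0

    def __post_init__(self) -> None:
        for f in self.__dataclass_fields__:
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    def pre_post(self, label: int) -> tuple[float, float]:
        return {
            NORMAL: (self.normal_pre_ms, self.normal_post_ms),
            PVC: (self.pvc_pre_ms, self.pvc_post_ms),
            PAC: (self.pac_pre_ms, self.pac_post_ms),
        }[label]


@dataclass
class LabelMask:
    """Hard per-sample class labels in {0,1,2,3} plus the sampling rate."""

    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if not np.isin(self.labels, (BACKGROUND, NORMAL, PVC, PAC)).all():
            raise ValueError("mask labels must be in {0,1,2,3}")

    def __len__(self) -> int:
        return len(self.labels)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def build_mask(
    annotations: list[BeatAnnotation],
    length: int,
    fs: float,
    windows: MaskWindows = MaskWindows(),
) -> LabelMask:
    """Paint each beat's class window into a per-sample label array.

    Overlaps resolve to the nearest annotated R-peak (ties by class
    priority PVC > PAC > Normal); untouched samples stay background.
    """
    labels = np.zeros(length, dtype=np.int8)
    if not annotations:
        return LabelMask(labels=labels, fs=fs)
    # owner of each painted sample: distance to its R-peak, for overlap resolution
    dist = np.full(length, np.iinfo(np.int64).max, dtype=np.int64)
    prio = np.full(length, -1, dtype=np.int8)
    for ann in annotations:
        if not 0 <= ann.index < length:
            raise ValueError(
                f"annotation index {ann.index} outside mask of length {length}"
            )
        pre_ms, post_ms = windows.pre_post(ann.label)
        start = max(ann.index - _round_half_up(pre_ms * fs / 1000.0), 0)
        stop = min(ann.index + _round_half_up(post_ms * fs / 1000.0), length)
        if stop <= start:
            continue
        sl = np.arange(start, stop)
        d = np.abs(sl - ann.index)
        p = _PRIORITY[ann.label]
        take = (d < dist[sl]) | ((d == dist[sl]) & (p > prio[sl]))
        idx = sl[take]
        labels[idx] = ann.label
        dist[idx] = d[take]
        prio[idx] = p
    return LabelMask(labels=labels, fs=fs)


def mask_to_onehot(mask: LabelMask, n_classes: int = 4) -> np.ndarray:
    """One-hot encode a label mask to shape ``(time, n_classes)``."""
    labels = mask.labels
    if labels.max(initial=0) >= n_classes:
        raise ValueError("label value exceeds n_classes")
    return np.eye(n_classes, dtype=np.float32)[labels]
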