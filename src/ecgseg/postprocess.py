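"""Probability mask -> beat list, and multi-lead vote merging.

A QRS mask is formed as ``1 - background`` (the output rows are
softmaxed); maximal runs where it exceeds the threshold (default 0.9) for
at least a minimum duration become detections. Each region is labelled by
the argmax of the per-region means of the Normal/PVC/PAC columns. Across
leads, detections within a merge tolerance are clustered and voted:
majority first, ties broken by the PVC > PAC > Normal hierarchy (an
``any_pvc_wins`` switch makes the hierarchy override the majority).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ProbMask
from .records import NORMAL, PAC, PVC

__all__ = ["BeatDetection", "PostprocessConfig", "beats_from_mask", "merge_leads"]

_PRIORITY = {PVC: 2, PAC: 1, NORMAL: 0}


@dataclass
class BeatDetection:
    """One post-processed beat: location, class, confidence, source region."""

    index: int
    label: int
    confidence: float
    region: tuple[int, int]

    def __post_init__(self) -> None:
        start, end = self.region
        if not start <= self.index < end:
            raise ValueError("beat index must lie inside its region")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


@dataclass(frozen=True)
class PostprocessConfig:
    qrs_threshold: float = 0.9
    min_duration_ms: float = 40.0
    merge_tolerance_ms: float = 150.0
    any_pvc_wins: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.qrs_threshold < 1.0:
            raise ValueError("qrs_threshold must be in (0, 1)")
        if self.min_duration_ms <= 0 or self.merge_tolerance_ms <= 0:
            raise ValueError("durations must be positive")


def beats_from_mask(
    prob: ProbMask, config: PostprocessConfig = PostprocessConfig()
) -> list[BeatDetection]:
    """Extract beat detections from an L x C probability mask."""
    probs = prob.probs
    qrs = 1.0 - probs[:, 0]
    above = qrs > config.qrs_threshold
    min_len = max(int(round(config.min_duration_ms * prob.fs / 1000.0)), 1)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    detections: list[BeatDetection] = []
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start < min_len:
            continue
        means = probs[start:end, 1:4].mean(axis=0)
        label = int(np.argmax(means)) + 1
        index = (start + end - 1) // 2
        detections.append(
            BeatDetection(
                index=int(index),
                label=label,
                confidence=float(min(means.max(), 1.0)),
                region=(int(start), int(end)),
            )
        )
    return detections


def _vote(labels: list[int], any_pvc_wins: bool) -> int:
    if any_pvc_wins and PVC in labels:
        return PVC
    counts = {c: labels.count(c) for c in set(labels)}
    best = max(counts.values())
    tied = [c for c, n in counts.items() if n == best]
    return max(tied, key=lambda c: _PRIORITY[c])


def merge_leads(
    per_lead: list[list[BeatDetection]],
    config: PostprocessConfig = PostprocessConfig(),
    fs: float = 125.0,
) -> list[BeatDetection]:
    """Cluster per-lead detections within the merge tolerance and vote.

    Each cluster emits one beat at the confidence-weighted mean index.
    Greedy left-to-right linkage: a detection joins the current cluster if
    it lies within the tolerance of the cluster's last member.
    """
    if not per_lead:
        raise ValueError("merge_leads needs at least one lead")
    if len(per_lead) == 1:
        return sorted(per_lead[0], key=lambda d: d.index)
    tol = config.merge_tolerance_ms * fs / 1000.0
    pool = sorted((d for lead in per_lead for d in lead), key=lambda d: d.index)
    merged: list[BeatDetection] = []
    cluster: list[BeatDetection] = []

    def emit(cluster: list[BeatDetection]) -> None:
        weights = np.array([max(d.confidence, 1e-9) for d in cluster])
        idx = int(round(np.average([d.index for d in cluster], weights=weights)))
        label = _vote([d.label for d in cluster], config.any_pvc_wins)
        start = min(d.region[0] for d in cluster)
        end = max(d.region[1] for d in cluster)
        idx = int(np.clip(idx, start, end - 1))
        merged.append(
            BeatDetection(
                index=idx,
                label=label,
                confidence=float(np.mean([d.confidence for d in cluster])),
                region=(start, end),
            )
        )

    for det in pool:
        if cluster and det.index - cluster[-1].index > tol:
            emit(cluster)
            cluster = []
        cluster.append(det)
    if cluster:
        emit(cluster)
    return merged
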