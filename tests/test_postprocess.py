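"""Mask-to-beat extraction vs a brute-force oracle; multi-lead voting."""

import numpy as np
import pytest

from ecgseg import (NORMAL, PAC, PVC, BeatDetection, PostprocessConfig,
                    ProbMask, beats_from_mask, merge_leads)

_PRIO = {PVC: 2, PAC: 1, NORMAL: 0}


def brute_force_beats(prob: ProbMask, config: PostprocessConfig):
    """Explicit sample-by-sample run scan (independent oracle)."""
    probs = prob.probs
    min_len = max(int(round(config.min_duration_ms * prob.fs / 1000.0)), 1)
    out = []
    start = None
    for i in range(len(probs) + 1):
        active = i < len(probs) and (1.0 - probs[i, 0]) > config.qrs_threshold
        if active and start is None:
            start = i
        elif not active and start is not None:
            if i - start >= min_len:
                means = probs[start:i, 1:4].mean(axis=0)
                label = int(np.argmax(means)) + 1
                out.append(((start, i), label, (start + i - 1) // 2))
            start = None
    return out


def _random_masks(n, rng, length=200):
    """Mix of unstructured rows and structured high-confidence runs."""
    masks = []
    for k in range(n):
        if k % 2 == 0:
            p = rng.dirichlet(np.ones(4) * 0.3, size=length)
        else:
            p = np.zeros((length, 4))
            p[:, 0] = 1.0
            pos = 5
            while pos < length - 20:
                width = int(rng.integers(2, 15))
                cls = int(rng.integers(1, 4))
                conf = rng.uniform(0.7, 1.0)
                p[pos : pos + width, 0] = 1 - conf
                p[pos : pos + width, cls] = conf
                pos += width + int(rng.integers(5, 30))
            p /= p.sum(axis=1, keepdims=True)
        masks.append(ProbMask(probs=p, fs=125.0))
    return masks


def test_all_background_mask_yields_no_beats():
    p = np.zeros((100, 4))
    p[:, 0] = 1.0
    assert beats_from_mask(ProbMask(probs=p, fs=125.0)) == []


def test_single_region_hand_case():
    p = np.zeros((100, 4))
    p[:, 0] = 1.0
    p[40:60] = [0.0, 0.2, 0.8, 0.0]
    dets = beats_from_mask(ProbMask(probs=p, fs=125.0))
    assert len(dets) == 1
    d = dets[0]
    assert d.label == PVC
    assert d.region == (40, 60)
    assert d.index == 49
    assert d.confidence == pytest.approx(0.8)


def test_short_run_filtered_by_min_duration():
    p = np.zeros((100, 4))
    p[:, 0] = 1.0
    p[40:42] = [0.0, 0.9, 0.05, 0.05]  # 2 samples = 16 ms < 40 ms
    assert beats_from_mask(ProbMask(probs=p, fs=125.0)) == []


def test_matches_brute_force_oracle_on_random_masks(rng):
    cfg = PostprocessConfig()
    for mask in _random_masks(300, rng):
        got = [(d.region, d.label, d.index) for d in beats_from_mask(mask, cfg)]
        assert got == brute_force_beats(mask, cfg)


def test_lower_threshold_grows_detected_support(rng):
    """Lowering the QRS threshold enlarges the above-threshold support:
    every region found at 0.9 lies inside a region found at the lower
    threshold (regions may merge, so the raw count is not monotone)."""
    for mask in _random_masks(40, rng):
        high = beats_from_mask(mask, PostprocessConfig(qrs_threshold=0.9))
        low = beats_from_mask(mask, PostprocessConfig(qrs_threshold=0.5))
        for d in high:
            assert any(r.region[0] <= d.region[0] and
                       d.region[1] <= r.region[1] for r in low)


def _det(index, label, conf=0.9, width=10):
    return BeatDetection(index=index, label=label, confidence=conf,
                         region=(index - width // 2, index + width // 2 + 1))


class TestMergeLeads:
    def test_single_lead_passthrough(self):
        dets = [_det(100, NORMAL), _det(200, PVC)]
        assert merge_leads([dets]) == dets

    def test_two_lead_tie_breaks_to_pvc(self):
        merged = merge_leads([[_det(1000, NORMAL)], [_det(1003, PVC)]])
        assert len(merged) == 1
        assert merged[0].label == PVC

    def test_majority_beats_hierarchy(self):
        leads = [[_det(500, NORMAL)], [_det(502, NORMAL)], [_det(498, PVC)]]
        merged = merge_leads(leads)
        assert len(merged) == 1
        assert merged[0].label == NORMAL

    def test_any_pvc_wins_switch(self):
        leads = [[_det(500, NORMAL)], [_det(502, NORMAL)], [_det(498, PVC)]]
        merged = merge_leads(leads, PostprocessConfig(any_pvc_wins=True))
        assert merged[0].label == PVC

    def test_distant_beats_stay_separate(self):
        merged = merge_leads([[_det(100, NORMAL)], [_det(400, PAC)]])
        assert [d.label for d in merged] == [NORMAL, PAC]

    def test_idempotent_on_own_output(self):
        leads = [[_det(100, NORMAL), _det(300, PVC)],
                 [_det(103, PAC), _det(301, PVC)]]
        once = merge_leads(leads)
        twice = merge_leads([once, once])
        assert [(d.index, d.label) for d in once] == \
               [(d.index, d.label) for d in twice]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_leads([])


def test_config_validation():
    with pytest.raises(ValueError):
        PostprocessConfig(qrs_threshold=1.5)
    with pytest.raises(ValueError):
        PostprocessConfig(min_duration_ms=0)
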