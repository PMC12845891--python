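"""Tolerance matching, metric arithmetic, and bootstrap behavior."""

import inspect

import numpy as np
import pytest

from ecgseg import (NORMAL, PAC, PVC, BeatAnnotation, MatchResult,
                    bootstrap_report, compute_metrics, match_beats,
                    pool_matches)


def _ann(index, label=NORMAL):
    return BeatAnnotation(index=index, label=label)


class TestMatchBeats:
    def test_offset_within_tolerance_matches(self):
        m = match_beats([_ann(1000)], [_ann(1005)], fs=125.0, tol_ms=75.0,
                        record_length=2500)
        assert m.counts["QRS"] == (1, 0, 0)
        assert m.counts["NORMAL"] == (1, 0, 0)

    def test_missed_beat_is_fn(self):
        m = match_beats([_ann(1000)], [], fs=125.0, record_length=2500)
        assert m.counts["QRS"] == (0, 0, 1)

    def test_edge_references_are_excluded(self):
        # first/last 0.2 s (25 samples at 125 Hz) are disregarded
        m = match_beats([_ann(10)], [], fs=125.0, record_length=2500)
        assert m.counts["QRS"] == (0, 0, 0)
        m2 = match_beats([_ann(2490)], [], fs=125.0, record_length=2500)
        assert m2.counts["QRS"] == (0, 0, 0)

    def test_class_mismatch_counts_both_ways(self):
        m = match_beats([_ann(1000, NORMAL)], [_ann(1002, PVC)], fs=125.0,
                        record_length=2500)
        assert m.counts["QRS"] == (1, 0, 0)
        assert m.counts["NORMAL"] == (0, 0, 1)
        assert m.counts["PVC"] == (0, 1, 0)

    def test_beyond_tolerance_is_fp_and_fn(self):
        # 100 samples = 800 ms >> 75 ms
        m = match_beats([_ann(1000)], [_ann(1100)], fs=125.0,
                        record_length=2500)
        assert m.counts["QRS"] == (0, 1, 1)

    def test_matching_invariant_under_global_shift(self):
        refs = [_ann(i, PVC) for i in (300, 600, 900)]
        preds = [_ann(i + 4, PVC) for i in (300, 600, 905)]
        m1 = match_beats(refs, preds, fs=125.0)
        shift = 1000
        m2 = match_beats([_ann(r.index + shift, r.label) for r in refs],
                         [_ann(p.index + shift, p.label) for p in preds],
                         fs=125.0)
        assert m1.counts == m2.counts

    def test_tolerance_monotonicity(self, rng):
        refs = [_ann(int(i)) for i in sorted(rng.integers(100, 5000, 20))]
        preds = [_ann(int(i)) for i in sorted(rng.integers(100, 5000, 20))]
        tps = [match_beats(refs, preds, fs=125.0, tol_ms=t).counts["QRS"][0]
               for t in (30, 75, 150)]
        assert tps[0] <= tps[1] <= tps[2]

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_beats([], [], fs=125.0, tol_ms=-1)

    def test_greedy_equals_exhaustive_when_spaced(self, rng):
        """With inter-beat spacing > 2x tolerance the greedy matcher is
        optimal; verify against exhaustive one-to-one assignment."""
        fs, tol_ms = 125.0, 75.0
        tol = tol_ms * fs / 1000.0

        def exhaustive_tp(refs, preds):
            """Optimal one-to-one matching via the assignment problem."""
            from scipy.optimize import linear_sum_assignment

            if not refs or not preds:
                return 0
            feasible = np.array(
                [[abs(r.index - p.index) <= tol for p in preds] for r in refs]
            )
            rows, cols = linear_sum_assignment(-feasible.astype(float))
            return int(feasible[rows, cols].sum())

        for trial in range(50):
            # beats spaced > 2x tolerance apart
            base = np.cumsum(rng.integers(int(2.2 * tol), 400,
                                          size=rng.integers(2, 10))) + 200
            refs = [_ann(int(i)) for i in base]
            preds = []
            for i in base:
                if rng.uniform() < 0.8:
                    preds.append(_ann(int(i + rng.integers(-12, 13))))
            if rng.uniform() < 0.4:
                preds.append(_ann(int(base[-1] + 500)))
            got = match_beats(refs, preds, fs=fs, tol_ms=tol_ms).counts["QRS"][0]
            assert got == exhaustive_tp(refs, preds)


class TestComputeMetrics:
    def _result(self, **counts):
        base = {k: (0, 0, 0) for k in ("NORMAL", "PVC", "PAC", "QRS")}
        base.update(counts)
        return MatchResult(counts=base)

    def test_direct_arithmetic(self):
        rep = compute_metrics(self._result(QRS=(9, 1, 1)))
        m = rep.metrics["QRS"]
        assert m["Pr"] == pytest.approx(0.9)
        assert m["Se"] == pytest.approx(0.9)
        assert m["F1"] == pytest.approx(0.9)

    def test_undefined_precision_reported_absent(self):
        rep = compute_metrics(self._result(PVC=(0, 0, 5)))
        assert rep.metrics["PVC"]["Se"] == 0.0
        assert rep.metrics["PVC"]["Pr"] is None
        assert rep.metrics["PVC"]["F1"] is None

    def test_perfect_detection(self):
        rep = compute_metrics(self._result(QRS=(10, 0, 0), NORMAL=(10, 0, 0)))
        assert rep.metrics["QRS"] == {"Se": 1.0, "Pr": 1.0, "F1": 1.0,
                                      "TP": 10, "FP": 0, "FN": 0}

    def test_support_weighted_average(self):
        rep = compute_metrics(
            self._result(NORMAL=(8, 0, 2), PVC=(1, 0, 1))  # Se 0.8 and 0.5
        )
        # weights 10 and 2
        assert rep.weighted["Se"] == pytest.approx((10 * 0.8 + 2 * 0.5) / 12)


class TestBootstrap:
    def _per_record(self, n=6, identical=True, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            if identical:
                qrs, pvc = (20, 1, 2), (5, 1, 1)
            else:
                qrs = (int(rng.integers(15, 25)), int(rng.integers(0, 3)),
                       int(rng.integers(0, 4)))
                pvc = (int(rng.integers(2, 8)), int(rng.integers(0, 2)),
                       int(rng.integers(0, 2)))
            counts = {"NORMAL": qrs, "PVC": pvc, "PAC": (0, 0, 0), "QRS": qrs}
            out.append(MatchResult(counts=counts))
        return out

    def test_identical_records_give_zero_width_intervals(self):
        rep = bootstrap_report(self._per_record(identical=True), n_iter=200,
                               seed=0)
        for key, entry in rep.bootstrap.items():
            lo, hi = entry["ci"]
            assert lo == hi == entry["mean"]
            assert entry["sd"] == 0.0

    def test_default_iteration_count_is_1000(self):
        sig = inspect.signature(bootstrap_report)
        assert sig.parameters["n_iter"].default == 1000

    def test_interval_brackets_point_estimate(self):
        rep = bootstrap_report(self._per_record(identical=False, seed=3),
                               n_iter=300, seed=1)
        assert rep.bootstrap  # non-empty
        for entry in rep.bootstrap.values():
            lo, hi = entry["ci"]
            assert lo <= entry["point"] <= hi

    def test_absent_class_has_no_bootstrap_metrics(self):
        rep = bootstrap_report(self._per_record(identical=True), n_iter=100,
                               seed=0)
        assert not any(k.startswith("PAC") for k in rep.bootstrap)

    def test_requires_two_records(self):
        with pytest.raises(ValueError):
            bootstrap_report(self._per_record(n=1), n_iter=10)


def test_pool_matches_sums_counts():
    a = MatchResult(counts={"QRS": (1, 2, 3), "NORMAL": (1, 0, 0),
                            "PVC": (0, 0, 0), "PAC": (0, 0, 0)})
    pooled = pool_matches([a, a])
    assert pooled.counts["QRS"] == (2, 4, 6)
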