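"""Beat-level scoring: tolerance matching, Se/Pr/F1, BCa bootstrap.

A predicted beat matches a reference when it falls within the matching
tolerance (default half-width 75 ms, i.e. a 150 ms interval centered on
the reference; the half-width is configurable because a 150 ms half-width
reading is also defensible). Matching is one-to-one greedy nearest-first.
Reference annotations in the first or last 0.2 s of a recording are
disregarded, as are predictions in those edge zones. QRS-level metrics
count matches of any class; per-class metrics require the classes to
agree. Sensitivity Se = TP/(TP+FN), precision Pr = TP/(TP+FP),
F1 = 2*Pr*Se/(Pr+Se); 0/0 is reported as absent, not as zero.

Confidence intervals come from a nonparametric bootstrap over records
(default 1000 iterations) with bias-corrected and accelerated (BCa)
intervals via :func:`scipy.stats.bootstrap`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .records import CLASS_NAMES, NORMAL, PAC, PVC

__all__ = ["MatchResult", "EvalReport", "match_beats", "compute_metrics",
           "bootstrap_report", "pool_matches"]

_CLASSES = (NORMAL, PVC, PAC)
_KEYS = tuple(CLASS_NAMES[c] for c in _CLASSES) + ("QRS",)


@dataclass
class MatchResult:
    """TP/FP/FN counts per class and for QRS-overall, plus matched pairs."""

    counts: dict[str, tuple[int, int, int]]  # key -> (TP, FP, FN)
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        counts = {
            k: tuple(a + b for a, b in zip(self.counts[k], other.counts[k]))
            for k in self.counts
        }
        return MatchResult(counts=counts, pairs=self.pairs + other.pairs)


@dataclass
class EvalReport:
    """Se/Pr/F1 per class and QRS; optionally bootstrap mean/CI/SD."""

    metrics: dict[str, dict[str, float | None]]
    weighted: dict[str, float | None] = field(default_factory=dict)
    bootstrap: dict[str, dict] = field(default_factory=dict)


def match_beats(
    ref,
    pred,
    fs: float,
    tol_ms: float = 75.0,
    edge_exclude_s: float = 0.2,
    record_length: int | None = None,
    exclude_pred_edges: bool = True,
) -> MatchResult:
    """One-to-one greedy nearest matching of predictions to references.

    ``tol_ms`` is the half-width of the acceptance interval around each
    reference. ``ref``/``pred`` are sequences with ``.index``/``.label``.
    """
    if tol_ms < 0:
        raise ValueError("tolerance must be non-negative")
    lo = edge_exclude_s * fs
    hi = (record_length - lo) if record_length is not None else np.inf
    refs = [r for r in ref if lo <= r.index < hi]
    preds = list(pred)
    if exclude_pred_edges:
        preds = [p for p in preds if lo <= p.index < hi]
    tol = tol_ms * fs / 1000.0

    candidates = []
    for i, r in enumerate(refs):
        for j, p in enumerate(preds):
            d = abs(r.index - p.index)
            if d <= tol:
                candidates.append((d, i, j))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    ref_used = [False] * len(refs)
    pred_used = [False] * len(preds)
    pairs: list[tuple[int, int]] = []
    for _d, i, j in candidates:
        if not ref_used[i] and not pred_used[j]:
            ref_used[i] = pred_used[j] = True
            pairs.append((i, j))

    counts: dict[str, tuple[int, int, int]] = {}
    tp_any = len(pairs)
    counts["QRS"] = (tp_any, len(preds) - tp_any, len(refs) - tp_any)
    for c in _CLASSES:
        name = CLASS_NAMES[c]
        tp = sum(1 for i, j in pairs if refs[i].label == c and preds[j].label == c)
        n_ref = sum(1 for r in refs if r.label == c)
        n_pred = sum(1 for p in preds if p.label == c)
        counts[name] = (tp, n_pred - tp, n_ref - tp)
    return MatchResult(
        counts=counts,
        pairs=[(refs[i].index, preds[j].index) for i, j in pairs],
    )


def pool_matches(results: list[MatchResult]) -> MatchResult:
    """Sum counts across records (micro pooling)."""
    if not results:
        raise ValueError("no match results to pool")
    out = results[0]
    for r in results[1:]:
        out = out + r
    return out


def _sepr(tp: float, fp: float, fn: float) -> dict[str, float | None]:
    se = tp / (tp + fn) if tp + fn > 0 else None
    pr = tp / (tp + fp) if tp + fp > 0 else None
    if se is not None and pr is not None and se + pr > 0:
        f1 = 2 * pr * se / (pr + se)
    elif se is not None and pr is not None:
        f1 = 0.0
    else:
        f1 = None
    return {"Se": se, "Pr": pr, "F1": f1, "TP": tp, "FP": fp, "FN": fn}


def compute_metrics(m: MatchResult) -> EvalReport:
    """Se/Pr/F1 from counts; support-weighted averages over the beat classes."""
    metrics = {k: _sepr(*m.counts[k]) for k in _KEYS}
    weighted: dict[str, float | None] = {}
    for stat in ("Se", "Pr", "F1"):
        num = den = 0.0
        for c in _CLASSES:
            name = CLASS_NAMES[c]
            support = m.counts[name][0] + m.counts[name][2]  # TP + FN
            v = metrics[name][stat]
            if support > 0 and v is not None:
                num += support * v
                den += support
        weighted[stat] = num / den if den > 0 else None
    return EvalReport(metrics=metrics, weighted=weighted)


def bootstrap_report(
    per_record: list[MatchResult],
    n_iter: int = 1000,
    method: str = "BCa",
    seed: int = 0,
) -> EvalReport:
    """Bootstrap records with replacement; recompute pooled metrics per
    replicate; report mean, 95% CI (BCa) and SD alongside the point
    estimates. Metrics for a class absent from every record are absent."""
    if len(per_record) < 2:
        raise ValueError("bootstrap needs at least two records")
    pooled = pool_matches(per_record)
    report = compute_metrics(pooled)
    arr = {
        k: np.array([r.counts[k] for r in per_record], dtype=float)
        for k in _KEYS
    }  # each (n_records, 3)
    rng = np.random.default_rng(seed)
    n = len(per_record)

    for key in _KEYS:
        tpfpfn = arr[key]
        if tpfpfn[:, 0].sum() + tpfpfn[:, 2].sum() == 0:
            continue  # class absent everywhere
        for stat in ("Se", "Pr", "F1"):
            def statistic(indices, key=key, stat=stat):
                c = arr[key][np.asarray(indices, dtype=int)].sum(axis=0)
                v = _sepr(*c)[stat]
                return np.nan if v is None else v
            reps = np.array(
                [statistic(rng.integers(0, n, size=n)) for _ in range(n_iter)]
            )
            reps = reps[np.isfinite(reps)]
            if reps.size == 0:
                continue
            point = statistic(np.arange(n))
            mean_val = float(np.mean(reps))
            sd_val = float(np.std(reps, ddof=1)) if reps.size > 1 else 0.0
            if np.ptp(reps) == 0:
                lo = hi = mean_val = float(reps[0])
                sd_val = 0.0
            else:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = scipy.stats.bootstrap(
                            (np.arange(n),),
                            statistic,
                            vectorized=False,
                            n_resamples=n_iter,
                            method=method,
                            confidence_level=0.95,
                            random_state=np.random.default_rng(seed + 1),
                        )
                    lo = float(res.confidence_interval.low)
                    hi = float(res.confidence_interval.high)
                    if not (np.isfinite(lo) and np.isfinite(hi)):
                        raise ValueError("non-finite BCa interval")
                except Exception:
                    lo, hi = np.percentile(reps, [2.5, 97.5])
            report.bootstrap[f"{key}_{stat}"] = {
                "mean": mean_val,
                "ci": (float(lo), float(hi)),
                "sd": sd_val,
                "point": None if np.isnan(point) else float(point),
                "n_iter": n_iter,
            }
    return report
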