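"""Individual-level agreement between polygenic score sets.

Two scores can rank a cohort very differently while achieving the same AUC;
this module quantifies that with pairwise Pearson correlations and the
percentage of individuals that land in the same extreme quintile (lowest =
low risk, highest = high risk) under both scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class QuintileAssignment:
    """Per-sample quintile labels 1..5 (1 = lowest scores)."""

    labels: np.ndarray
    group_sizes: np.ndarray
    nominal_size: int

    def tail(self, which: int) -> np.ndarray:
        if which not in (1, 5):
            raise ValueError("tail must be 1 or 5")
        return np.flatnonzero(self.labels == which)


@dataclass
class ConsistencyResult:
    label_a: str
    label_b: str
    pearson_r: float
    overlap_q1_pct: float
    overlap_q5_pct: float

    def to_row(self) -> dict:
        return {
            "score_a": self.label_a,
            "score_b": self.label_b,
            "pearson_r": self.pearson_r,
            "overlap_q1_pct": self.overlap_q1_pct,
            "overlap_q5_pct": self.overlap_q5_pct,
        }


def pearson(scores_a: np.ndarray, scores_b: np.ndarray) -> float:
    """Sample Pearson correlation of two equally indexed score vectors."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must share samples")
    if len(a) < 3:
        raise ValueError("need at least 3 samples")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant score vector")
    return float(np.corrcoef(a, b)[0, 1])


def quintile_assign(scores: np.ndarray, sample_ids=None) -> QuintileAssignment:
    """Split samples into 5 consecutive rank groups of near-equal size.

    Samples are ranked ascending (ties broken stably by sample-ID order); the
    sample of 0-based rank r goes to group floor(r*5/N) + 1. The nominal
    per-quintile size N/5 is reported with banker's rounding.
    """
    s = np.asarray(scores, dtype=float)
    n = len(s)
    if n < 5:
        raise ValueError("need at least 5 samples for quintiles")
    ids = np.arange(n) if sample_ids is None else np.asarray(sample_ids)
    order = np.lexsort((ids, s))  # ascending score, stable by ID
    labels = np.empty(n, dtype=int)
    ranks = np.arange(n)
    labels[order] = ranks * 5 // n + 1
    sizes = np.bincount(labels, minlength=6)[1:]
    return QuintileAssignment(
        labels=labels,
        group_sizes=sizes,
        nominal_size=round(n / 5),  # Python round: half-to-even
    )


def tail_overlap(assign_a: QuintileAssignment, assign_b: QuintileAssignment, tail: int) -> float:
    """100 * |tail_a intersect tail_b| / |tail_a| for the chosen tail (1 or 5)."""
    if len(assign_a.labels) != len(assign_b.labels):
        raise ValueError("assignments cover different sample universes")
    ta = set(assign_a.tail(tail).tolist())
    tb = set(assign_b.tail(tail).tolist())
    if not ta:
        raise ValueError("empty tail")
    return 100.0 * len(ta & tb) / len(ta)


def compare_pair(scores_a, scores_b, label_a="a", label_b="b", sample_ids=None) -> ConsistencyResult:
    qa = quintile_assign(scores_a, sample_ids)
    qb = quintile_assign(scores_b, sample_ids)
    return ConsistencyResult(
        label_a=label_a,
        label_b=label_b,
        pearson_r=pearson(scores_a, scores_b),
        overlap_q1_pct=tail_overlap(qa, qb, 1),
        overlap_q5_pct=tail_overlap(qa, qb, 5),
    )


def consistency_matrix(scoresets, pairs="all", sample_ids=None) -> list[ConsistencyResult]:
    """Pairwise consistency over a list of (label, values) score sets.

    ``scoresets`` may be ScoreSet objects (label taken from provenance) or
    (label, values) tuples. ``pairs`` is "all" or an explicit list of
    (index_a, index_b) pairs.
    """
    entries = []
    for s in scoresets:
        if hasattr(s, "values") and hasattr(s, "label"):
            entries.append((s.label, np.asarray(s.values, dtype=float)))
        else:
            label, vals = s
            entries.append((str(label), np.asarray(vals, dtype=float)))
    n0 = {len(v) for _, v in entries}
    if len(n0) > 1:
        raise ValueError("score sets cover different numbers of samples")
    if pairs == "all":
        pair_list = list(combinations(range(len(entries)), 2))
    else:
        pair_list = list(pairs)
    out = []
    for i, j in pair_list:
        la, va = entries[i]
        lb, vb = entries[j]
        out.append(compare_pair(va, vb, la, lb, sample_ids))
    return out


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
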