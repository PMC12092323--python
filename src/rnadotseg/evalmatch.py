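"""Scoring of predicted dot coordinates against ground truth.

Predictions and ground truth are matched one-to-one within a Euclidean pixel
tolerance (default 5, the protocol used for expert inter-rater agreement);
matching is maximum-cardinality optimal assignment, so the score does not
depend on point ordering.  Precision, recall and F1 follow from the matched
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["MatchConfig", "MatchReport", "match_dots", "aggregate_reports"]


@dataclass
class MatchConfig:
    tolerance: float = 5.0
    method: str = "optimal"   # optimal | greedy (greedy for sensitivity checks)

    def __post_init__(self):
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.method not in ("optimal", "greedy"):
            raise ValueError(f"unknown matching method {self.method!r}")


@dataclass
class MatchReport:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]] = field(default_factory=list)
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "pairs": [list(p) for p in self.pairs],
                "precision": self.precision, "recall": self.recall, "f1": self.f1}


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    if tp == fp == fn == 0:
        # perfect agreement on absence
        return 1.0, 1.0, 1.0
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _report(tp: int, n_pred: int, n_gt: int, pairs) -> MatchReport:
    fp, fn = n_pred - tp, n_gt - tp
    p, r, f1 = _prf(tp, fp, fn)
    return MatchReport(tp=tp, fp=fp, fn=fn, pairs=list(pairs),
                       precision=p, recall=r, f1=f1)


def match_dots(pred, gt, tolerance: float = 5.0,
               method: str = "optimal") -> MatchReport:
    """One-to-one matching of predicted to ground-truth coordinates.

    A pair counts as a true positive iff its Euclidean distance is <= the
    tolerance (inclusive).  'optimal' computes a maximum-cardinality
    assignment; 'greedy' pairs nearest-first and can under-count.
    """
    pred = [tuple(map(float, p)) for p in pred]
    gt = [tuple(map(float, g)) for g in gt]
    if not pred or not gt:
        return _report(0, len(pred), len(gt), [])

    pa = np.asarray(pred)
    ga = np.asarray(gt)
    dist = np.hypot(pa[:, None, 0] - ga[None, :, 0], pa[:, None, 1] - ga[None, :, 1])
    feasible = dist <= tolerance

    if method == "greedy":
        order = np.argsort(dist, axis=None)
        used_p: set[int] = set()
        used_g: set[int] = set()
        pairs = []
        for flat in order:
            i, j = np.unravel_index(flat, dist.shape)
            if not feasible[i, j]:
                break
            if i in used_p or j in used_g:
                continue
            used_p.add(int(i))
            used_g.add(int(j))
            pairs.append((int(i), int(j)))
        return _report(len(pairs), len(pred), len(gt), sorted(pairs))

    # optimal: large constant cost on infeasible edges makes the minimum-cost
    # assignment maximise the number of within-tolerance pairs
    big = tolerance * (len(pred) + len(gt) + 1) + 1.0
    cost = np.where(feasible, dist, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j]]
    return _report(len(pairs), len(pred), len(gt), sorted(pairs))


def aggregate_reports(reports: list[MatchReport]) -> MatchReport:
    """Micro-aggregation over patches: sum TP/FP/FN, recompute P/R/F1."""
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report to aggregate")
    tp = sum(r.tp for r in reports)
    fp = sum(r.fp for r in reports)
    fn = sum(r.fn for r in reports)
    p, r, f1 = _prf(tp, fp, fn)
    return MatchReport(tp=tp, fp=fp, fn=fn, pairs=[], precision=p, recall=r, f1=f1)
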