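"""Call-set scoring: precision/recall/F1 and window-level AUC.

Matching is a documented simplification of standard SV benchmarking:
a call matches a truth deletion iff their starts are within
``max_breakpoint_distance`` (default 500 bp) and the smaller size is at
least ``min_size_similarity`` (default 0.7) of the larger.  Pairs are
assigned greedily by ascending breakpoint distance, one-to-one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass
class MatchCriteria:
    max_breakpoint_distance: int = 500
    min_size_similarity: float = 0.7

    def __post_init__(self):
        if self.max_breakpoint_distance < 0:
            raise ValueError("max_breakpoint_distance must be >= 0")
        if not 0.0 < self.min_size_similarity <= 1.0:
            raise ValueError("min_size_similarity must be in (0, 1]")

    def matches(self, call, truth) -> bool:
        if call.contig != truth.contig:
            return False
        if abs(call.start - truth.start) > self.max_breakpoint_distance:
            return False
        lo, hi = sorted((call.size, truth.size))
        return lo / hi >= self.min_size_similarity


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    matches: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1}


def match_calls(calls: Sequence, truths: Sequence,
                criteria: MatchCriteria | None = None) -> EvalReport:
    """Greedy one-to-one matching by ascending breakpoint distance.

    ``calls`` and ``truths`` need ``contig``, ``start`` and ``size``
    attributes (DeletionCall and TruthDeletion both qualify).
    """
    criteria = criteria or MatchCriteria()
    pairs = []
    for ci, c in enumerate(calls):
        for ti, t in enumerate(truths):
            if criteria.matches(c, t):
                pairs.append((abs(c.start - t.start), ci, ti))
    pairs.sort()
    used_c, used_t = set(), set()
    matches = []
    for _, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        matches.append((ci, ti))
    tp = len(matches)
    fp = len(calls) - tp
    fn = len(truths) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return EvalReport(tp, fp, fn, precision, recall, f1, matches)


def window_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC with midrank tie handling.

    Raises if only one class is present (the metric is undefined).
    """
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("window_auc needs both a positive and a negative "
                         "label; got a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def breakpoint_accuracy(calls, truths, report: EvalReport,
                        max_start_error: int = 40,
                        max_size_error_frac: float = 0.10) -> dict:
    """Among matched pairs, the fraction with refined breakpoints within
    ``max_start_error`` bp and sizes within ``max_size_error_frac`` of truth."""
    if not report.matches:
        return {"n": 0, "start_within": 0.0, "size_within": 0.0,
                "both_within": 0.0}
    start_ok = size_ok = both = 0
    for ci, ti in report.matches:
        c, t = calls[ci], truths[ti]
        s_ok = abs(c.start - t.start) <= max_start_error
        z_ok = abs(c.size - t.size) <= max_size_error_frac * t.size
        start_ok += s_ok
        size_ok += z_ok
        both += s_ok and z_ok
    n = len(report.matches)
    return {"n": n, "start_within": start_ok / n, "size_within": size_ok / n,
            "both_within": both / n}


def write_report(report: EvalReport, calls, truths, out_json: str | Path,
                 out_tsv: str | Path | None = None) -> None:
    """JSON summary plus optional TSV of per-call match assignments."""
    Path(out_json).write_text(json.dumps(report.to_dict(), indent=1))
    if out_tsv is None:
        return
    matched = dict(report.matches)
    lines = ["call_index\tcontig\tstart\tsize\tmatched_truth_index\t"
             "truth_start\ttruth_size"]
    for ci, c in enumerate(calls):
        ti = matched.get(ci)
        if ti is None:
            lines.append(f"{ci}\t{c.contig}\t{c.start}\t{c.size}\t.\t.\t.")
        else:
            t = truths[ti]
            lines.append(f"{ci}\t{c.contig}\t{c.start}\t{c.size}\t{ti}\t"
                         f"{t.start}\t{t.size}")
    Path(out_tsv).write_text("\n".join(lines) + "\n")
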