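"""Evaluation metrics: detection precision/recall/f-measure against a truth
set, and phasing switch rate, mismatch rate and block N50."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .phasing import HaplotypeBlock

_UNMATCHABLE = 10**9


@dataclass
class Matching:
    pairs: List[Tuple[int, int]]  # (call index, truth index)
    n_calls: int
    n_truth: int
    tolerance: int

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return self.n_calls - self.tp

    @property
    def fn(self) -> int:
        return self.n_truth - self.tp


@dataclass
class DetectionReport:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f_measure: float
    match_tolerance: int


@dataclass
class PhasingReport:
    switch_rate: float
    mismatch_rate: float
    n50: int
    blocks: int
    switch_errors: int = 0
    mismatch_errors: int = 0
    switch_positions: int = 0
    mismatch_positions: int = 0


def _distance(call, truth) -> int:
    return max(abs(call.start - truth.start), abs(call.end - truth.end))


def match_calls(
    calls: Sequence, truth: Sequence, tolerance: int = 100, require_type: bool = True
) -> Matching:
    """Optimal 1-to-1 matching of calls to truth records.

    A pair is admissible when the types agree (if required) and both
    breakpoints lie within `tolerance` bases; among admissible assignments
    the total breakpoint distance is minimized, which also maximizes the
    number of matches (inadmissible pairings carry a prohibitive cost).
    """
    if not calls or not truth:
        return Matching([], len(calls), len(truth), tolerance)
    cost = np.full((len(calls), len(truth)), float(_UNMATCHABLE))
    for i, c in enumerate(calls):
        for j, t in enumerate(truth):
            if require_type and c.vtype != t.vtype:
                continue
            d = _distance(c, t)
            if d <= tolerance:
                cost[i, j] = d
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < _UNMATCHABLE]
    return Matching(pairs, len(calls), len(truth), tolerance)


def precision_recall_f(matching: Matching) -> DetectionReport:
    tp, fp, fn = matching.tp, matching.fp, matching.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return DetectionReport(tp, fp, fn, precision, recall, f, matching.tolerance)


# ---------------------------------------------------------------------------
# Phasing metrics

def switch_mismatch_rates(
    blocks: Sequence[HaplotypeBlock], truth_hap: Dict[str, int]
) -> Tuple[float, float, Dict[str, int]]:
    """Switch and mismatch error rates of phased blocks against truth.

    `truth_hap` maps variant id -> haplotype (0/1) carrying the alternate
    allele.  Within each block (>= 2 variants) the assignment is compared
    under the better global flip; isolated single-variant disagreements count
    as mismatch errors, persistent phase changes as switch errors.  Possible
    switch positions are (n-1) per block, possible mismatch positions n.
    """
    sw = mm = 0
    sw_pos = mm_pos = 0
    for b in blocks:
        if len(b) < 2:
            continue
        for vid in b.variant_ids:
            if vid not in truth_hap:
                raise KeyError(f"phased variant {vid} missing from truth haplotypes")
        # disagreement indicator under one flip choice; error classification
        # below is invariant to the global flip
        d = [b.alleles[vid] ^ (1 - truth_hap[vid]) for vid in b.variant_ids]
        changes = [d[i] ^ d[i + 1] for i in range(len(d) - 1)]
        i = 0
        while i < len(changes):
            if changes[i]:
                if i + 1 < len(changes) and changes[i + 1]:
                    mm += 1  # isolated flip of one variant
                    i += 2
                    continue
                sw += 1
            i += 1
        sw_pos += len(b) - 1
        mm_pos += len(b)
    counts = {
        "switch_errors": sw,
        "mismatch_errors": mm,
        "switch_positions": sw_pos,
        "mismatch_positions": mm_pos,
    }
    return (sw / sw_pos if sw_pos else 0.0, mm / mm_pos if mm_pos else 0.0, counts)


def block_n50(blocks: Sequence[HaplotypeBlock]) -> int:
    """N50 of block reference spans (last minus first variant position + 1)."""
    spans = sorted((b.span[1] - b.span[0] + 1 for b in blocks), reverse=True)
    if not spans:
        return 0
    total = sum(spans)
    cum = 0
    for s in spans:
        cum += s
        if 2 * cum >= total:
            return s
    return spans[-1]


def phasing_report(
    blocks: Sequence[HaplotypeBlock], truth_hap: Dict[str, int]
) -> PhasingReport:
    switch, mismatch, c = switch_mismatch_rates(blocks, truth_hap)
    return PhasingReport(
        switch_rate=switch,
        mismatch_rate=mismatch,
        n50=block_n50(blocks),
        blocks=len(blocks),
        switch_errors=c["switch_errors"],
        mismatch_errors=c["mismatch_errors"],
        switch_positions=c["switch_positions"],
        mismatch_positions=c["mismatch_positions"],
    )
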