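"""In-memory alignment store shared by all calling stages.

Parses a coordinate-sorted SAM/BAM once (via pysam) into per-read numpy
CIGAR-run arrays, or accepts the simulator's records directly, so that the
pileup, feature-extraction, breakpoint and phasing stages never re-parse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .simdata import OP_D, OP_I, OP_M, OP_S, SamRecord, _CODE_OF

_REF_CONSUMING = frozenset({0, 2, 3, 7, 8})  # M, D, N, =, X
_QRY_CONSUMING = frozenset({0, 1, 4, 7, 8})  # M, I, S, =, X


@dataclass
class Alignment:
    """One read's alignment as run arrays; `pos0` is the 0-based ref start."""

    name: str
    pos0: int
    ops: np.ndarray
    lens: np.ndarray
    seq: np.ndarray  # uint8 codes, 255 for unknown bases

    def __post_init__(self) -> None:
        ref_mask = (self.ops == OP_M) | (self.ops == OP_D)
        self.ref_end0 = self.pos0 + int(self.lens[ref_mask].sum())
        self.left_clip = int(self.lens[0]) if self.ops.size and self.ops[0] == OP_S else 0
        self.right_clip = int(self.lens[-1]) if self.ops.size > 1 and self.ops[-1] == OP_S else 0
        if self.ops.size == 1 and self.ops[0] == OP_S:
            self.right_clip = 0

    # --- derived run coordinates -------------------------------------------------
    def run_ref_starts(self) -> np.ndarray:
        adv = np.where(np.isin(self.ops, (OP_M, OP_D)), self.lens, 0)
        return self.pos0 + np.concatenate([[0], np.cumsum(adv)[:-1]])

    def run_query_starts(self) -> np.ndarray:
        adv = np.where(np.isin(self.ops, (OP_M, OP_I, OP_S)), self.lens, 0)
        return np.concatenate([[0], np.cumsum(adv)[:-1]])

    def overlaps(self, l0: int, r0: int) -> bool:
        return self.pos0 < r0 and self.ref_end0 > l0


def _expand(starts: np.ndarray, lens: np.ndarray) -> np.ndarray:
    """Concatenate arange(start, start+len) for each run."""
    lens = lens.astype(np.int64)
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, np.int64)
    offsets = np.repeat(np.cumsum(lens) - lens, lens)
    return np.repeat(starts, lens) + np.arange(total) - offsets


class AlnStore:
    """All alignments of one contig, sorted by position."""

    def __init__(self, alignments: Sequence[Alignment], ref_name: str, ref_len: int):
        self.alns = sorted(alignments, key=lambda a: (a.pos0, a.name))
        self.ref_name = ref_name
        self.ref_len = ref_len
        self._starts = np.array([a.pos0 for a in self.alns])
        self._max_span = max((a.ref_end0 - a.pos0 for a in self.alns), default=0)

    def __len__(self) -> int:
        return len(self.alns)

    def __iter__(self):
        return iter(self.alns)

    def overlapping(self, l0: int, r0: int) -> List[Alignment]:
        """Alignments whose reference span intersects [l0, r0) (0-based)."""
        lo = int(np.searchsorted(self._starts, l0 - self._max_span))
        hi = int(np.searchsorted(self._starts, r0, side="right"))
        return [a for a in self.alns[lo:hi] if a.overlaps(l0, r0)]

    @classmethod
    def from_records(cls, records: Sequence[SamRecord], ref_name: str, ref_len: int) -> "AlnStore":
        alns = [
            Alignment(r.name, r.pos - 1, r.ops, r.lens, r.seq) for r in records
        ]
        return cls(alns, ref_name, ref_len)

    @classmethod
    def from_sam(cls, path: str, contig: Optional[str] = None) -> "AlnStore":
        alns: List[Alignment] = []
        last_pos = -1
        with pysam.AlignmentFile(path, check_sq=True) as sam:
            refs = list(sam.references)
            if contig is None:
                if len(refs) != 1:
                    raise ValueError(
                        f"SAM has {len(refs)} contigs; pass `contig` explicitly"
                    )
                contig = refs[0]
            if contig not in refs:
                raise ValueError(f"contig {contig!r} not in SAM header {refs}")
            ref_len = sam.get_reference_length(contig)
            for rec in sam:
                if rec.is_unmapped or rec.reference_name != contig:
                    if rec.reference_name not in refs and not rec.is_unmapped:
                        raise ValueError(f"read {rec.query_name} references unknown contig")
                    continue
                if rec.reference_start < last_pos:
                    raise ValueError("alignments are not coordinate-sorted")
                last_pos = rec.reference_start
                ct = rec.cigartuples or []
                ops = np.fromiter((o for o, _ in ct), np.uint8, len(ct))
                lens = np.fromiter((l for _, l in ct), np.int64, len(ct))
                seq = rec.query_sequence
                codes = (
                    _CODE_OF[np.frombuffer(seq.encode(), np.uint8)]
                    if seq
                    else np.empty(0, np.uint8)
                )
                alns.append(Alignment(rec.query_name, rec.reference_start, ops, lens, codes))
        return cls(alns, contig, ref_len)
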