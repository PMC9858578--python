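"""Breakpoint resolution from soft-clip clusters and insert-source tracing.

The start of a variant is estimated from reads soft-clipped at their right
end (the clip begins where the deleted span begins) and the end from reads
clipped at their left end; candidate positions go through Tukey-fence
outlier removal and are averaged.  Long CIGAR deletion runs from reads that
bridge the variant contribute candidates as well — at zero sequencing error
an aligner bridges confidently and leaves no clips, and the D-run boundaries
are then exact.

Inserted-fragment origins are traced by iteratively matching the clipped
sequences back to the reference with exact k-mer anchors: flank-matching
anchors (mapping back beside the variant) are peeled away and the remaining
fragment's best anchor away from the variant names the source locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .alignments import Alignment, AlnStore
from .density import CandidateRegion
from .simdata import OP_D, OP_S, decode, encode

LEFT_CLIP = "left_clip"
RIGHT_CLIP = "right_clip"


@dataclass
class SoftClipEvidence:
    read_name: str
    side: str  # left_clip | right_clip
    clip_len: int
    anchor_pos: int  # 1-based: first aligned base (left) / last aligned base (right)
    clipped_seq: str

    def __post_init__(self) -> None:
        if self.clip_len != len(self.clipped_seq) or self.clip_len < 1:
            raise ValueError("clip_len must equal len(clipped_seq) >= 1")
        if self.side not in (LEFT_CLIP, RIGHT_CLIP):
            raise ValueError(f"unknown side {self.side!r}")


@dataclass
class BreakpointEstimate:
    position: int
    support: int
    discarded: int
    low_confidence: bool = False


@dataclass
class InsertTrace:
    source_locus: Optional[int]
    matched_len: int
    iterations: int
    status: str  # placed | unplaced


def collect_softclips(
    store: AlnStore,
    region: CandidateRegion,
    side: str,
    min_clip: int = 50,
    pad: int = 50,
) -> List[SoftClipEvidence]:
    """Soft clips of the requested side anchored within region +- pad.

    Only clips strictly longer than `min_clip` qualify.
    """
    l0 = region.l - 1 - pad
    r0 = region.r + pad
    out: List[SoftClipEvidence] = []
    for a in store.overlapping(max(l0, 0), r0):
        if side == RIGHT_CLIP and a.right_clip > min_clip:
            anchor = a.ref_end0  # 1-based last aligned base
            if l0 < anchor <= r0:
                seq = decode(a.seq[a.seq.size - a.right_clip :])
                out.append(SoftClipEvidence(a.name, side, a.right_clip, anchor, seq))
        elif side == LEFT_CLIP and a.left_clip > min_clip:
            anchor = a.pos0 + 1  # 1-based first aligned base
            if l0 < anchor <= r0:
                seq = decode(a.seq[: a.left_clip])
                out.append(SoftClipEvidence(a.name, side, a.left_clip, anchor, seq))
    return out


def deletion_run_candidates(
    store: AlnStore,
    region: CandidateRegion,
    which: str,
    min_del_run: int = 100,
    pad: int = 50,
) -> List[int]:
    """Start/end candidates from long CIGAR deletion runs inside the region."""
    l0 = max(region.l - 1 - pad, 0)
    r0 = region.r + pad
    out: List[int] = []
    for a in store.overlapping(l0, r0):
        big = (a.ops == OP_D) & (a.lens >= min_del_run)
        if not big.any():
            continue
        rs = a.run_ref_starts()
        for s0, ln in zip(rs[big], a.lens[big]):
            if s0 >= l0 and s0 + ln <= r0:
                out.append(int(s0) + 1 if which == "start" else int(s0 + ln))
    return out


def tukey_filter(values: Sequence[float]) -> List[float]:
    """Drop values outside the 1.5*IQR Tukey fences (never drops everything)."""
    vals = list(values)
    if not vals:
        raise ValueError("tukey_filter requires at least one value")
    arr = np.asarray(vals, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    kept = [v for v in vals if lo <= v <= hi]
    return kept if kept else vals


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def locate_breakpoint(
    evidence: Sequence[SoftClipEvidence],
    which: str,
    extra_candidates: Sequence[int] = (),
    fallback: Optional[int] = None,
) -> BreakpointEstimate:
    """Mean of the outlier-filtered candidate set, rounded half-up.

    Right clips vote for `anchor + 1` (first deleted base) when locating a
    start; left clips vote for `anchor - 1` (last deleted base) when locating
    an end.  With no evidence at all, the density-scan region bound is
    returned flagged low-confidence.
    """
    if which not in ("start", "end"):
        raise ValueError("which must be 'start' or 'end'")
    want = RIGHT_CLIP if which == "start" else LEFT_CLIP
    cands: List[int] = []
    for ev in evidence:
        if ev.side != want:
            continue
        cands.append(ev.anchor_pos + 1 if which == "start" else ev.anchor_pos - 1)
    cands.extend(int(c) for c in extra_candidates)
    if not cands:
        if fallback is None:
            raise ValueError("no evidence and no fallback position")
        return BreakpointEstimate(fallback, 0, 0, low_confidence=True)
    kept = tukey_filter(cands)
    return BreakpointEstimate(
        _round_half_up(float(np.mean(kept))), len(kept), len(cands) - len(kept)
    )


# ---------------------------------------------------------------------------
# Exact-anchor alignment

@dataclass
class Anchor:
    ref_pos: int  # 1-based start on the reference
    query_pos: int  # 0-based start on the query
    run_len: int


class KmerIndex:
    """Sorted-array index of all reference k-mers (A/C/G/T encoded base-4)."""

    def __init__(self, ref_codes: np.ndarray, k: int = 13):
        if k < 4 or k > 15:
            raise ValueError("k must be in [4, 15]")
        self.k = k
        self.ref = ref_codes
        kmers = _encode_kmers(ref_codes, k)
        self.order = np.argsort(kmers, kind="stable")
        self.sorted = kmers[self.order]

    def hits(self, kmer: int) -> np.ndarray:
        lo = int(np.searchsorted(self.sorted, kmer, side="left"))
        hi = int(np.searchsorted(self.sorted, kmer, side="right"))
        return self.order[lo:hi]


def _encode_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, np.int64)
    out = np.zeros(n, np.int64)
    for j in range(k):
        out = out * 4 + codes[j : j + n].astype(np.int64)
    return out


_INDEX_CACHE: dict = {}


def _get_index(reference: Union[str, np.ndarray], k: int) -> Tuple[KmerIndex, np.ndarray]:
    import hashlib

    ref = encode(reference) if isinstance(reference, str) else reference
    key = (hashlib.md5(ref.tobytes()).hexdigest(), k)
    if key not in _INDEX_CACHE:
        if len(_INDEX_CACHE) > 4:
            _INDEX_CACHE.clear()
        _INDEX_CACHE[key] = (KmerIndex(ref, k), ref)
    return _INDEX_CACHE[key]


def anchor_align(
    query: Union[str, np.ndarray],
    reference: Union[str, np.ndarray],
    min_anchor: int = 50,
    k: int = 13,
    max_hits_per_kmer: int = 50,
) -> List[Anchor]:
    """Maximal exact-match runs (>= min_anchor) between query and reference.

    K-mer seeds are extended in both directions to maximal runs; duplicate
    discoveries of the same run are collapsed.  Results are sorted by
    descending run length (ties by reference position).
    """
    q = encode(query) if isinstance(query, str) else query
    if q.size < min(min_anchor, k):
        return []
    index, ref = _get_index(reference, k)
    qk = _encode_kmers(q, k)
    seen = set()
    anchors: List[Anchor] = []
    covered_until = 0
    for qpos in range(qk.size):
        if qpos + k <= covered_until:
            continue
        hits = index.hits(int(qk[qpos]))
        if hits.size == 0 or hits.size > max_hits_per_kmer:
            continue
        for rpos in hits:
            rpos = int(rpos)
            diag = rpos - qpos
            # extend left
            qs, rs = qpos, rpos
            while qs > 0 and rs > 0 and q[qs - 1] == ref[rs - 1]:
                qs -= 1
                rs -= 1
            if (diag, qs) in seen:
                continue
            # extend right
            qe, re_ = qpos + k, rpos + k
            while qe < q.size and re_ < ref.size and q[qe] == ref[re_]:
                qe += 1
                re_ += 1
            seen.add((diag, qs))
            run = qe - qs
            covered_until = max(covered_until, qe)
            if run >= min_anchor:
                anchors.append(Anchor(rs + 1, qs, run))
    anchors.sort(key=lambda a: (-a.run_len, a.ref_pos, a.query_pos))
    return anchors


# ---------------------------------------------------------------------------
# Insert-source tracing

def trace_insert_source(
    clips: Sequence[Union[SoftClipEvidence, str]],
    reference: Union[str, np.ndarray],
    region: Optional[CandidateRegion] = None,
    aligner: Optional[Callable[..., List[Anchor]]] = None,
    min_anchor: int = 20,
    k: int = 13,
    max_iterations: int = 3,
    max_seqs: int = 8,
    expected_ins_len: Optional[int] = None,
    fastq_path: Optional[str] = None,
) -> InsertTrace:
    """Locate the reference origin of an inserted fragment from clipped reads.

    Each clipped sequence is treated as an artificial read and matched to the
    reference; anchors that map back beside the variant (within a clip-length
    exclusion zone) are flank matches and are peeled off, re-queuing the
    still-unmatched portion for up to `max_iterations` rounds.  Anchors
    landing elsewhere vote for a source locus: right-side clips carry the
    insert at their head, so `ref_pos - query_pos` projects the insert start
    directly; left-side clips carry it at their tail and project its end.
    """
    if not clips:
        raise ValueError("trace_insert_source needs at least one clipped sequence")
    if aligner is None:
        aligner = anchor_align
    evs: List[SoftClipEvidence] = []
    for c in clips[:max_seqs]:
        if isinstance(c, str):
            evs.append(SoftClipEvidence("artificial", RIGHT_CLIP, len(c), 0, c))
        else:
            evs.append(c)
    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for i, ev in enumerate(evs):
                fh.write(f"@clip_{i}_{ev.read_name}\n{ev.clipped_seq}\n+\n{'I' * ev.clip_len}\n")

    # candidate source estimates: (estimate, run_len, query_offset, is_direct)
    cands: List[Tuple[int, int, int, bool]] = []
    iterations_used = 0
    for ev in evs:
        if region is not None:
            zone = (region.l - ev.clip_len, region.r + ev.clip_len)
        elif ev.anchor_pos > 0:
            zone = (ev.anchor_pos - ev.clip_len, ev.anchor_pos + ev.clip_len)
        else:
            zone = None
        frontier: List[Tuple[str, int]] = [(ev.clipped_seq, 0)]
        seen_frags = set()
        for it in range(max_iterations):
            if not frontier:
                break
            iterations_used = max(iterations_used, it + 1)
            nxt: List[Tuple[str, int]] = []
            for seq, off in frontier:
                if len(seq) < min_anchor or (seq, off) in seen_frags:
                    continue
                seen_frags.add((seq, off))
                anchors = aligner(seq, reference, min_anchor=min_anchor, k=k)
                if not anchors:
                    continue
                for an in anchors:
                    gq = off + an.query_pos
                    in_zone = zone is not None and zone[0] <= an.ref_pos <= zone[1]
                    if in_zone:
                        continue
                    if ev.side == RIGHT_CLIP:
                        est = an.ref_pos - gq
                        cands.append((est, an.run_len, gq, True))
                    elif expected_ins_len is not None:
                        tail = ev.clip_len - (gq + an.run_len)
                        est_end = an.ref_pos + an.run_len - 1 + tail
                        cands.append((est_end - expected_ins_len + 1, an.run_len, tail, False))
                top = anchors[0]
                pre, suf = seq[: top.query_pos], seq[top.query_pos + top.run_len :]
                if len(pre) >= min_anchor:
                    nxt.append((pre, off))
                if len(suf) >= min_anchor:
                    nxt.append((suf, off + top.query_pos + top.run_len))
            frontier = nxt

    direct = [c for c in cands if c[3]]
    pool = direct if direct else cands
    if not pool:
        return InsertTrace(None, 0, iterations_used, "unplaced")
    # cluster estimates within 100 bases; pick the cluster with most anchor mass
    pool.sort(key=lambda c: c[0])
    clusters: List[List[Tuple[int, int, int, bool]]] = [[pool[0]]]
    for c in pool[1:]:
        if c[0] - clusters[-1][-1][0] <= 100:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    best = max(clusters, key=lambda cl: (sum(c[1] for c in cl), -min(c[2] for c in cl)))
    winner = min(best, key=lambda c: (c[2], -c[1]))  # least query drift first
    matched = max(c[1] for c in best)
    return InsertTrace(int(winner[0]), int(matched), iterations_used, "placed")
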