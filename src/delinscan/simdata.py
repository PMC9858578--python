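"""Diploid-genome and CLR-read simulator with truth-derived alignments.

The simulator plants delins / insertions / deletions / SNVs on two haplotype
copies of a random reference, samples long reads at a configured depth with
an insertion/deletion-dominated error process, and then *projects* each read
back onto the reference coordinate system to produce a sorted SAM file — no
external aligner is involved, so the alignments are exact by construction.

Aligner behaviour around large novel inserts is emulated explicitly: a read
crossing a delins/insertion is either bridged (CIGAR I + D operations) or
soft-clipped on its shorter-anchor side, with a clip probability that scales
with the error rate (a noise-free alignment always bridges).  Reads that
begin or end inside an inserted fragment are always soft-clipped there, which
is what seeds the breakpoint clusters downstream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import SimConfig

# Base encoding: A,C,G,T -> 0..3
_BASE_CHARS = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i
    _CODE_OF[ord(chr(_b).lower())] = _i

# CIGAR op codes (SAM order)
OP_M, OP_I, OP_D, OP_S = 0, 1, 2, 4

MIN_READ_LEN = 200


def encode(seq: str) -> np.ndarray:
    codes = _CODE_OF[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def decode(codes: np.ndarray) -> str:
    return _BASE_CHARS[codes].tobytes().decode()


@dataclass
class TruthVariant:
    """A planted variant, in 1-based inclusive reference coordinates.

    ``end`` is the last deleted base; pure insertions use the convention
    ``end = start - 1`` (empty deletion span).
    """

    id: str
    vtype: str  # delins | insertion | deletion | snv
    haplotype: str  # "0" | "1" | "both"
    start: int
    end: int
    inserted_seq: str = ""
    insert_source: Optional[int] = None
    alt_base: str = ""  # SNV alternate base

    def __post_init__(self) -> None:
        if self.end < self.start - 1:
            raise ValueError(f"{self.id}: end {self.end} < start-1 {self.start - 1}")
        if self.vtype in ("delins", "insertion") and not self.inserted_seq:
            raise ValueError(f"{self.id}: {self.vtype} requires an inserted sequence")
        if self.vtype in ("deletion", "snv") and self.inserted_seq:
            raise ValueError(f"{self.id}: {self.vtype} must not carry an inserted sequence")

    @property
    def del_len(self) -> int:
        return self.end - self.start + 1

    def on_hap(self, hap: int) -> bool:
        return self.haplotype == "both" or self.haplotype == str(hap)


@dataclass
class SimulatedRead:
    name: str
    haplotype: int
    hap_start: int  # 0-based start on the haplotype sequence
    seq: np.ndarray  # uint8 base codes
    ops: np.ndarray  # CIGAR ops vs the haplotype (M/I/D)
    lens: np.ndarray

    @property
    def hap_span(self) -> int:
        return int(self.lens[(self.ops == OP_M) | (self.ops == OP_D)].sum())


@dataclass
class SamRecord:
    """One alignment line; coordinates are 1-based as in SAM."""

    name: str
    pos: int
    ops: np.ndarray
    lens: np.ndarray
    seq: np.ndarray
    haplotype: int = -1

    def cigar_string(self) -> str:
        return "".join(f"{l}{'MIDNSHP=X'[o]}" for o, l in zip(self.ops, self.lens))

    @property
    def ref_span(self) -> int:
        return int(self.lens[(self.ops == OP_M) | (self.ops == OP_D)].sum())


def _merge_runs(ops: np.ndarray, lens: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    keep = lens > 0
    ops, lens = ops[keep], lens[keep]
    if ops.size == 0:
        return ops, lens
    starts = np.concatenate([[0], np.flatnonzero(np.diff(ops)) + 1])
    return ops[starts], np.add.reduceat(lens, starts)


def generate_reference(length: int, seed: int) -> str:
    """Uniform i.i.d. A/C/G/T reference sequence of the given length."""
    if length <= 0:
        raise ValueError(f"reference length must be positive, got {length}")
    rng = np.random.default_rng(seed)
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Variant planting

_SV_MARGIN = 1500  # minimum spacing between SV intervals and from genome ends


def plant_variants(
    reference: str, config: SimConfig
) -> Tuple[str, str, List[TruthVariant]]:
    """Plant the configured variants; returns the two haplotypes and truth.

    Delins delete a span drawn from ``delins_len_range`` and insert a
    fragment of length uniform in [0.9, 1.1] x the deletion length, copied
    from a random reference locus (recorded as ``insert_source``).  Pure
    insertions copy a fragment the same way; pure deletions reuse the delins
    length range.  SVs are heterozygous (haplotype 0 or 1); SNVs land on
    haplotype 0, 1 or both.
    """
    ref = encode(reference)
    n = len(ref)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lo, hi = config.delins_len_range

    intervals: List[Tuple[int, int]] = []  # occupied (start0, end0_excl) incl. margin

    def _place(span: int, tries: int = 2000) -> int:
        """Pick a 0-based start for an SV of `span` ref bases, non-overlapping."""
        for _ in range(tries):
            s = int(rng.integers(_SV_MARGIN, n - span - _SV_MARGIN)) if n - span - 2 * _SV_MARGIN > 0 else -1
            if s < 0:
                break
            if all(s + span + _SV_MARGIN <= a or s - _SV_MARGIN >= b for a, b in intervals):
                intervals.append((s, s + span))
                return s
        raise RuntimeError(
            f"could not place an SV of {span} bases without overlap "
            f"(ref_length={n}, {len(intervals)} already placed)"
        )

    truth: List[TruthVariant] = []

    def _copy_fragment(length: int) -> Tuple[str, int]:
        src0 = int(rng.integers(0, n - length))
        return decode(ref[src0 : src0 + length]), src0 + 1

    for i in range(config.n_delins):
        dlen = int(rng.integers(lo, hi + 1))
        ilen = max(1, int(round(dlen * rng.uniform(0.9, 1.1))))
        s0 = _place(dlen)
        seq, src = _copy_fragment(ilen)
        truth.append(
            TruthVariant(
                id=f"delins_{i + 1}", vtype="delins", haplotype=str(rng.integers(2)),
                start=s0 + 1, end=s0 + dlen, inserted_seq=seq, insert_source=src,
            )
        )
    for i in range(config.n_ins):
        ilen = int(rng.integers(lo, hi + 1))
        s0 = _place(1)  # breakpoint site
        seq, src = _copy_fragment(ilen)
        truth.append(
            TruthVariant(
                id=f"ins_{i + 1}", vtype="insertion", haplotype=str(rng.integers(2)),
                start=s0 + 1, end=s0, inserted_seq=seq, insert_source=src,
            )
        )
    for i in range(config.n_del):
        dlen = int(rng.integers(lo, hi + 1))
        s0 = _place(dlen)
        truth.append(
            TruthVariant(
                id=f"del_{i + 1}", vtype="deletion", haplotype=str(rng.integers(2)),
                start=s0 + 1, end=s0 + dlen,
            )
        )

    if config.snv_rate > 0:
        mask = rng.random(n) < config.snv_rate
        # keep SNVs away from SV intervals so truth records stay independent
        for a, b in intervals:
            mask[max(0, a - 10) : min(n, b + 10)] = False
        positions = np.flatnonzero(mask)
        haps = rng.choice(["0", "1", "both"], size=positions.size, p=[0.45, 0.45, 0.10])
        shifts = rng.integers(1, 4, size=positions.size, dtype=np.uint8)
        for j, (p0, hp, sh) in enumerate(zip(positions, haps, shifts)):
            alt = decode(np.array([(ref[p0] + sh) % 4], dtype=np.uint8))
            truth.append(
                TruthVariant(
                    id=f"snv_{j + 1}", vtype="snv", haplotype=str(hp),
                    start=int(p0) + 1, end=int(p0) + 1, alt_base=alt,
                )
            )

    truth.sort(key=lambda v: (v.start, v.id))
    hap0 = _apply_variants(ref, truth, 0)
    hap1 = _apply_variants(ref, truth, 1)
    return decode(hap0), decode(hap1), truth


def _apply_variants(ref: np.ndarray, truth: Sequence[TruthVariant], hap: int) -> np.ndarray:
    base = ref.copy()
    for v in truth:
        if v.vtype == "snv" and v.on_hap(hap):
            base[v.start - 1] = encode(v.alt_base)[0]
    pieces: List[np.ndarray] = []
    cur = 0
    for v in truth:
        if v.vtype == "snv" or not v.on_hap(hap):
            continue
        pieces.append(base[cur : v.start - 1])
        if v.inserted_seq:
            pieces.append(encode(v.inserted_seq))
        cur = v.end  # skip deleted span (end is inclusive; end = start-1 keeps all)
    pieces.append(base[cur:])
    return np.concatenate(pieces)


# ---------------------------------------------------------------------------
# Haplotype -> reference segment map

@dataclass
class _MapSeg:
    kind: str  # "M" or "V"
    hap_lo: int  # 0-based inclusive
    hap_len: int
    ref_lo: int = -1  # 0-based ref start (M segments)
    var: Optional[TruthVariant] = None


def _hap_map(truth: Sequence[TruthVariant], hap: int, ref_len: int) -> List[_MapSeg]:
    segs: List[_MapSeg] = []
    ref_cur = 0
    hap_cur = 0
    for v in truth:
        if v.vtype == "snv" or not v.on_hap(hap):
            continue
        m_len = (v.start - 1) - ref_cur
        if m_len > 0:
            segs.append(_MapSeg("M", hap_cur, m_len, ref_cur))
            hap_cur += m_len
        segs.append(_MapSeg("V", hap_cur, len(v.inserted_seq), var=v))
        hap_cur += len(v.inserted_seq)
        ref_cur = v.end
    if ref_len - ref_cur > 0:
        segs.append(_MapSeg("M", hap_cur, ref_len - ref_cur, ref_cur))
    return segs


# ---------------------------------------------------------------------------
# Read simulation

def simulate_reads(
    haplotypes: Tuple[str, str], config: SimConfig, rng: Optional[np.random.Generator] = None
) -> List[SimulatedRead]:
    """Sample reads to the configured depth with per-base error injection.

    Lengths are Normal(read_len_mean, read_len_sd) truncated below at 200
    bases (shorter draws are resampled); starts are uniform with full
    containment; each read comes from either haplotype with probability 1/2.
    """
    if config.error_rate >= 0.5:
        raise ValueError("error_rate must be < 0.5")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    haps = [encode(h) for h in haplotypes]
    target = config.depth * config.ref_length
    mix = np.array(config.error_mix)
    reads: List[SimulatedRead] = []
    total = 0
    i = 0
    while total < target:
        hap_idx = int(rng.integers(2))
        hap = haps[hap_idx]
        length = 0
        while length < MIN_READ_LEN:
            length = int(round(rng.normal(config.read_len_mean, config.read_len_sd)))
        length = min(length, len(hap))
        start = int(rng.integers(0, len(hap) - length + 1))
        seq, ops, lens = _inject_errors(hap[start : start + length], config.error_rate, mix, rng)
        reads.append(SimulatedRead(f"read_{i + 1}", hap_idx, start, seq, ops, lens))
        total += len(seq)
        i += 1
    return reads


def _inject_errors(
    template: np.ndarray, error_rate: float, mix: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inject i.i.d. per-base errors; returns (seq, cigar ops, cigar lens).

    One event per selected template base: substitution replaces it, deletion
    drops it, insertion appends one random base after it.  The CIGAR is the
    read-vs-template alignment implied by the events.
    """
    L = template.size
    k = rng.binomial(L, error_rate) if error_rate > 0 else 0
    if k == 0:
        return template.copy(), np.array([OP_M], np.uint8), np.array([L], np.int64)
    pos = np.sort(rng.choice(L, size=k, replace=False))
    etype = rng.choice(3, size=k, p=mix)  # 0=ins 1=del 2=sub

    seq = template.copy()
    sub_pos = pos[etype == 2]
    seq[sub_pos] = (seq[sub_pos] + rng.integers(1, 4, size=sub_pos.size, dtype=np.uint8)) % 4
    del_pos = pos[etype == 1]
    ins_pos = pos[etype == 0]
    ins_bases = rng.integers(0, 4, size=ins_pos.size, dtype=np.uint8)
    kept = np.delete(seq, del_pos)
    # insertion goes after its template base; shift indices for removed bases
    ins_at = ins_pos + 1 - np.searchsorted(del_pos, ins_pos, side="right")
    seq = np.insert(kept, ins_at, ins_bases)

    struct = etype != 2
    spos, sop = pos[struct], np.where(etype[struct] == 0, OP_I, OP_D).astype(np.uint8)
    nev = spos.size
    if nev == 0:
        return seq, np.array([OP_M], np.uint8), np.array([L], np.int64)
    prev = np.concatenate([[0], spos[:-1] + 1])
    m_len = spos + (sop == OP_I) - prev  # ins events consume their base into the M run
    ops = np.empty(2 * nev + 1, np.uint8)
    lens = np.empty(2 * nev + 1, np.int64)
    ops[0::2] = OP_M
    lens[0::2][:nev] = m_len
    lens[-1] = L - (spos[-1] + 1)
    ops[1::2] = sop
    lens[1::2] = 1
    return seq, *_merge_runs(ops, lens)


# ---------------------------------------------------------------------------
# Truth-derived alignments

def emit_truth_alignments(
    reads: Sequence[SimulatedRead],
    reference: str,
    truth: Sequence[TruthVariant],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[SamRecord]:
    """Project reads onto the reference; returns records sorted by position."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    ref_len = len(reference)
    maps = [_hap_map(truth, h, ref_len) for h in (0, 1)]
    starts = [np.array([s.hap_lo for s in m]) for m in maps]
    clip_p = config.clip_prob * min(1.0, config.error_rate / 0.15)
    out: List[SamRecord] = []
    for read in reads:
        rec = _project_read(read, maps[read.haplotype], starts[read.haplotype], clip_p, rng)
        if rec is not None:
            out.append(rec)
    out.sort(key=lambda r: (r.pos, r.name))
    return out


def _project_read(
    read: SimulatedRead,
    segs: List[_MapSeg],
    seg_starts: np.ndarray,
    clip_p: float,
    rng: np.random.Generator,
) -> Optional[SamRecord]:
    a = read.hap_start
    H = read.hap_span
    qlen_expected = int(read.lens[(read.ops == OP_M) | (read.ops == OP_I)].sum())
    if qlen_expected != read.seq.size:
        raise ValueError(f"{read.name}: edit trace inconsistent with sequence length")

    # Fast path: entire read inside one M segment.
    si = int(np.searchsorted(seg_starts, a, side="right")) - 1
    seg = segs[si]
    if seg.kind == "M" and a + H <= seg.hap_lo + seg.hap_len:
        pos = seg.ref_lo + (a - seg.hap_lo)
        return _finalize(read, pos, list(zip(read.ops.tolist(), read.lens.tolist())), rng, clip_p)

    # General path: walk runs against map segments.
    items: List[Tuple] = []  # ("op", op, len) | ("var", var, qlen)
    first_ref = -1
    ri, consumed = 0, 0  # run index, hap consumed within current run
    hap_pos = a
    ops_l, lens_l = read.ops.tolist(), read.lens.tolist()

    def _take(amount: int) -> List[Tuple[int, int]]:
        """Consume `amount` hap bases from the run stream, returning runs."""
        nonlocal ri, consumed
        got: List[Tuple[int, int]] = []
        while True:
            if ri >= len(ops_l):
                break
            op, ln = ops_l[ri], lens_l[ri]
            if op == OP_I:
                got.append((op, ln))
                ri += 1
                continue
            if amount == 0:
                break
            avail = ln - consumed
            use = min(avail, amount)
            got.append((op, use))
            amount -= use
            consumed += use
            if consumed == ln:
                ri += 1
                consumed = 0
        return got

    while si < len(segs) and hap_pos < a + H:
        seg = segs[si]
        seg_hi = seg.hap_lo + seg.hap_len
        if seg.kind == "V" and seg.hap_len == 0:
            # pure deletion junction: emit if strictly inside the read walk
            if hap_pos > a and hap_pos < a + H and items:
                items.append(("var", seg.var, 0))
            si += 1
            continue
        take = min(seg_hi, a + H) - hap_pos
        runs = _take(take)
        if seg.kind == "M":
            if first_ref < 0 and any(o != OP_I for o, _ in runs):
                first_ref = seg.ref_lo + (hap_pos - seg.hap_lo)
            items.extend(("op", o, l) for o, l in runs)
        else:  # inserted fragment: record query bases consumed over it
            q = sum(l for o, l in runs if o in (OP_M, OP_I))
            items.append(("var", seg.var, q))
        hap_pos += take
        if hap_pos >= seg_hi:
            si += 1
    # trailing pure-insert error runs
    items.extend(("op", o, l) for o, l in _take(0))

    if first_ref < 0 and not any(it[0] == "var" for it in items):
        return None
    return _resolve_variants(read, first_ref, items, rng, clip_p)


def _resolve_variants(
    read: SimulatedRead, pos0: int, items: List[Tuple], rng: np.random.Generator, clip_p: float
) -> Optional[SamRecord]:
    """Turn variant markers into I/D runs or soft clips, then finalize."""

    def _qlen(its) -> int:
        q = 0
        for it in its:
            if it[0] == "op" and it[1] in (OP_M, OP_I, OP_S):
                q += it[2]
            elif it[0] == "var":
                q += it[2]
        return q

    while True:
        vi = next((j for j, it in enumerate(items) if it[0] == "var"), None)
        if vi is None:
            break
        _, var, q = items[vi]
        left = items[:vi]
        right = items[vi + 1 :]
        has_left = any(it[0] == "op" and it[1] == OP_M for it in left)
        has_right = any(it[0] == "op" and it[1] == OP_M for it in right)
        span = var.del_len
        repl: List[Tuple]
        if has_left and has_right:
            clip = var.inserted_seq != "" and rng.random() < clip_p
            if not clip:
                repl = []
                if q > 0:
                    repl.append(("op", OP_I, q))
                if span > 0:
                    repl.append(("op", OP_D, span))
                items = left + repl + right
                continue
            qL, qR = _qlen(left), q + _qlen(right)
            if qL >= qR:
                items = left + ([("op", OP_S, qR)] if qR else [])
            else:
                items = ([("op", OP_S, qL + q)] if qL + q else []) + right
                pos0 = var.end  # 0-based: first ref base after the deleted span
            continue
        if has_left:  # read ends inside the insert
            items = left + ([("op", OP_S, q + _qlen(right))] if q + _qlen(right) else [])
            continue
        if has_right:  # read starts inside the insert
            items = ([("op", OP_S, _qlen(left) + q)] if _qlen(left) + q else []) + right
            pos0 = var.end
            continue
        return None  # read lies entirely within the inserted fragment

    return _finalize(read, pos0, [(it[1], it[2]) for it in items], rng, clip_p)


def _finalize(
    read: SimulatedRead, pos0: int, runs: List[Tuple[int, int]], rng, clip_p
) -> Optional[SamRecord]:
    ops = np.array([o for o, _ in runs], np.uint8)
    lens = np.array([l for _, l in runs], np.int64)
    ops, lens = _merge_runs(ops, lens)
    # leading/trailing D never appears in a valid alignment
    while ops.size and ops[0] == OP_D:
        pos0 += int(lens[0])
        ops, lens = ops[1:], lens[1:]
    while ops.size and ops[-1] == OP_D:
        ops, lens = ops[:-1], lens[:-1]
    # leading/trailing I becomes (part of) a soft clip
    changed = True
    while changed and ops.size:
        changed = False
        if ops[0] == OP_I or (ops.size > 1 and ops[0] == OP_S and ops[1] == OP_I):
            if ops[0] == OP_I:
                ops = ops.copy()
                ops[0] = OP_S
            else:
                lens = lens.copy()
                lens[1] += lens[0]
                ops, lens = ops[1:], lens[1:]
            ops, lens = _merge_runs(ops, lens)
            changed = True
        if ops.size and (ops[-1] == OP_I or (ops.size > 1 and ops[-1] == OP_S and ops[-2] == OP_I)):
            if ops[-1] == OP_I:
                ops = ops.copy()
                ops[-1] = OP_S
            else:
                lens = lens.copy()
                lens[-2] += lens[-1]
                ops, lens = ops[:-1], lens[:-1]
            ops, lens = _merge_runs(ops, lens)
            changed = True
    if not (ops == OP_M).any():
        return None
    qlen = int(lens[(ops == OP_M) | (ops == OP_I) | (ops == OP_S)].sum())
    if qlen != read.seq.size:
        raise AssertionError(
            f"{read.name}: CIGAR consumes {qlen} query bases, sequence has {read.seq.size}"
        )
    return SamRecord(read.name, pos0 + 1, ops, lens, read.seq, read.haplotype)


# ---------------------------------------------------------------------------
# File output

def write_fasta(path: str, name: str, seq: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str, reads: Sequence[SimulatedRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            s = decode(r.seq)
            fh.write(f"@{r.name}\n{s}\n+\n{'I' * len(s)}\n")


def sam_header(ref_name: str, ref_len: int) -> str:
    return f"@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:{ref_name}\tLN:{ref_len}\n"


def write_sam(path: str, records: Sequence[SamRecord], ref_name: str, ref_len: int) -> None:
    with open(path, "w") as fh:
        fh.write(sam_header(ref_name, ref_len))
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.name, "0", ref_name, str(r.pos), "60", r.cigar_string(),
                        "*", "0", "0", decode(r.seq), "*", f"HP:i:{r.haplotype}",
                    ]
                )
                + "\n"
            )


def write_truth_files(
    truth: Sequence[TruthVariant], vcf_path: str, bed_path: str,
    reference: str, ref_name: str = "ref",
) -> None:
    """Write the truth VCF (phased GT on two haplotypes) and SV BED.

    VCF records are left-anchored: REF is the base before the event plus the
    deleted span, ALT is that base plus the inserted sequence.  The BED uses
    0-based half-open SV intervals.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref_name},length={len(reference)}>",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Variant class">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="Last deleted base (1-based)">',
        '##INFO=<ID=SRC,Number=1,Type=Integer,Description="Insert source locus (1-based)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsim",
    ]
    bed_lines = []
    for v in sorted(truth, key=lambda t: (t.start, t.id)):
        gt = {"0": "1|0", "1": "0|1", "both": "1|1"}[v.haplotype]
        if v.vtype == "snv":
            ref_a = reference[v.start - 1]
            lines.append(
                f"{ref_name}\t{v.start}\t{v.id}\t{ref_a}\t{v.alt_base}\t.\tPASS\t"
                f"SVTYPE=SNV\tGT\t{gt}"
            )
            continue
        anchor_pos = v.start - 1  # base before the event
        if anchor_pos < 1:
            raise ValueError(f"{v.id}: SV at position 1 cannot be left-anchored")
        ref_a = reference[anchor_pos - 1 : v.end]
        alt_a = reference[anchor_pos - 1] + v.inserted_seq
        info = f"SVTYPE={v.vtype.upper()};END={v.end}"
        if v.insert_source is not None:
            info += f";SRC={v.insert_source}"
        lines.append(
            f"{ref_name}\t{anchor_pos}\t{v.id}\t{ref_a}\t{alt_a}\t.\tPASS\t{info}\tGT\t{gt}"
        )
        bed_lines.append(f"{ref_name}\t{v.start - 1}\t{max(v.end, v.start)}\t{v.id}\t{v.vtype}")
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(bed_path, "w") as fh:
        fh.write("\n".join(bed_lines) + ("\n" if bed_lines else ""))


def read_truth_vcf(path: str) -> List[TruthVariant]:
    """Round-trip reader for the truth VCF written above."""
    out: List[TruthVariant] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
            gt = f[9]
            hap = {"1|0": "0", "0|1": "1", "1|1": "both"}[gt]
            svtype = info.get("SVTYPE", "SNV").lower()
            pos = int(f[1])
            if svtype == "snv":
                out.append(
                    TruthVariant(f[2], "snv", hap, pos, pos, alt_base=f[4])
                )
                continue
            end = int(info["END"])
            ins = f[4][1:]
            src = int(info["SRC"]) if "SRC" in info else None
            out.append(
                TruthVariant(f[2], svtype, hap, pos + 1, end, inserted_seq=ins, insert_source=src)
            )
    out.sort(key=lambda v: (v.start, v.id))
    return out


# ---------------------------------------------------------------------------
# End-to-end convenience

@dataclass
class SimResult:
    config: SimConfig
    reference: str
    haplotypes: Tuple[str, str]
    truth: List[TruthVariant]
    reads: List[SimulatedRead]
    records: List[SamRecord]
    ref_name: str = "ref"

    @property
    def sv_truth(self) -> List[TruthVariant]:
        return [v for v in self.truth if v.vtype != "snv"]


def simulate(config: SimConfig) -> SimResult:
    """Run the whole simulator: reference, variants, reads, alignments."""
    reference = generate_reference(config.ref_length, config.seed)
    hap0, hap1, truth = plant_variants(reference, config)
    reads = simulate_reads((hap0, hap1), config)
    records = emit_truth_alignments(reads, reference, truth, config)
    return SimResult(config, reference, (hap0, hap1), truth, reads, records)


def write_outputs(result: SimResult, outdir: str) -> Dict[str, str]:
    """Write FASTA/FASTQ/SAM/VCF/BED into `outdir`; returns a path manifest."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "reference": os.path.join(outdir, "reference.fa"),
        "hap0": os.path.join(outdir, "hap0.fa"),
        "hap1": os.path.join(outdir, "hap1.fa"),
        "reads": os.path.join(outdir, "reads.fq"),
        "alignments": os.path.join(outdir, "alignments.sam"),
        "truth_vcf": os.path.join(outdir, "truth.vcf"),
        "truth_bed": os.path.join(outdir, "truth.bed"),
    }
    write_fasta(paths["reference"], result.ref_name, result.reference)
    write_fasta(paths["hap0"], "hap0", result.haplotypes[0])
    write_fasta(paths["hap1"], "hap1", result.haplotypes[1])
    write_fastq(paths["reads"], result.reads)
    write_sam(paths["alignments"], result.records, result.ref_name, len(result.reference))
    write_truth_files(result.truth, paths["truth_vcf"], paths["truth_bed"], result.reference, result.ref_name)
    return paths


def manifest_checksums(paths: Dict[str, str]) -> Dict[str, str]:
    out = {}
    for key, p in sorted(paths.items()):
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            h.update(fh.read())
        out[key] = h.hexdigest()
    return out
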