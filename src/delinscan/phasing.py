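"""Read-backed haplotype phasing with LD-based secondary splicing.

SNVs (from a VCF) and the caller's SV records are merged into a set of
phasable heterozygous variants; every read is scored ref/alt/missing at each
variant it spans informatively; variants co-observed on enough concordant
reads are spliced into haplotype blocks; and remaining adjacent blocks are
joined by a linkage-disequilibrium correlation score

    L = sum_i sum_j lq(i, j) * p(j)

accumulated over all cross-block variant pairs, where lq is the signed
normalized covariance D = p(AB) - p(A) p(B) of the paired alleles among
co-informative reads and p(j) is the posterior variant's alternate-allele
frequency.  The orientation (same / flipped) with the higher L wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .alignments import Alignment, AlnStore
from .simdata import OP_D, OP_I, OP_M, OP_S, decode, encode

REF, ALT = 0, 1


@dataclass
class PhasableVariant:
    id: str
    contig: str
    position: int  # 1-based; SV position is the first deleted base
    kind: str  # snv | deletion | insertion | delins
    ref_allele: str
    alt_allele: str
    end: int = 0  # last deleted base (SVs); == position for SNVs
    ins_len: int = 0
    p: float = float("nan")  # alternate-allele frequency among informative reads
    phasable: bool = False

    def __post_init__(self) -> None:
        if self.end == 0:
            self.end = self.position if self.kind != "insertion" else self.position - 1


class MalformedVcf(ValueError):
    pass


def read_snv_vcf(path: str, contig: Optional[str] = None) -> List[PhasableVariant]:
    """Read SNV records from a VCF; non-SNV records are ignored."""
    out: List[PhasableVariant] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise MalformedVcf(f"{path}:{ln}: fewer than 8 VCF columns")
            chrom, pos, vid, ref, alt = f[0], f[1], f[2], f[3], f[4]
            if contig is not None and chrom != contig:
                continue
            if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                continue  # not a simple SNV
            try:
                p = int(pos)
            except ValueError as e:
                raise MalformedVcf(f"{path}:{ln}: bad POS {pos!r}") from e
            name = vid if vid not in (".", "") else f"snv@{p}"
            out.append(PhasableVariant(name, chrom, p, "snv", ref, alt))
    out.sort(key=lambda v: v.position)
    return out


def merge_variants(
    sv_calls: Sequence, snvs: Sequence[PhasableVariant], contig: str
) -> List[PhasableVariant]:
    """Union of SNVs and SV calls, position-sorted, duplicates collapsed."""
    merged: Dict[Tuple[int, str], PhasableVariant] = {}
    for v in snvs:
        merged.setdefault((v.position, v.kind), v)
    for c in sv_calls:
        pv = PhasableVariant(
            id=c.id,
            contig=contig,
            position=c.start,
            kind=c.vtype,
            ref_allele="N",
            alt_allele=getattr(c, "inserted_seq", "") or "",
            end=c.end,
            ins_len=len(getattr(c, "inserted_seq", "") or ""),
        )
        merged.setdefault((pv.position, pv.kind), pv)
    return sorted(merged.values(), key=lambda v: (v.position, v.kind, v.id))


# ---------------------------------------------------------------------------
# Read-allele matrix

class ReadAlleleMatrix:
    """Sparse read x variant matrix with entries in {ref, alt}."""

    def __init__(self, variant_ids: Sequence[str]):
        self.variant_ids = list(variant_ids)
        self.vindex = {v: i for i, v in enumerate(self.variant_ids)}
        self.by_read: Dict[str, Dict[int, int]] = {}

    def set(self, read: str, variant_id: str, allele: int) -> None:
        self.by_read.setdefault(read, {})[self.vindex[variant_id]] = allele

    def column(self, variant_id: str) -> List[int]:
        vi = self.vindex[variant_id]
        return [row[vi] for row in self.by_read.values() if vi in row]

    def n_entries(self) -> int:
        return sum(len(r) for r in self.by_read.values())

    def pair_counts(self) -> Dict[Tuple[int, int], np.ndarray]:
        """2x2 joint allele counts for every co-observed variant pair."""
        counts: Dict[Tuple[int, int], np.ndarray] = {}
        for row in self.by_read.values():
            items = sorted(row.items())
            for a in range(len(items)):
                ia, ea = items[a]
                for b in range(a + 1, len(items)):
                    ib, eb = items[b]
                    key = (ia, ib)
                    if key not in counts:
                        counts[key] = np.zeros((2, 2), np.int64)
                    counts[key][ea, eb] += 1
        return counts


def assign_read_alleles(
    variants: Sequence[PhasableVariant],
    store: AlnStore,
    reference: Union[str, np.ndarray],
    pad: int = 20,
    clip_tol: int = 20,
    min_clip: int = 50,
) -> ReadAlleleMatrix:
    """Score every read at every variant it spans informatively.

    SNVs use the aligned base; deletions/delins are alt when the read gaps or
    clips across the span and ref when it aligns contiguously through;
    insertions are alt on a long enough insertion operation (or clip) at the
    breakpoint.  Everything else is missing.
    """
    ref = encode(reference) if isinstance(reference, str) else reference
    mat = ReadAlleleMatrix([v.id for v in variants])
    positions = np.array([v.position for v in variants])
    for a in store:
        lo = int(np.searchsorted(positions, a.pos0 + 1 - pad))
        hi = int(np.searchsorted(positions, a.ref_end0 + pad, side="right"))
        if hi <= lo:
            continue
        qidx = _query_index(a)
        for v in variants[lo:hi]:
            allele = _score_variant(a, v, qidx, ref, pad, clip_tol, min_clip)
            if allele is not None:
                mat.set(a.name, v.id, allele)
    return mat


def _query_index(a: Alignment) -> np.ndarray:
    """Per reference offset (from pos0), the query index of the aligned base
    or -1 inside deletions."""
    n = a.ref_end0 - a.pos0
    out = np.full(n, -1, np.int64)
    rs = a.run_ref_starts() - a.pos0
    qs = a.run_query_starts()
    for op, ln, r0, q0 in zip(a.ops, a.lens, rs, qs):
        if op == OP_M:
            out[r0 : r0 + ln] = np.arange(q0, q0 + ln)
    return out


def _score_variant(
    a: Alignment,
    v: PhasableVariant,
    qidx: np.ndarray,
    ref: np.ndarray,
    pad: int,
    clip_tol: int,
    min_clip: int,
) -> Optional[int]:
    if v.kind == "snv":
        off = v.position - 1 - a.pos0
        if off < 0 or off >= qidx.size:
            return None
        qi = qidx[off]
        if qi < 0 or not a.seq.size:
            return None
        base = a.seq[qi]
        alt = encode(v.alt_allele)[0] if v.alt_allele in "ACGT" else 255
        if base == alt:
            return ALT
        if base == ref[v.position - 1]:
            return REF
        return None

    s, e = v.position, v.end
    # clip at the breakpoint is alt evidence
    if a.right_clip > min_clip and abs((a.ref_end0 + 1) - s) <= clip_tol:
        return ALT
    if a.left_clip > min_clip and abs(a.pos0 - e) <= clip_tol:  # pos0 == e means first aligned base is e+1
        return ALT

    if v.kind in ("deletion", "delins"):
        if a.pos0 + 1 > s - pad or a.ref_end0 < e + pad:
            return None
        span = slice(s - 1 - a.pos0, e - a.pos0)
        gap_frac = float((qidx[span] < 0).mean())
        if gap_frac >= 0.5:
            return ALT
        if gap_frac <= 0.1:
            return REF
        return None

    # insertion: breakpoint between e (= s-1) and s
    if a.pos0 + 1 > s - pad - 1 or a.ref_end0 < s + pad:
        return None
    imask = a.ops == OP_I
    if imask.any():
        rs = a.run_ref_starts()
        anchors = rs[imask] - 1  # 0-based site left of the insertion
        near = np.abs(anchors - (s - 2)) <= clip_tol
        if near.any():
            need = max(min_clip, int(0.3 * v.ins_len)) if v.ins_len else min_clip
            if int(a.lens[imask][near].max()) >= need:
                return ALT
    return REF


def annotate_frequencies(
    variants: Sequence[PhasableVariant],
    matrix: ReadAlleleMatrix,
    het_min: float = 0.2,
    min_informative: int = 2,
) -> None:
    """Estimate each variant's alternate frequency p and gate heterozygosity.

    Variants with p outside [het_min, 1 - het_min] (or with too few
    informative reads) are flagged homozygous/noise and left unphased.
    """
    for v in variants:
        col = matrix.column(v.id)
        if len(col) >= min_informative:
            v.p = float(np.mean(col))
            v.phasable = het_min <= v.p <= 1.0 - het_min
        else:
            v.p = float("nan")
            v.phasable = False


def load_and_merge_variants(
    sv_calls: Sequence,
    snv_vcf: Optional[str],
    store: AlnStore,
    reference: Union[str, np.ndarray],
    het_min: float = 0.2,
    pad: int = 20,
    clip_tol: int = 20,
    min_clip: int = 50,
) -> Tuple[List[PhasableVariant], ReadAlleleMatrix]:
    """Merge SNVs and SV calls, score reads, and gate to heterozygous variants.

    Returns the full merged variant list (with `p` and `phasable` set) and
    the read-allele matrix over all of them.
    """
    snvs = read_snv_vcf(snv_vcf, contig=store.ref_name) if snv_vcf else []
    variants = merge_variants(sv_calls, snvs, store.ref_name)
    matrix = assign_read_alleles(variants, store, reference, pad, clip_tol, min_clip)
    annotate_frequencies(variants, matrix, het_min)
    return variants, matrix


def restrict_matrix(matrix: ReadAlleleMatrix, keep_ids: Sequence[str]) -> ReadAlleleMatrix:
    """Project the matrix onto a subset of variants."""
    keep = set(keep_ids)
    out = ReadAlleleMatrix([v for v in matrix.variant_ids if v in keep])
    for read, row in matrix.by_read.items():
        for vi, allele in row.items():
            vid = matrix.variant_ids[vi]
            if vid in keep:
                out.set(read, vid, allele)
    return out


# ---------------------------------------------------------------------------
# Haplotype blocks

@dataclass
class HaplotypeBlock:
    """Phased variants with hap-A alleles (hap B is the complement)."""

    id: int
    variant_ids: List[str]
    alleles: Dict[str, int]  # variant id -> 1 if hap A carries the alt
    positions: Dict[str, int]
    provenance: List[str] = field(default_factory=list)  # one per junction

    @property
    def span(self) -> Tuple[int, int]:
        pos = [self.positions[v] for v in self.variant_ids]
        return (min(pos), max(pos))

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass
class SpliceDecision:
    anterior: int
    posterior: int
    L_same: float
    L_flipped: float
    orientation: str
    accepted: bool

    @property
    def L(self) -> float:
        return max(self.L_same, self.L_flipped)


class _ParityUnion:
    """Union-find tracking relative phase (parity) to the component root."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.parity = [0] * n
        self.size = [1] * n

    def find(self, x: int) -> Tuple[int, int]:
        path = []
        p = 0
        while self.parent[x] != x:
            path.append(x)
            p ^= self.parity[x]
            x = self.parent[x]
        # path compression with accumulated parity
        acc = p
        for node in path:
            np_ = acc
            acc ^= self.parity[node]
            self.parent[node] = x
            self.parity[node] = np_
        return x, p

    def union(self, a: int, b: int, rel: int) -> bool:
        ra, pa = self.find(a)
        rb, pb = self.find(b)
        if ra == rb:
            return (pa ^ pb) == rel
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
            pa, pb = pb, pa
        self.parent[rb] = ra
        self.parity[rb] = pa ^ pb ^ rel
        self.size[ra] += self.size[rb]
        return True


def read_backed_splice(
    matrix: ReadAlleleMatrix,
    variants: Sequence[PhasableVariant],
    min_shared: int = 2,
) -> List[HaplotypeBlock]:
    """Greedy read-backed splicing into haplotype blocks.

    Variant pairs co-observed on >= min_shared reads with a clear co-allele
    majority are joined (strongest-majority pairs first); conflicting weaker
    evidence is outvoted.  Every phasable variant ends up in exactly one
    block; blocks are returned position-sorted.
    """
    byid = {v.id: v for v in variants}
    ids = matrix.variant_ids
    counts = matrix.pair_counts()
    edges = []
    for (ia, ib), c in counts.items():
        cis = int(c[0, 0] + c[1, 1])
        trans = int(c[0, 1] + c[1, 0])
        total = cis + trans
        if total < min_shared or cis == trans:
            continue
        rel = 0 if cis > trans else 1  # same-haplotype alt pattern or opposite
        edges.append((abs(cis - trans), total, ia, ib, rel))
    edges.sort(key=lambda e: (-e[0], -e[1], e[2], e[3]))
    uf = _ParityUnion(len(ids))
    for _, _, ia, ib, rel in edges:
        uf.union(ia, ib, rel)

    comps: Dict[int, List[int]] = {}
    for i in range(len(ids)):
        root, _ = uf.find(i)
        comps.setdefault(root, []).append(i)
    blocks: List[HaplotypeBlock] = []
    for root, members in comps.items():
        members.sort(key=lambda i: (byid[ids[i]].position, ids[i]))
        first_parity = uf.find(members[0])[1]
        alleles = {}
        for i in members:
            _, par = uf.find(i)
            # normalize: block's first variant has its alt on hap A
            alleles[ids[i]] = 1 - (par ^ first_parity)
        vids = [ids[i] for i in members]
        blocks.append(
            HaplotypeBlock(
                0,
                vids,
                alleles,
                {vid: byid[vid].position for vid in vids},
                ["read_backed"] * (len(vids) - 1),
            )
        )
    blocks.sort(key=lambda b: b.span[0])
    for n, b in enumerate(blocks):
        b.id = n
    return blocks


def ld_correlation(
    block_a: HaplotypeBlock,
    block_b: HaplotypeBlock,
    matrix: ReadAlleleMatrix,
    orientation: str = "same",
    pair_counts: Optional[Dict[Tuple[int, int], np.ndarray]] = None,
    freqs: Optional[Dict[str, float]] = None,
) -> float:
    """Accumulated linkage strength between two blocks under an orientation.

    For each cross-block variant pair, lq is the normalized covariance
    D = p(AB) - p(A) p(B) of "read agrees with hap A" indicators among reads
    informative at both sites (0 with no co-informative reads), signed by the
    orientation; each term is weighted by the posterior variant's alternate
    frequency p(j).
    """
    if orientation not in ("same", "flipped"):
        raise ValueError("orientation must be 'same' or 'flipped'")
    if pair_counts is None:
        pair_counts = matrix.pair_counts()
    L = 0.0
    flip = orientation == "flipped"
    for va in block_a.variant_ids:
        ia = matrix.vindex[va]
        ha = block_a.alleles[va]
        for vb in block_b.variant_ids:
            ib = matrix.vindex[vb]
            hb = block_b.alleles[vb] ^ (1 if flip else 0)
            key, swapped = ((ia, ib), False) if ia < ib else ((ib, ia), True)
            c = pair_counts.get(key)
            if c is None:
                continue
            if swapped:
                c = c.T
            n = c.sum()
            # x = read matches hap A of block A at va;  y likewise for B
            # entry e==ALT matches hap A iff the block allele is 1
            p_x = c[ha, :].sum() / n
            p_y = c[:, hb].sum() / n
            p_xy = c[ha, hb] / n
            D = float(p_xy - p_x * p_y)
            p_j = 0.5
            if freqs is not None:
                p_j = freqs.get(vb, 0.5)
            L += D * p_j
    return L


def secondary_splice(
    blocks: Sequence[HaplotypeBlock],
    matrix: ReadAlleleMatrix,
    freqs: Optional[Dict[str, float]] = None,
    min_L: float = 0.0,
    decisions: Optional[List[SpliceDecision]] = None,
) -> List[HaplotypeBlock]:
    """Left-to-right LD splicing of adjacent blocks, iterated to a fixpoint.

    For each junction the posterior block is joined in the orientation with
    the higher correlation L when that L clears min_L; within-block allele
    assignments are never altered (only whole-block flips).
    """
    blocks = [
        HaplotypeBlock(b.id, list(b.variant_ids), dict(b.alleles), dict(b.positions), list(b.provenance))
        for b in blocks
    ]
    pair_counts = matrix.pair_counts()
    max_passes = max(len(blocks), 1)
    for _ in range(max_passes):
        blocks.sort(key=lambda b: b.span[0])
        changed = False
        out: List[HaplotypeBlock] = []
        cur = blocks[0] if blocks else None
        for nxt in blocks[1:]:
            L_same = ld_correlation(cur, nxt, matrix, "same", pair_counts, freqs)
            L_flip = ld_correlation(cur, nxt, matrix, "flipped", pair_counts, freqs)
            best = max(L_same, L_flip)
            orient = "same" if L_same >= L_flip else "flipped"
            accept = best >= min_L
            if decisions is not None:
                decisions.append(
                    SpliceDecision(cur.id, nxt.id, L_same, L_flip, orient, accept)
                )
            if accept:
                cur = _merge_blocks(cur, nxt, orient)
                changed = True
            else:
                out.append(cur)
                cur = nxt
        if cur is not None:
            out.append(cur)
        blocks = out
        if not changed:
            break
    for n, b in enumerate(blocks):
        b.id = n
    return blocks


def _merge_blocks(a: HaplotypeBlock, b: HaplotypeBlock, orientation: str) -> HaplotypeBlock:
    alleles = dict(a.alleles)
    for vid, al in b.alleles.items():
        alleles[vid] = al ^ (1 if orientation == "flipped" else 0)
    vids = a.variant_ids + b.variant_ids
    positions = {**a.positions, **b.positions}
    vids.sort(key=lambda v: (positions[v], v))
    prov = a.provenance + ["ld_spliced"] + b.provenance
    return HaplotypeBlock(a.id, vids, alleles, positions, prov)


# ---------------------------------------------------------------------------
# Phased VCF

def emit_phased_vcf(
    blocks: Sequence[HaplotypeBlock],
    variants: Sequence[PhasableVariant],
    path: str,
    reference: Union[str, np.ndarray],
    ref_name: str = "ref",
    sample: str = "sample",
) -> None:
    """Write phased genotypes with a PS (phase set) per block.

    Blocks of a single variant are emitted unphased (0/1).  SV records are
    left-anchored with explicit REF/ALT sequences and SVTYPE/END INFO keys.
    """
    refs = decode(reference) if not isinstance(reference, str) else reference
    block_of: Dict[str, HaplotypeBlock] = {}
    for b in blocks:
        for vid in b.variant_ids:
            block_of[vid] = b
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref_name},length={len(refs)}>",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Variant class">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="Last deleted base (1-based)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    rows = []
    for v in variants:
        b = block_of.get(v.id)
        if b is not None and len(b) >= 2:
            hap_a = b.alleles[v.id]
            gt = "1|0" if hap_a == 1 else "0|1"
            ps = b.positions[b.variant_ids[0]]
            fmt, samp = "GT:PS", f"{gt}:{ps}"
        else:
            fmt, samp = "GT", "0/1"
        if v.kind == "snv":
            pos, ref_a, alt_a, info = v.position, refs[v.position - 1], v.alt_allele, "SVTYPE=SNV"
        else:
            pos = v.position - 1
            if pos < 1:
                continue
            ref_a = refs[pos - 1 : v.end]
            ins = v.alt_allele if v.alt_allele not in ("<SV>", "") else ""
            alt_a = refs[pos - 1] + ins
            if alt_a == ref_a:
                alt_a = f"<{v.kind.upper()}>"
            info = f"SVTYPE={v.kind.upper()};END={v.end}"
        rows.append((pos, f"{ref_name}\t{pos}\t{v.id}\t{ref_a}\t{alt_a}\t.\tPASS\t{info}\t{fmt}\t{samp}"))
    rows.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        fh.write("\n".join(lines + [r[1] for r in rows]) + "\n")


def read_phased_blocks(path: str) -> Dict[int, List[str]]:
    """Phase-set id -> phased variant ids, for round-trip checks."""
    out: Dict[int, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            fmt = f[8].split(":")
            if "PS" not in fmt:
                continue
            ps = int(f[9].split(":")[fmt.index("PS")])
            out.setdefault(ps, []).append(f[2])
    return out
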