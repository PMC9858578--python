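"""Variant merging, read-allele scoring, block splicing and the LD
correlation used for secondary splicing."""

import numpy as np
import pytest

from delinscan import phasing
from delinscan.alignments import AlnStore
from delinscan.metrics import block_n50
from delinscan.phasing import (
    HaplotypeBlock, MalformedVcf, PhasableVariant, ReadAlleleMatrix,
    annotate_frequencies, assign_read_alleles, emit_phased_vcf, ld_correlation,
    merge_variants, read_backed_splice, read_phased_blocks, read_snv_vcf,
    secondary_splice,
)
from delinscan.pipeline import VariantCall
from delinscan.simdata import OP_D, OP_I, OP_M, OP_S, SamRecord, encode, generate_reference


def _rec(name, pos, cigar, seq):
    ops = np.array([o for o, _ in cigar], np.uint8)
    lens = np.array([l for _, l in cigar], np.int64)
    return SamRecord(name, pos, ops, lens, encode(seq))


def _snv(i, pos, ref="A", alt="C"):
    return PhasableVariant(f"s{i}", "ref", pos, "snv", ref, alt)


class TestVcfIO:
    def test_snv_vcf_round_trip(self, tmp_path, sim15):
        from delinscan.simdata import write_truth_files

        vcf = str(tmp_path / "t.vcf")
        write_truth_files(sim15.truth, vcf, vcf + ".bed", sim15.reference, "ref")
        snvs = read_snv_vcf(vcf, contig="ref")
        truth_snvs = [v for v in sim15.truth if v.vtype == "snv"]
        assert len(snvs) == len(truth_snvs)
        assert all(a.position == b.start and a.alt_allele == b.alt_base
                   for a, b in zip(snvs, truth_snvs))

    def test_malformed_vcf_reports_line(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("##fileformat=VCFv4.2\nref\tnotanumber\n")
        with pytest.raises(MalformedVcf, match=":2"):
            read_snv_vcf(str(p))


class TestMergeVariants:
    def test_union_with_empty_snv_set(self):
        calls = [VariantCall(f"c{i}", "delins", 1000 * i + 500, 1000 * i + 900)
                 for i in range(3)]
        merged = merge_variants(calls, [], "ref")
        assert [v.kind for v in merged] == ["delins"] * 3

    def test_duplicate_records_collapsed(self):
        snvs = [_snv(1, 100), _snv(2, 100)]
        assert len(merge_variants([], snvs, "ref")) == 1

    def test_position_sorted(self):
        calls = [VariantCall("c1", "deletion", 5000, 5400)]
        snvs = [_snv(1, 9000), _snv(2, 100)]
        merged = merge_variants(calls, snvs, "ref")
        assert [v.position for v in merged] == [100, 5000, 9000]


@pytest.fixture(scope="module")
def toy_case():
    """Two haplotype groups of reads over two SNVs and one deletion."""
    ref = generate_reference(4_000, seed=50)
    v_snv1 = PhasableVariant("s1", "ref", 500, "snv", ref[499], _other(ref[499]))
    v_del = PhasableVariant("d1", "ref", 1500, "deletion", "N", "", end=1900)
    v_snv2 = PhasableVariant("s2", "ref", 2500, "snv", ref[2499], _other(ref[2499]))
    variants = [v_snv1, v_del, v_snv2]
    recs = []
    for i in range(6):  # haplotype A: alt at all three
        seq = list(ref[:1500] + ref[1900:3000])
        seq[499] = v_snv1.alt_allele
        seq[1500 + (2499 - 1900)] = v_snv2.alt_allele
        recs.append(_rec(f"hapA_{i}", 1, [(OP_M, 1500), (OP_D, 400), (OP_M, 1100)],
                         "".join(seq)))
    for i in range(6):  # haplotype B: reference everywhere
        recs.append(_rec(f"hapB_{i}", 1, [(OP_M, 3000)], ref[:3000]))
    store = AlnStore.from_records(recs, "ref", len(ref))
    return ref, variants, store


def _other(b):
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[b]


class TestAssignReadAlleles:
    def test_haplotype_reads_scored_consistently(self, toy_case):
        ref, variants, store = toy_case
        mat = assign_read_alleles(variants, store, ref)
        for name, row in mat.by_read.items():
            want = 1 if name.startswith("hapA") else 0
            assert set(row.values()) == {want}, name
            assert len(row) == 3

    def test_read_ending_before_variant_is_missing(self, toy_case):
        ref, variants, store = toy_case
        short = _rec("short", 1, [(OP_M, 490)], ref[:490])  # ends 10 bp before s1
        mat = assign_read_alleles(variants, AlnStore.from_records([short], "ref", len(ref)), ref)
        assert mat.by_read.get("short", {}) == {}

    def test_matrix_invariant_to_read_order(self, toy_case):
        ref, variants, store = toy_case
        recs = list(store)
        rev = AlnStore.from_records(
            [SamRecord(a.name, a.pos0 + 1, a.ops, a.lens, a.seq) for a in recs[::-1]],
            "ref", len(ref),
        )
        m1 = assign_read_alleles(variants, store, ref)
        m2 = assign_read_alleles(variants, rev, ref)
        assert m1.by_read == m2.by_read

    def test_clip_at_breakpoint_scores_alt(self, toy_case):
        ref, variants, store = toy_case
        clipped = _rec("clipped", 1, [(OP_M, 1499), (OP_S, 300)],
                       ref[:1499] + "A" * 300)
        mat = assign_read_alleles(
            variants, AlnStore.from_records([clipped], "ref", len(ref)), ref
        )
        assert mat.by_read["clipped"][mat.vindex["d1"]] == 1

    def test_frequency_gate_marks_homozygous_unphasable(self, toy_case):
        ref, variants, store = toy_case
        mat = assign_read_alleles(variants, store, ref)
        annotate_frequencies(variants, mat, het_min=0.2)
        assert all(v.phasable for v in variants)
        assert all(abs(v.p - 0.5) < 0.2 for v in variants)
        hom = PhasableVariant("hom", "ref", 800, "snv", ref[799], _other(ref[799]))
        mat2 = ReadAlleleMatrix(["hom"])
        for i in range(10):
            mat2.set(f"r{i}", "hom", 1)
        annotate_frequencies([hom], mat2, het_min=0.2)
        assert not hom.phasable


class TestReadBackedSplice:
    def test_concordant_pair_joined(self, toy_case):
        ref, variants, store = toy_case
        mat = assign_read_alleles(variants, store, ref)
        blocks = read_backed_splice(mat, variants, min_shared=2)
        assert len(blocks) == 1 and len(blocks[0]) == 3
        b = blocks[0]
        assert len(set(b.alleles.values())) == 1  # all on the same haplotype

    def test_unlinked_variants_stay_apart(self):
        variants = [_snv(1, 100), _snv(2, 50_000)]
        mat = ReadAlleleMatrix(["s1", "s2"])
        for i in range(5):
            mat.set(f"a{i}", "s1", 1)
            mat.set(f"b{i}", "s2", 1)
        blocks = read_backed_splice(mat, variants)
        assert sorted(len(b) for b in blocks) == [1, 1]

    def test_conflicting_read_outvoted(self):
        variants = [_snv(1, 100), _snv(2, 300)]
        mat = ReadAlleleMatrix(["s1", "s2"])
        for i in range(5):
            mat.set(f"good{i}", "s1", 1)
            mat.set(f"good{i}", "s2", 1)
        mat.set("bad", "s1", 1)
        mat.set("bad", "s2", 0)
        (block,) = read_backed_splice(mat, variants)
        assert block.alleles["s1"] == block.alleles["s2"]

    def test_every_variant_in_exactly_one_block(self, sim15, store15):
        truth_snvs = [t for t in sim15.truth if t.vtype == "snv"]
        variants = [
            PhasableVariant(t.id, "ref", t.start, "snv", "N", t.alt_base)
            for t in truth_snvs[:40]
        ]
        mat = assign_read_alleles(variants, store15, sim15.reference)
        annotate_frequencies(variants, mat)
        phasable = [v for v in variants if v.phasable]
        sub = phasing.restrict_matrix(mat, [v.id for v in phasable])
        blocks = read_backed_splice(sub, phasable)
        seen = [v for b in blocks for v in b.variant_ids]
        assert sorted(seen) == sorted(v.id for v in phasable)


def _block(bid, items):
    """items: [(vid, pos, allele)]"""
    return HaplotypeBlock(
        bid, [v for v, _, _ in items], {v: a for v, _, a in items},
        {v: p for v, p, _ in items}, ["read_backed"] * (len(items) - 1),
    )


class TestLdCorrelation:
    def _matrix(self, entries):
        mat = ReadAlleleMatrix(["x", "y"])
        for r, (ex, ey) in enumerate(entries):
            mat.set(f"r{r}", "x", ex)
            mat.set(f"r{r}", "y", ey)
        return mat

    def test_perfect_linkage_sign_flips_with_orientation(self):
        mat = self._matrix([(1, 1)] * 5 + [(0, 0)] * 5)
        a = _block(0, [("x", 100, 1)])
        b = _block(1, [("y", 900, 1)])
        same = ld_correlation(a, b, mat, "same")
        flipped = ld_correlation(a, b, mat, "flipped")
        assert same > 0
        assert flipped == pytest.approx(-same)

    def test_independent_variants_contribute_zero(self):
        mat = self._matrix([(1, 1), (1, 0), (0, 1), (0, 0)] * 3)
        a = _block(0, [("x", 100, 1)])
        b = _block(1, [("y", 900, 1)])
        assert ld_correlation(a, b, mat, "same") == pytest.approx(0.0)

    def test_no_coinformative_reads_gives_zero(self):
        mat = ReadAlleleMatrix(["x", "y"])
        mat.set("r1", "x", 1)
        mat.set("r2", "y", 1)
        a = _block(0, [("x", 100, 1)])
        b = _block(1, [("y", 900, 1)])
        assert ld_correlation(a, b, mat, "same") == 0.0


class TestSecondarySplice:
    def test_single_block_unchanged(self):
        mat = ReadAlleleMatrix(["x"])
        b = _block(0, [("x", 100, 1)])
        out = secondary_splice([b], mat)
        assert len(out) == 1 and out[0].variant_ids == ["x"]

    def test_gate_blocks_splicing_without_evidence(self):
        mat = ReadAlleleMatrix(["x", "y"])
        mat.set("r1", "x", 1)
        mat.set("r2", "y", 1)
        a = _block(0, [("x", 100, 1)])
        b = _block(1, [("y", 900, 1)])
        out = secondary_splice([a, b], mat, min_L=0.01)
        assert len(out) == 2

    def test_correct_orientation_chosen_and_n50_monotone(self):
        entries = [(1, 0)] * 6 + [(0, 1)] * 6  # variants in trans
        mat = ReadAlleleMatrix(["x", "y"])
        for r, (ex, ey) in enumerate(entries):
            mat.set(f"r{r}", "x", ex)
            mat.set(f"r{r}", "y", ey)
        a = _block(0, [("x", 100, 1)])
        b = _block(1, [("y", 900, 1)])
        before = block_n50([a, b])
        out = secondary_splice([a, b], mat, min_L=0.0)
        assert len(out) == 1
        assert out[0].alleles["x"] != out[0].alleles["y"]  # trans resolved
        assert "ld_spliced" in out[0].provenance
        assert block_n50(out) >= before

    def test_within_block_assignments_preserved(self):
        mat = ReadAlleleMatrix(["x", "y", "z"])
        for r in range(4):
            mat.set(f"r{r}", "y", 1)
            mat.set(f"r{r}", "z", 1)
        a = _block(0, [("x", 100, 1)])
        b = _block(1, [("y", 900, 1), ("z", 950, 0)])
        out = secondary_splice([a, b], mat, min_L=0.0)
        (merged,) = out
        assert (merged.alleles["y"] ^ merged.alleles["z"]) == 1


class TestPhasedVcf:
    def test_round_trip_reconstructs_block_membership(self, tmp_path):
        ref = generate_reference(5_000, seed=8)
        variants = [
            PhasableVariant("s1", "ref", 500, "snv", ref[499], _other(ref[499])),
            PhasableVariant("s2", "ref", 900, "snv", ref[899], _other(ref[899])),
            PhasableVariant("d1", "ref", 2000, "delins", "N", "ACGTACGT", end=2200),
            PhasableVariant("lone", "ref", 4000, "snv", ref[3999], _other(ref[3999])),
        ]
        blocks = [
            _block(0, [("s1", 500, 1), ("s2", 900, 0), ("d1", 2000, 1)]),
            _block(1, [("lone", 4000, 1)]),
        ]
        path = str(tmp_path / "phased.vcf")
        emit_phased_vcf(blocks, variants, path, ref, "ref")
        sets = read_phased_blocks(path)
        assert sets == {500: ["s1", "s2", "d1"]}
        # single-variant block emitted unphased
        lone_line = [l for l in open(path) if l.split("\t")[2:3] == ["lone"]][0]
        assert "0/1" in lone_line

    def test_output_parses_with_pysam(self, tmp_path):
        import pysam

        ref = generate_reference(3_000, seed=9)
        variants = [
            PhasableVariant("s1", "ref", 100, "snv", ref[99], _other(ref[99])),
            PhasableVariant("s2", "ref", 200, "snv", ref[199], _other(ref[199])),
        ]
        blocks = [_block(0, [("s1", 100, 1), ("s2", 200, 1)])]
        path = str(tmp_path / "p.vcf")
        emit_phased_vcf(blocks, variants, path, ref, "ref")
        with pysam.VariantFile(path) as vf:
            recs = list(vf)
        assert len(recs) == 2
        assert recs[0].samples[0]["GT"] == (1, 0)
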