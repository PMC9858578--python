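"""Density-scan oracles and invariants: pileup counting, Gaussian window
weights, score calculus, smoothing, and threshold region calling."""

import numpy as np
import pytest
from scipy.stats import norm

from delinscan.alignments import AlnStore
from delinscan.config import SimConfig
from delinscan.density import (
    CandidateRegion, Pileup, SitePileup, build_pileup, call_candidate_regions,
    score_track, smooth_track, unmatched_proportion, weight_vector,
)
from delinscan.simdata import OP_D, OP_I, OP_M, SamRecord, encode, generate_reference, simulate


def _mk_store(records, ref):
    return AlnStore.from_records(records, "ref", len(ref))


def _rec(name, pos, cigar, seq):
    ops = np.array([o for o, _ in cigar], np.uint8)
    lens = np.array([l for _, l in cigar], np.int64)
    return SamRecord(name, pos, ops, lens, encode(seq))


class TestPileup:
    def test_perfect_match_reads_have_zero_unmatched(self):
        ref = generate_reference(500, seed=1)
        recs = [_rec(f"r{i}", 1 + 10 * i, [(OP_M, 300)], ref[10 * i : 10 * i + 300])
                for i in range(10)]
        pu = build_pileup(_mk_store(recs, ref), ref)
        assert pu.u.sum() == 0
        assert pu.d.max() > 0

    def test_single_mismatch_counts_one_of_ten(self):
        ref = generate_reference(400, seed=2)
        x = 200  # 1-based mismatch site
        seqs = [ref[:300] for _ in range(10)]
        mutated = list(seqs[0])
        mutated[x - 1] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[x - 1]]
        seqs[0] = "".join(mutated)
        recs = [_rec(f"r{i}", 1, [(OP_M, 300)], s) for i, s in enumerate(seqs)]
        pu = build_pileup(_mk_store(recs, ref), ref)
        assert pu.site(x).u == 1 and pu.site(x).d == 10
        assert pu.u.sum() == 1

    def test_deletion_insertion_and_clip_evidence(self):
        ref = generate_reference(400, seed=3)
        # read with a 20-base deletion at ref 101-120, an insertion after 200,
        # and a right soft clip anchored at 300
        seq = ref[:100] + ref[120:200] + "ACGT" + ref[200:300] + "TTTT"
        rec = _rec("r", 1, [(OP_M, 100), (OP_D, 20), (OP_M, 80), (OP_I, 4),
                            (OP_M, 100), (4, 4)], seq)
        pu = build_pileup(_mk_store([rec], ref), ref)
        assert all(pu.site(p).u == 1 for p in range(101, 121))  # deleted span
        assert pu.site(200).u == 1  # insertion anchor
        assert pu.site(300).u == 1  # clip-adjacent site
        assert pu.site(150).u == 0 and pu.site(150).d == 1
        assert pu.site(330).d == 0  # clipped bases contribute nothing

    def test_matches_naive_cigar_walk_oracle(self, sim15, store15, pileup15):
        lo, hi = 40_000, 60_000
        ref = encode(sim15.reference)
        d = np.zeros(len(ref), np.int64)
        u = np.zeros(len(ref), np.int64)
        for a in store15.overlapping(lo, hi):
            sites = set()
            r, q = a.pos0, 0
            for op, ln in zip(a.ops, a.lens):
                if op == OP_M:
                    for j in range(ln):
                        d[r + j] += 1
                        if a.seq[q + j] != ref[r + j]:
                            sites.add(r + j)
                    r += ln
                    q += ln
                elif op == OP_D:
                    for j in range(ln):
                        d[r + j] += 1
                        sites.add(r + j)
                    r += ln
                elif op == OP_I:
                    if r - 1 >= a.pos0:
                        sites.add(r - 1)
                    q += ln
                else:  # soft clip
                    sites.add(a.pos0 if q == 0 else a.ref_end0 - 1)
                    q += ln
            for s in sites:
                u[s] += 1
        assert (pileup15.d[lo:hi] == d[lo:hi]).all()
        assert (pileup15.u[lo:hi] == u[lo:hi]).all()

    def test_unmatched_proportion(self):
        assert unmatched_proportion(SitePileup(1, 10, 0)) == 0.0
        assert unmatched_proportion(SitePileup(1, 20, 3)) == pytest.approx(0.15)
        assert unmatched_proportion(SitePileup(1, 0, 0)) == 0.0

    def test_u_exceeding_d_rejected(self):
        with pytest.raises(ValueError, match="u > d"):
            Pileup("ref", np.array([1]), np.array([2]))


class TestWeights:
    @pytest.mark.parametrize("w", [1, 5, 50, 200])
    def test_normalized_sum_is_one(self, w):
        assert weight_vector(w).weights.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("w", [5, 50])
    def test_symmetric_and_peaked_at_center(self, w):
        wt = weight_vector(w).weights
        assert np.allclose(wt, wt[::-1])
        assert wt.argmax() == w
        assert (np.diff(wt[: w + 1]) >= 0).all()

    def test_raw_sum_matches_gaussian_mass_oracle(self):
        raw = weight_vector(50).raw_sum
        xs = np.linspace(-3, 3, 101)
        quad = np.trapezoid(norm.pdf(xs), xs)  # trapezoid quadrature oracle
        assert raw == pytest.approx(quad, abs=2e-3)
        assert raw == pytest.approx(0.9973, abs=1e-3)

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            weight_vector(0)


def _score_oracle(p, weights):
    """Naive double loop with edge renormalization."""
    w = weights.weights
    half = weights.windows_len
    out = np.zeros_like(p)
    for c in range(len(p)):
        num = den = 0.0
        for k in range(-half, half + 1):
            if 0 <= c + k < len(p):
                num += w[k + half] * p[c + k]
                den += w[k + half]
        out[c] = num / den
    return out


class TestScores:
    def test_all_matched_scores_zero(self, weights50):
        pu = Pileup("ref", np.full(201, 30), np.zeros(201, np.int64))
        assert score_track(pu, weights50).scores[100] == 0.0

    def test_all_unmatched_scores_one(self, weights50):
        pu = Pileup("ref", np.full(201, 30), np.full(201, 30))
        assert score_track(pu, weights50).scores[100] == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_weighted_sum(self, rng, weights50):
        d = rng.integers(1, 40, size=400)
        u = rng.integers(0, d + 1)
        pu = Pileup("ref", d, u)
        got = score_track(pu, weights50).scores
        want = _score_oracle(pu.proportions(), weights50)
        assert np.allclose(got, want, atol=1e-12)

    def test_locality(self, rng, weights50):
        d = np.full(400, 20)
        u = rng.integers(0, 10, size=400)
        base = score_track(Pileup("ref", d, u.copy()), weights50).scores
        u2 = u.copy()
        u2[200] = 20
        bumped = score_track(Pileup("ref", d, u2), weights50).scores
        changed = np.flatnonzero(base != bumped)
        assert changed.min() >= 150 and changed.max() <= 250

    def test_monotone_in_p(self, rng, weights50):
        d = np.full(300, 20)
        u = rng.integers(0, 15, size=300)
        base = score_track(Pileup("ref", d, u.copy()), weights50).scores
        u2 = u.copy()
        u2[123] += 1
        bumped = score_track(Pileup("ref", d, u2), weights50).scores
        assert (bumped >= base - 1e-15).all()
        assert bumped[123] > base[123]

    def test_scores_bounded(self, rng, weights50):
        d = rng.integers(0, 30, size=500)
        u = rng.integers(0, np.maximum(d, 1) + 1)
        u = np.minimum(u, d)
        s = score_track(Pileup("ref", d, u), weights50).scores
        assert ((0 <= s) & (s <= 1)).all()


class TestSmoothing:
    def test_constant_track_unchanged(self):
        tr = score_track(Pileup("ref", np.full(100, 10), np.full(100, 5)),
                         weight_vector(5))
        sm = smooth_track(tr, 7).smooth_scores
        assert np.allclose(sm, 0.5, atol=1e-12)

    def test_interior_spike_divided_by_window(self):
        from delinscan.density import ScoreTrack

        s = np.zeros(101)
        s[50] = 0.8
        tr = ScoreTrack("ref", 1, s)
        sm = smooth_track(tr, 10).smooth_scores
        assert sm[50] == pytest.approx(0.8 / 21)

    def test_matches_naive_moving_average(self, rng):
        from delinscan.density import ScoreTrack

        s = rng.random(300)
        sm = smooth_track(ScoreTrack("ref", 1, s.copy()), 13).smooth_scores
        want = np.array([
            s[max(0, i - 13) : i + 14].mean() for i in range(300)
        ])
        assert np.allclose(sm, want, atol=1e-12)


class TestRegions:
    def _track(self, smooth):
        from delinscan.density import ScoreTrack

        tr = ScoreTrack("ref", 1, smooth.copy())
        tr.smooth_scores = smooth
        return tr

    def test_all_below_threshold_gives_nothing(self):
        assert call_candidate_regions(self._track(np.full(50, 0.1)), 0.3) == []

    def test_single_plateau(self):
        s = np.full(100, 0.1)
        s[30:61] = 0.8
        (reg,) = call_candidate_regions(self._track(s), 0.5)
        assert (reg.l, reg.r) == (31, 61)
        assert reg.peak_score == pytest.approx(0.8)

    def test_score_exactly_at_threshold_breaks_runs(self):
        s = np.array([0.1, 0.6, 0.5, 0.6, 0.1])
        regs = call_candidate_regions(self._track(s), 0.5)
        assert [(r.l, r.r) for r in regs] == [(2, 2), (4, 4)]

    def test_merge_gap_joins_close_regions(self):
        s = np.full(60, 0.1)
        s[10:20] = 0.9
        s[25:35] = 0.9
        regs = call_candidate_regions(self._track(s), 0.5, merge_gap=10)
        assert [(r.l, r.r) for r in regs] == [(11, 35)]
        regs = call_candidate_regions(self._track(s), 0.5, merge_gap=2)
        assert len(regs) == 2

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(50):
            s = rng.random(80)
            T = float(rng.uniform(0.2, 0.8))
            got = [(r.l, r.r) for r in call_candidate_regions(self._track(s), T)]
            want = []
            i = 0
            while i < len(s):
                if s[i] > T:
                    j = i
                    while j + 1 < len(s) and s[j + 1] > T:
                        j += 1
                    want.append((i + 1, j + 1))
                    i = j + 1
                else:
                    i += 1
            assert got == want

    def test_threshold_domain_checked(self):
        with pytest.raises(ValueError):
            call_candidate_regions(self._track(np.zeros(5)), 1.5)


class TestSignalDetection:
    def test_zero_noise_single_delins_called_exactly_once(self, ensemble):
        cfg = SimConfig(ref_length=100_000, n_delins=1, snv_rate=0.0,
                        error_rate=0.0, depth=25, seed=42)
        sim = simulate(cfg)
        store = AlnStore.from_records(sim.records, sim.ref_name, len(sim.reference))
        pu = build_pileup(store, sim.reference)
        tr = smooth_track(score_track(pu, weight_vector(50)), 50)
        regs = call_candidate_regions(tr, 0.25, 100)
        (v,) = sim.sv_truth
        assert len(regs) == 1
        assert regs[0].l <= v.end and regs[0].r >= v.start

    def test_every_delins_overlapped_at_fifteen_percent_error(self, sim15, pileup15):
        tr = smooth_track(score_track(pileup15, weight_vector(50)), 50)
        regs = call_candidate_regions(tr, 0.25, 100)
        for v in sim15.sv_truth:
            if v.vtype != "delins":
                continue
            assert any(r.l <= v.end and r.r >= v.start for r in regs), v.id
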