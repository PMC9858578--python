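# Methods

## Problem setting

A delins (complex indel) deletes a reference segment `[s, e]` and inserts a
different sequence at the same breakpoint. On continuous long reads (CLR)
with ~15% sequencing error the alignment evidence for such events is diluted
by a dense background of spurious 1-base insertions, deletions and
substitutions, so the caller is built around *aggregated density* signals
rather than individual signatures.

## Variation-density scan

For each reference site the pileup counts `d`, the reads whose alignment
covers the site, and `u`, the covering reads carrying *any* disagreement
there. "Unmatched" covers all CIGAR evidence exactly once per read per
site: an aligned base differing from the reference, a site inside a
deletion run, an insertion anchored immediately after the site, and the
single aligned site adjacent to a soft clip. Clipped bases themselves are
not aligned anywhere and contribute to neither count; sites with `d = 0`
are defined to have proportion `p = 0` (absence of reads is not evidence of
variation).

The per-site score is a Gaussian-weighted average of `p` over a window of
half-width `windows_len` sites: weights are the standard normal density
sampled at `3k/windows_len` (so the window spans ±3σ; the raw discrete sum
is the ±3σ Gaussian mass ≈ 0.9973) and are renormalised to sum to exactly 1,
which makes a fully mutated window score exactly 1 and a fully matched
window exactly 0. A `weight_vector(..., renormalize=False)` flag restores
the raw weights. The score track is then smoothed by a centred moving
average of half-width `smooth_win` (divisor `2·win+1`; truncated windows
with the actual count at contig edges — both averages renormalise over the
offsets that exist). Candidate regions are maximal runs with
`smoothScore > T` (a site exactly at `T` breaks a run); regions closer than
`merge_gap` sites are merged.

**Why T = 0.25.** For a *heterozygous* delins the deleted span is still
covered by the other haplotype, so the plateau of `p` is bounded near 0.5;
with a fraction of the variant-haplotype reads soft-clipped rather than
bridging, the expected plateau at 15% error and depth 25 is ≈ 0.4–0.5, with
read-sampling noise of several hundredths. The smoothed noise floor at 15%
error is ≈ 0.15 with a standard deviation around 0.01. The default
`T = 0.25` therefore sits > 8σ above the floor while leaving the plateau a
wide margin; `windows_len = 50` keeps the window well inside the shortest
(500 bp) delins. Both are configuration keys.

## Region typing

Each candidate region is summarised by: the fractions of in-region
alignment columns (M + I + D operations of overlapping reads, restricted to
the region) that are insertion, deletion and mismatch columns; the longest
run of sites whose unmatched proportion exceeds `site_unmatched_thresh`
(default 0.3) divided by the region length; the region length; and the
mean depth. Insertion operations are point events and region bounds are
smoothed-score crossings that can land a few sites inside the true span, so
insertion anchors are counted within `edge_pad = 50` sites of the region.

Classification uses one binary RBF SVM (`C = 1`, `gamma = 'scale'`, features
standardised with training-set mean/variance stored inside the ensemble)
per unordered pair of the classes {deletion, insertion, delins, noise} —
6 models for m = 4 — and majority vote; ties break by summed
decision-function margin, then by fixed class order, so predictions are
deterministic. The "noise" class absorbs false-positive regions.

The bundled training corpus is simulated: 400 kb genomes with 7 variants of
each type at every combination of error rate {0, 0.05, 0.10, 0.15} and
depth {25, 10}. Density-called regions are labelled by overlap with truth;
variants the scan missed (chiefly insertions, see Limitations) contribute
truth-derived regions; variant-free intervals supply extra noise examples.
Training is seeded and reproducible; `delinscan train` regenerates it.

## Breakpoint resolution

Start candidates come from reads soft-clipped at their right end (clip
strictly longer than `min_clip = 50` bases, anchored within
`windows_len` of the region): the first deleted base is the anchor + 1.
End candidates come from left-end clips (anchor − 1). Because an aligner
bridges the variant confidently when the error rate is low — leaving no
clips at all at zero noise — boundaries of CIGAR deletion runs of at least
`min_del_run = 100` bases inside the region are pooled into the candidate
sets as well; at zero noise these are exact. Tukey fences
(`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`, quartiles by linear interpolation, never
discarding every value) remove outliers and the mean of the kept candidates,
rounded half-up, is the estimate. With no evidence at all the density-scan
region bound is reported with a low-confidence flag. Pure insertions have
an empty deletion span and are reported as `start = end + 1`.

## Insert-source tracing

Clipped sequences of a delins/insertion region are treated as artificial
reads (optionally written as FASTQ) and matched to the reference by exact
k-mer seeding (`k = 13`, sorted-array index) with bidirectional extension
to maximal exact runs of at least `min_anchor` bases. Anchors mapping
within a clip-length exclusion zone around the region are flank matches;
they are peeled off and the unmatched portions re-queued for up to
`max_iterations = 3` rounds. Anchors landing elsewhere vote for a source
locus: a right-side clip carries the insert at its head, so
`ref_pos − query_pos` projects the insert start directly; left-side clips
project the insert end and need the expected insert length (taken as the
deletion-span length, exploiting the approximately-equal-length convention)
to recover the start, so they are used only as a fallback. Estimates are
clustered within 100 bases and the cluster with the largest total anchor
mass wins, represented by its least-drifted member.

`min_anchor` defaults to 20 for tracing: at a 15% error rate exact runs of
≥ 50 bases occur in only ~4% of 500–1000 bp insert copies, while ≥ 20 base
runs occur several times per copy and a 20-mer false match against a
megabase-scale reference has probability below 1e-3.

## Phasing

SNVs (from a VCF; produced upstream by any small-variant caller, or by the
simulator) and SV calls are merged, deduplicated by (position, kind), and
scored against every read: SNVs by the aligned base; deletions/delins alt
when the read soft-clips at a breakpoint (within `clip_tol = 20`) or gaps
across ≥ 50% of the span, ref when it aligns contiguously through (< 10%
gapped), missing in between or when the span ± `sv_pad = 20` is not fully
covered; insertions alt on a long-enough insertion operation near the
breakpoint. The alternate-allele frequency `p` of each variant is the mean
over informative reads; variants with `p` outside
`[het_min, 1 − het_min]` (default 0.2) or fewer than 2 informative reads
are treated as homozygous/noise and left unphased.

Read-backed splicing joins variant pairs co-observed on at least
`min_shared = 2` reads with a clear cis/trans majority, strongest majority
first, through a parity union-find; conflicting minority reads are
outvoted. Blocks are disjoint, position-sorted and cover every phasable
variant. Secondary splicing scans adjacent blocks left to right and
computes the LD correlation `L = Σ_i Σ_j lq(i,j) · p(j)` over all
cross-block pairs, where `lq` is the covariance
`D = p(AB) − p(A)p(B)` of "read agrees with haplotype A" indicators among
reads informative at both sites (0 without co-informative reads) under the
candidate orientation, and `p(j)` is the posterior variant's alternate
frequency. The orientation with the higher `L` is accepted when
`L ≥ min_L` (default 0), the junction is recorded as `ld_spliced`, and the
scan iterates to a fixpoint (capped at one pass per block). Whole-block
flips are the only modification ever applied to existing blocks. Which
variant's frequency multiplies `lq`, and the `lq` estimator itself, are the
genuinely open design points; the posterior-frequency covariance form was
chosen because its sign flips with orientation, which the selection rule
requires (r² would be orientation-blind).

Phased output is VCF v4.2 with `GT:PS` (phase set = position of the block's
first variant); single-variant blocks are emitted unphased (`0/1`); SVs are
left-anchored with explicit REF/ALT sequences.

## Evaluation metrics

Detection: optimal 1-to-1 matching (assignment problem) between calls and
truth, a pair being admissible when types agree and both breakpoints are
within `match_tolerance = 100` bases (≪ the 500 bp minimum delins length);
precision = TP/(TP+FP), recall = TP/(TP+FN), f = 2PR/(P+R), all 0 on empty
denominators. Phasing: per block (≥ 2 variants) the assignment is compared
with truth up to a global flip; an isolated single-variant disagreement is
a mismatch error, a phase change otherwise is a switch error (an interior
flipped run of length ≥ 2 costs two switches); possible switch positions
are `n − 1` per block and possible mismatch positions `n`; N50 is computed
on block reference spans (last minus first variant position + 1),
reading haplotype completeness as genomic extent.

## Simulator

The reference is i.i.d. uniform A/C/G/T (a user FASTA can be supplied to
the CLI instead); delins delete a span drawn from `delins_len_range` and
insert a fragment of uniform 0.9–1.1 × that length copied from a random
reference locus (recorded as the truth source); pure insertions copy
fragments the same way; SVs are heterozygous, SNVs land on haplotype 0, 1
or both (0.45/0.45/0.10). Reads have Normal(read_len_mean, read_len_sd)
lengths truncated below at 200 bases, uniform fully-contained starts, a
fair haplotype coin, and i.i.d. per-base errors at `error_rate` with mix
(0.45 insertion, 0.40 deletion, 0.15 substitution) — indel-dominated as on
CLR instruments. Alignments are *projected from truth* rather than
computed: each read's edit trace is composed with the haplotype-to-reference
segment map.

Aligner behaviour at large novel inserts is emulated explicitly, since no
real mapper is run: a read crossing a delins/insertion is soft-clipped on
its shorter-anchor side with probability
`clip_prob · min(1, error_rate/0.15)` (default `clip_prob = 0.3`) and
otherwise bridged as I + D operations; reads starting or ending inside the
inserted fragment are always clipped there; pure deletions always bridge as
D. The error scaling encodes that a real aligner bridges confidently at low
error; the clipped fraction at 15% error supplies the soft-clip clusters that
breakpoint resolution needs while the bridged fraction keeps the
deleted-span density signal near 0.5. Reads are forward-strand with
constant base quality; the haplotype of origin is stored in an `HP` tag
for debugging and never read by the caller.

What the simulator does *not* model — and what passing tests therefore do
not demonstrate — includes: context-dependent and homopolymer error
clustering, chimeric reads, coverage biases, multi-contig genomes,
reverse-strand alignment asymmetries, and real aligner artefacts such as
ambiguous gap placement near tandem repeats. Results on real BLASR/minimap2
alignments will be correspondingly noisier, and the CLI accepts such
alignments directly for that purpose.

## Problem sizes used in the checks

The shipped acceptance checks run the published design at reduced scale —
1 Mbp genomes with 20 delins instead of 10 Mbp with 100, ten seeded
replicates, plus five-seed arms at depth 5×/15× and delins lengths
500/1000 bp — chosen so a full verification pass completes in minutes on a
single CPU while keeping ≥ 20 variants per replicate for stable rates.

## Numerical choices and degenerate inputs

- Window averages use full convolution with an explicit centre slice so
  tracks shorter than the window remain correctly centred.
- Weight renormalisation tolerance 1e-12; score values clipped to [0, 1]
  against floating-point drift.
- Breakpoint means round half-up; Tukey quartiles use linear interpolation.
- Ties: classification (margin sum, then class order), LD orientation
  (`same` wins at equality), region runs (score exactly `T` breaks a run).
- Zero-depth sites score 0; empty truth/call/variant sets produce valid
  empty outputs; a region with no overlapping reads is dropped with a
  logged warning.
- All randomness flows from explicit seeds (numpy `SeedSequence` children
  per stage), and reruns are byte-identical.

## Known limitations

- Pure insertions rarely produce a density plateau (the insertion anchor is
  a point event), so insertion recall from the density scan is poor; they
  are retained as a class mainly to keep the classifier honest.
- Homozygous SVs are excluded from phasing by the heterozygosity gate and
  genotypes are not otherwise called.
- Inserted sequence in the output is reconstructed from the traced source
  locus (or a representative clipped read) and is approximate at high error
  rates; breakpoints and source loci are the precise quantities.
- One contig per run; split-read (supplementary-alignment) evidence and
  inversion/translocation classes are out of scope.
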