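"""End-to-end orchestration of the five calling stages.

The stages (density scan, region classification, breakpoint resolution,
insert tracing, phasing) are chained behind plain functions that the CLI
wraps thinly.  All randomness derives from the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import breakpoints as bp
from . import classify, density, metrics, phasing, simdata
from .alignments import AlnStore
from .config import PipelineConfig, SimConfig
from .simdata import SimResult, TruthVariant, encode

log = logging.getLogger("delinscan")


@dataclass
class VariantCall:
    """A typed structural-variant call with resolved breakpoints."""

    id: str
    vtype: str  # deletion | insertion | delins
    start: int  # first deleted base (end + 1 for pure insertions)
    end: int  # last deleted base
    inserted_seq: str = ""
    insert_source: Optional[int] = None
    region: Optional[Tuple[int, int]] = None
    start_support: int = 0
    end_support: int = 0
    low_confidence: bool = False
    votes: Dict[str, int] = field(default_factory=dict)
    trace_status: str = "untraced"


def run_call(
    store: AlnStore,
    reference: Union[str, np.ndarray],
    ensemble: classify.SvmEnsemble,
    cfg: Optional[PipelineConfig] = None,
) -> List[VariantCall]:
    """Density scan -> SVM typing -> breakpoints -> insert tracing."""
    cfg = cfg or PipelineConfig()
    ref = encode(reference) if isinstance(reference, str) else reference
    weights = density.weight_vector(cfg.windows_len)
    pileup = density.build_pileup(store, ref)
    track = density.smooth_track(density.score_track(pileup, weights), cfg.smooth_win)
    regions = density.call_candidate_regions(track, cfg.threshold_T, cfg.merge_gap)
    log.info("density scan: %d candidate regions", len(regions))

    calls: List[VariantCall] = []
    n_noise = 0
    for i, reg in enumerate(regions):
        try:
            feats = classify.extract_features(
                reg, store, ref, pileup, cfg.site_unmatched_thresh
            )
        except classify.NoReadsInRegion:
            log.warning("region %d-%d dropped: no overlapping reads", reg.l, reg.r)
            continue
        label, votes = classify.classify_region(feats, ensemble)
        if label == "noise":
            n_noise += 1
            continue
        right = bp.collect_softclips(store, reg, bp.RIGHT_CLIP, cfg.min_clip, cfg.windows_len)
        left = bp.collect_softclips(store, reg, bp.LEFT_CLIP, cfg.min_clip, cfg.windows_len)
        extra_s = extra_e = ()
        if label in ("deletion", "delins"):
            extra_s = bp.deletion_run_candidates(store, reg, "start", cfg.min_del_run, cfg.windows_len)
            extra_e = bp.deletion_run_candidates(store, reg, "end", cfg.min_del_run, cfg.windows_len)
        start_est = bp.locate_breakpoint(right, "start", extra_s, fallback=reg.l)
        if label == "insertion":
            # both clip sides estimate the same insertion point
            ins_cands = [ev.anchor_pos for ev in left]
            start_est = bp.locate_breakpoint(right, "start", ins_cands, fallback=reg.l)
            end_est = bp.BreakpointEstimate(
                start_est.position - 1, start_est.support, start_est.discarded,
                start_est.low_confidence,
            )
        else:
            end_est = bp.locate_breakpoint(left, "end", extra_e, fallback=reg.r)
        call = VariantCall(
            id=f"call_{len(calls) + 1}",
            vtype=label,
            start=start_est.position,
            end=end_est.position if label != "insertion" else start_est.position - 1,
            region=(reg.l, reg.r),
            start_support=start_est.support,
            end_support=end_est.support,
            low_confidence=start_est.low_confidence or end_est.low_confidence,
            votes=votes,
        )
        if call.end < call.start - 1:
            call.end = call.start - 1
        if label in ("delins", "insertion"):
            clips = right + left
            if clips:
                expected = call.end - call.start + 1 if label == "delins" else None
                trace = bp.trace_insert_source(
                    clips, reference, region=reg,
                    min_anchor=cfg.min_anchor, k=cfg.kmer_k,
                    max_iterations=cfg.max_iterations, expected_ins_len=expected,
                )
                call.trace_status = trace.status
                if trace.status == "placed":
                    call.insert_source = trace.source_locus
                    ins_len = expected or trace.matched_len
                    src0 = max(0, trace.source_locus - 1)
                    call.inserted_seq = simdata.decode(ref[src0 : src0 + ins_len])
            if not call.inserted_seq and right:
                head = max(right, key=lambda ev: ev.clip_len)
                approx = call.end - call.start + 1 if label == "delins" else head.clip_len
                call.inserted_seq = head.clipped_seq[: max(approx, 1)]
        calls.append(call)
    log.info("classification: %d calls, %d noise regions dropped", len(calls), n_noise)
    calls.sort(key=lambda c: c.start)
    for n, c in enumerate(calls):
        c.id = f"call_{n + 1}"
    return calls


# ---------------------------------------------------------------------------
# Phasing

@dataclass
class PhaseResult:
    variants: List[phasing.PhasableVariant]
    phasable: List[phasing.PhasableVariant]
    matrix: phasing.ReadAlleleMatrix
    blocks_read_backed: List[phasing.HaplotypeBlock]
    blocks: List[phasing.HaplotypeBlock]
    decisions: List[phasing.SpliceDecision]


def run_phase(
    calls: Sequence[VariantCall],
    snv_vcf: Optional[str],
    store: AlnStore,
    reference: Union[str, np.ndarray],
    cfg: Optional[PipelineConfig] = None,
) -> PhaseResult:
    """Merge variants, build the read-allele matrix, splice haplotype blocks."""
    cfg = cfg or PipelineConfig()
    variants, matrix = phasing.load_and_merge_variants(
        calls, snv_vcf, store, reference,
        het_min=cfg.het_min, pad=cfg.sv_pad, clip_tol=cfg.clip_tol, min_clip=cfg.min_clip,
    )
    phasable = [v for v in variants if v.phasable]
    sub = phasing.restrict_matrix(matrix, [v.id for v in phasable])
    blocks_rb = phasing.read_backed_splice(sub, phasable, cfg.min_shared)
    freqs = {v.id: v.p for v in phasable}
    decisions: List[phasing.SpliceDecision] = []
    blocks = phasing.secondary_splice(blocks_rb, sub, freqs, cfg.min_L, decisions)
    log.info(
        "phasing: %d/%d variants phasable, %d read-backed blocks -> %d after LD splicing",
        len(phasable), len(variants), len(blocks_rb), len(blocks),
    )
    return PhaseResult(variants, phasable, sub, blocks_rb, blocks, decisions)


# ---------------------------------------------------------------------------
# Evaluation against truth

def truth_alt_haplotypes(
    phase: PhaseResult, truth: Sequence[TruthVariant], tolerance: int = 100
) -> Dict[str, int]:
    """Map phased variant ids to the truth haplotype carrying the alt allele.

    SNVs match by exact position; SVs by type within the breakpoint
    tolerance.  Heterozygous truth only; unmatched variants are omitted.
    """
    out: Dict[str, int] = {}
    snv_truth = {t.start: t for t in truth if t.vtype == "snv" and t.haplotype in ("0", "1")}
    sv_truth = [t for t in truth if t.vtype != "snv" and t.haplotype in ("0", "1")]
    from types import SimpleNamespace

    sv_vars = [
        SimpleNamespace(id=v.id, vtype=v.kind, start=v.position, end=v.end)
        for v in phase.phasable
        if v.kind != "snv"
    ]
    m = metrics.match_calls(sv_vars, sv_truth, tolerance=tolerance, require_type=False)
    for vi, ti in m.pairs:
        out[sv_vars[vi].id] = int(sv_truth[ti].haplotype)
    for v in phase.phasable:
        if v.kind == "snv" and v.position in snv_truth:
            out[v.id] = int(snv_truth[v.position].haplotype)
    return out


def restrict_blocks(
    blocks: Sequence[phasing.HaplotypeBlock], keep: Dict[str, int]
) -> List[phasing.HaplotypeBlock]:
    """Drop variants without truth assignment (keeps junction order)."""
    out = []
    for b in blocks:
        vids = [v for v in b.variant_ids if v in keep]
        if not vids:
            continue
        out.append(
            phasing.HaplotypeBlock(
                b.id, vids, {v: b.alleles[v] for v in vids},
                {v: b.positions[v] for v in vids}, ["restricted"] * (len(vids) - 1),
            )
        )
    return out


def evaluate_detection(
    calls: Sequence[VariantCall],
    truth: Sequence[TruthVariant],
    tolerance: int = 100,
    vtype: Optional[str] = None,
) -> metrics.DetectionReport:
    cs = [c for c in calls if vtype is None or c.vtype == vtype]
    ts = [t for t in truth if t.vtype != "snv" and (vtype is None or t.vtype == vtype)]
    return metrics.precision_recall_f(metrics.match_calls(cs, ts, tolerance))


def evaluate_phasing(
    phase: PhaseResult,
    truth: Sequence[TruthVariant],
    blocks: Optional[Sequence[phasing.HaplotypeBlock]] = None,
    tolerance: int = 100,
) -> metrics.PhasingReport:
    keep = truth_alt_haplotypes(phase, truth, tolerance)
    use = phase.blocks if blocks is None else blocks
    return metrics.phasing_report(restrict_blocks(use, keep), keep)


# ---------------------------------------------------------------------------
# Replicate convenience (simulate -> call -> phase -> evaluate)

@dataclass
class ReplicateResult:
    sim: SimResult
    store: AlnStore
    calls: List[VariantCall]
    detection: metrics.DetectionReport
    detection_delins: metrics.DetectionReport
    phase: Optional[PhaseResult] = None
    phasing_final: Optional[metrics.PhasingReport] = None
    phasing_read_backed: Optional[metrics.PhasingReport] = None


def run_replicate(
    sim_cfg: SimConfig,
    ensemble: classify.SvmEnsemble,
    cfg: Optional[PipelineConfig] = None,
    do_phase: bool = True,
    workdir: Optional[str] = None,
) -> ReplicateResult:
    """Simulate one dataset and run the full pipeline against its truth."""
    cfg = cfg or PipelineConfig(sim=sim_cfg)
    sim = simdata.simulate(sim_cfg)
    store = AlnStore.from_records(sim.records, sim.ref_name, len(sim.reference))
    calls = run_call(store, sim.reference, ensemble, cfg)
    det = evaluate_detection(calls, sim.truth, cfg.match_tolerance)
    det_delins = evaluate_detection(calls, sim.truth, cfg.match_tolerance, vtype="delins")
    result = ReplicateResult(sim, store, calls, det, det_delins)
    if do_phase:
        snv_vcf = None
        if workdir is not None:
            os.makedirs(workdir, exist_ok=True)
            snv_vcf = os.path.join(workdir, "truth_snv.vcf")
        else:
            import tempfile

            tmp = tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False)
            snv_vcf = tmp.name
            tmp.close()
        simdata.write_truth_files(
            [t for t in sim.truth if t.vtype == "snv"],
            snv_vcf, snv_vcf + ".bed", sim.reference, sim.ref_name,
        )
        try:
            phase = run_phase(calls, snv_vcf, store, sim.reference, cfg)
            result.phase = phase
            result.phasing_final = evaluate_phasing(phase, sim.truth, tolerance=cfg.match_tolerance)
            result.phasing_read_backed = evaluate_phasing(
                phase, sim.truth, blocks=phase.blocks_read_backed, tolerance=cfg.match_tolerance
            )
        finally:
            if workdir is None:
                os.unlink(snv_vcf)
                if os.path.exists(snv_vcf + ".bed"):
                    os.unlink(snv_vcf + ".bed")
    return result


# ---------------------------------------------------------------------------
# Tables / reports

def calls_table(calls: Sequence[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.id, "type": c.vtype, "start": c.start, "end": c.end,
                "insert_len": len(c.inserted_seq), "insert_source": c.insert_source,
                "start_support": c.start_support, "end_support": c.end_support,
                "low_confidence": c.low_confidence, "trace_status": c.trace_status,
            }
            for c in calls
        ]
    )


def blocks_table(blocks: Sequence[phasing.HaplotypeBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "block": b.id, "n_variants": len(b), "start": b.span[0],
                "end": b.span[1], "variants": ",".join(b.variant_ids),
                "provenance": ",".join(b.provenance),
            }
            for b in blocks
        ]
    )


def detection_report_dict(rep: metrics.DetectionReport) -> Dict:
    return dataclasses.asdict(rep)


def write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
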