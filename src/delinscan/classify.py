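"""Region typing with pairwise (one-vs-one) SVMs and majority voting.

Each candidate region is summarised by six CIGAR-derived features and
classified as deletion / insertion / delins / noise by m(m-1)/2 binary RBF
SVMs, one per unordered class pair, with the most-voted label winning.
Ties break by summed decision-function margin, then by fixed class order.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .alignments import AlnStore, _expand
from .density import CandidateRegion, Pileup
from .simdata import OP_D, OP_I, OP_M, encode

CLASSES = ("deletion", "delins", "insertion", "noise")

FEATURE_NAMES = (
    "ins_rate",
    "del_rate",
    "mismatch_rate",
    "max_consec_unmatched_ratio",
    "region_len",
    "mean_depth",
)


@dataclass
class RegionFeatures:
    """CIGAR-operation rates of the reads overlapping a candidate region.

    Rates are fractions of all in-region alignment columns (M + I + D ops of
    overlapping reads, restricted to the region); the consecutive-unmatched
    ratio is the longest run of high-discordance sites over the region length.
    """

    ins_rate: float
    del_rate: float
    mismatch_rate: float
    max_consec_unmatched_ratio: float
    region_len: int
    mean_depth: float

    def vector(self) -> np.ndarray:
        return np.array(
            [
                self.ins_rate,
                self.del_rate,
                self.mismatch_rate,
                self.max_consec_unmatched_ratio,
                float(self.region_len),
                self.mean_depth,
            ]
        )

    def validate(self) -> None:
        v = self.vector()
        if not np.isfinite(v).all():
            raise ValueError(f"non-finite feature values: {self}")
        for name in ("ins_rate", "del_rate", "mismatch_rate", "max_consec_unmatched_ratio"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"feature {name}={x} outside [0, 1]")
        if self.region_len < 1:
            raise ValueError("region_len must be >= 1")


class NoReadsInRegion(ValueError):
    """Raised when a candidate region is covered by no alignment."""


def extract_features(
    region: CandidateRegion,
    store: AlnStore,
    reference,
    pileup: Optional[Pileup] = None,
    site_unmatched_thresh: float = 0.3,
    edge_pad: int = 50,
) -> RegionFeatures:
    """Compute the feature vector of one candidate region.

    The pileup (recomputed over the region if not supplied) provides the
    consecutive-unmatched run and the mean depth; the per-read CIGAR walk
    provides the insertion / deletion / mismatch column rates.  Insertion
    anchors are point events that can fall a few sites outside the called
    bounds (region edges are smoothed-score crossings), so they are counted
    within `edge_pad` sites of the region as well.
    """
    from .density import build_pileup  # local import to avoid cycle at import time

    ref = encode(reference) if isinstance(reference, str) else reference
    l0, r0 = region.l - 1, region.r  # 0-based half-open
    alns = store.overlapping(l0, r0)
    if not alns:
        raise NoReadsInRegion(f"no reads overlap region {region.l}-{region.r}")

    ins_b = del_b = mism_b = m_b = 0
    for a in alns:
        rs = a.run_ref_starts()
        qs = a.run_query_starts()
        m = a.ops == OP_M
        if m.any():
            starts = np.maximum(rs[m], l0)
            ends = np.minimum(rs[m] + a.lens[m], r0)
            span = np.maximum(ends - starts, 0)
            m_b += int(span.sum())
            if a.seq.size:
                sel = span > 0
                if sel.any():
                    roff = starts[sel]
                    qoff = qs[m][sel] + (starts[sel] - rs[m][sel])
                    rpos = _expand(roff, span[sel])
                    qpos = _expand(qoff, span[sel])
                    mism_b += int((a.seq[qpos] != ref[rpos]).sum())
        dmask = a.ops == OP_D
        if dmask.any():
            span = np.minimum(rs[dmask] + a.lens[dmask], r0) - np.maximum(rs[dmask], l0)
            del_b += int(np.maximum(span, 0).sum())
        imask = a.ops == OP_I
        if imask.any():
            anchors = rs[imask] - 1
            inside = (anchors >= l0 - edge_pad) & (anchors < r0 + edge_pad)
            ins_b += int(a.lens[imask][inside].sum())

    denom = max(m_b + del_b + ins_b, 1)
    if pileup is None:
        pileup = build_pileup(store, ref, region=(region.l, region.r))
    p = pileup.proportions()[l0:r0]
    d = pileup.d[l0:r0]
    hot = p >= site_unmatched_thresh
    max_run = 0
    run = 0
    for h in hot:  # region-sized loop; regions are short
        run = run + 1 if h else 0
        max_run = max(max_run, run)
    n_sites = r0 - l0
    return RegionFeatures(
        ins_rate=ins_b / denom,
        del_rate=del_b / denom,
        mismatch_rate=mism_b / denom,
        max_consec_unmatched_ratio=max_run / n_sites,
        region_len=n_sites,
        mean_depth=float(d.mean()),
    )


# ---------------------------------------------------------------------------
# One-vs-one ensemble

@dataclass
class SvmEnsemble:
    classes: Tuple[str, ...]
    models: Dict[Tuple[str, str], SVC]
    scaler: StandardScaler
    feature_names: Tuple[str, ...] = FEATURE_NAMES
    schema_version: int = 1

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str) -> "SvmEnsemble":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise ValueError(f"{path} does not contain a {cls.__name__}")
        return obj


def train_ensemble(
    labeled: Sequence[Tuple[RegionFeatures, str]],
    classes: Sequence[str] = CLASSES,
    seed: int = 0,
    C: float = 1.0,
    gamma: str = "scale",
) -> SvmEnsemble:
    """Fit one binary RBF SVM per unordered class pair on standardized features."""
    classes = tuple(classes)
    X = np.vstack([f.vector() for f, _ in labeled])
    y = np.array([lab for _, lab in labeled])
    for c in classes:
        n = int((y == c).sum())
        if n == 0:
            raise ValueError(f"no training examples for class {c!r}")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    models: Dict[Tuple[str, str], SVC] = {}
    for a, b in combinations(classes, 2):
        sel = (y == a) | (y == b)
        clf = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
        clf.fit(Xs[sel], (y[sel] == b).astype(int))
        models[(a, b)] = clf
    return SvmEnsemble(classes, models, scaler)


def classify_region(
    features: RegionFeatures, ensemble: SvmEnsemble
) -> Tuple[str, Dict[str, int]]:
    """Majority vote over all pairwise models; returns (label, vote counts)."""
    features.validate()
    x = ensemble.scaler.transform(features.vector()[None, :])
    votes = {c: 0 for c in ensemble.classes}
    margins = {c: 0.0 for c in ensemble.classes}
    for (a, b), clf in ensemble.models.items():
        df = float(clf.decision_function(x)[0])  # >0 favours class b
        winner = b if df > 0 else a
        votes[winner] += 1
        margins[a] -= df
        margins[b] += df
    best = max(votes.values())
    tied = [c for c in ensemble.classes if votes[c] == best]
    if len(tied) > 1:
        mbest = max(margins[c] for c in tied)
        tied = sorted(c for c in tied if margins[c] == mbest)
    return tied[0], votes


# ---------------------------------------------------------------------------
# Training-corpus generation

def make_training_set(
    seed: int = 0,
    error_rates: Sequence[float] = (0.0, 0.05, 0.10, 0.15),
    depths: Sequence[float] = (25.0, 10.0),
    per_type: int = 7,
    ref_length: int = 400_000,
    windows_len: int = 50,
    threshold_T: float = 0.25,
) -> List[Tuple[RegionFeatures, str]]:
    """Simulate truth-labelled regions across error rates and depths.

    Density-called regions are labelled by overlap with the planted truth
    (unmatched regions become `noise`); variants the scan missed contribute
    truth-derived regions so every class is represented at every condition;
    extra noise examples are drawn from variant-free intervals.
    """
    from .config import SimConfig
    from .density import build_pileup, call_candidate_regions, score_track, smooth_track, weight_vector
    from .simdata import simulate
    from .alignments import AlnStore

    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    weights = weight_vector(windows_len)
    out: List[Tuple[RegionFeatures, str]] = []
    type_of = {"delins": "delins", "insertion": "insertion", "deletion": "deletion"}
    conditions = [(err, dep) for err in error_rates for dep in depths]
    for err, depth in conditions:
        cfg = SimConfig(
            ref_length=ref_length,
            n_delins=per_type,
            n_ins=per_type,
            n_del=per_type,
            snv_rate=5e-4,
            depth=depth,
            error_rate=err,
            seed=int(rng.integers(2**31 - 1)),
        )
        sim = simulate(cfg)
        store = AlnStore.from_records(sim.records, sim.ref_name, len(sim.reference))
        ref = encode(sim.reference)
        pileup = build_pileup(store, ref)
        track = smooth_track(score_track(pileup, weights), windows_len)
        regions = call_candidate_regions(track, threshold_T, merge_gap=2 * windows_len)
        svs = sim.sv_truth
        matched = set()
        for reg in regions:
            lab = "noise"
            for v in svs:
                if reg.l <= max(v.end, v.start) and reg.r >= v.start:
                    lab = type_of[v.vtype]
                    matched.add(v.id)
                    break
            try:
                out.append((extract_features(reg, store, ref, pileup), lab))
            except NoReadsInRegion:
                continue
        for v in svs:  # variants the scan missed (mostly insertions)
            if v.id in matched:
                continue
            reg = CandidateRegion(
                sim.ref_name,
                max(1, v.start - windows_len),
                min(len(sim.reference), max(v.end, v.start) + windows_len),
                0.0,
                threshold_T,
            )
            try:
                out.append((extract_features(reg, store, ref, pileup), type_of[v.vtype]))
            except NoReadsInRegion:
                continue
        # variant-free noise intervals
        occupied = [(v.start - 2000, max(v.end, v.start) + 2000) for v in svs]
        added = 0
        attempts = 0
        while added < per_type and attempts < 200:
            attempts += 1
            ln = int(rng.integers(150, 1200))
            s = int(rng.integers(1, ref_length - ln))
            if any(s <= b and s + ln >= a for a, b in occupied):
                continue
            reg = CandidateRegion(sim.ref_name, s, s + ln - 1, 0.0, threshold_T)
            try:
                out.append((extract_features(reg, store, ref, pileup), "noise"))
                added += 1
            except NoReadsInRegion:
                continue
    return out


def default_ensemble(seed: int = 0, **kwargs) -> SvmEnsemble:
    """Train the bundled default model from a seeded simulated corpus."""
    labeled = make_training_set(seed=seed, **kwargs)
    return train_ensemble(labeled, CLASSES, seed=seed)
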