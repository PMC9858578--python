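"""Variation-density scoring and candidate-region calling.

The signal is the per-site proportion p of covering reads that carry an
unmatched base, averaged over a sliding window with discrete standard-normal
weights truncated at +-3 sigma, then smoothed with a centred moving average
and thresholded into maximal above-threshold runs.

"Unmatched" at a reference site means any CIGAR evidence of disagreement:
an aligned base differing from the reference, the site falling inside a
deletion in the read's alignment, an insertion anchored immediately after
the site, or the site being adjacent to a soft clip of the read.  Clipped
bases themselves contribute to neither the numerator nor the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .alignments import Alignment, AlnStore, _expand
from .simdata import OP_D, OP_I, OP_M, OP_S, encode


@dataclass
class SitePileup:
    """Counts at one 1-based reference site: d covering reads, u unmatched."""

    position: int
    d: int
    u: int


@dataclass
class Pileup:
    """Vectorised pileup over a whole contig (arrays indexed by 0-based site)."""

    contig: str
    d: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        if (self.u > self.d).any():
            raise ValueError("pileup invariant violated: u > d")

    def __len__(self) -> int:
        return len(self.d)

    def site(self, position: int) -> SitePileup:
        return SitePileup(position, int(self.d[position - 1]), int(self.u[position - 1]))

    def proportions(self) -> np.ndarray:
        """Per-site u/d with zero-depth sites defined as 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(self.d > 0, self.u / np.maximum(self.d, 1), 0.0)
        return p


def unmatched_proportion(site: SitePileup) -> float:
    """u/d at one site; 0 when no read covers it."""
    return site.u / site.d if site.d > 0 else 0.0


def build_pileup(
    store: AlnStore,
    reference: Union[str, np.ndarray],
    region: Optional[tuple] = None,
) -> Pileup:
    """Count covering (d) and unmatched (u) reads at every reference site.

    `region`, if given, is a 1-based inclusive (start, end) pair; counts
    outside it are zero.
    """
    ref = encode(reference) if isinstance(reference, str) else reference
    n = store.ref_len
    if len(ref) != n:
        raise ValueError(f"reference length {len(ref)} != header length {n}")
    d_diff = np.zeros(n + 1, np.int64)
    u = np.zeros(n, np.int64)
    if region is not None:
        alns: Sequence[Alignment] = store.overlapping(region[0] - 1, region[1])
    else:
        alns = list(store)
    for a in alns:
        rs = a.run_ref_starts()
        qs = a.run_query_starts()
        cover = (a.ops == OP_M) | (a.ops == OP_D)
        np.add.at(d_diff, rs[cover], 1)
        np.add.at(d_diff, rs[cover] + a.lens[cover], -1)

        upos_parts = []
        m = a.ops == OP_M
        if m.any() and a.seq.size:
            rpos = _expand(rs[m], a.lens[m])
            qpos = _expand(qs[m], a.lens[m])
            upos_parts.append(rpos[a.seq[qpos] != ref[rpos]])
        dmask = a.ops == OP_D
        if dmask.any():
            upos_parts.append(_expand(rs[dmask], a.lens[dmask]))
        imask = a.ops == OP_I
        if imask.any():
            anchors = rs[imask] - 1  # site immediately left of the insertion
            upos_parts.append(anchors[anchors >= a.pos0])
        if a.left_clip:
            upos_parts.append(np.array([a.pos0]))
        if a.right_clip:
            upos_parts.append(np.array([a.ref_end0 - 1]))
        if upos_parts:
            sites = np.unique(np.concatenate(upos_parts))
            np.add.at(u, sites, 1)
    d = np.cumsum(d_diff[:-1])
    if region is not None:
        mask = np.zeros(n, bool)
        mask[region[0] - 1 : region[1]] = True
        d = np.where(mask, d, 0)
        u = np.where(mask, u, 0)
    return Pileup(store.ref_name, d, u)


# ---------------------------------------------------------------------------
# Window weights and scores

@dataclass
class WindowWeights:
    """Discrete Gaussian window weights over offsets -windows_len..windows_len."""

    windows_len: int
    weights: np.ndarray
    raw_weights: np.ndarray = field(repr=False, default=None)

    @property
    def raw_sum(self) -> float:
        return float(self.raw_weights.sum())


def weight_vector(windows_len: int, renormalize: bool = True) -> WindowWeights:
    """Standard-normal weights sampled at 3k/windows_len, k = -w..w.

    The raw discrete weights sum to roughly the +-3 sigma Gaussian mass
    (0.9974); by default they are renormalized to sum to exactly 1 so that a
    fully-mutated window scores exactly 1.
    """
    if windows_len < 1:
        raise ValueError(f"windows_len must be >= 1, got {windows_len}")
    k = np.arange(-windows_len, windows_len + 1)
    raw = (3.0 / windows_len) * norm.pdf(3.0 * k / windows_len)
    w = raw / raw.sum() if renormalize else raw
    return WindowWeights(windows_len, w, raw)


@dataclass
class ScoreTrack:
    contig: str
    start: int  # 1-based position of scores[0]
    scores: np.ndarray
    smooth_scores: Optional[np.ndarray] = None
    win: Optional[int] = None


def _windowed_average(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Kernel-weighted average with edge truncation (weights renormalized
    over the offsets that exist at contig edges).

    Full convolution with an explicit centre slice: numpy's "same" mode
    centres on the longer operand, which is wrong for tracks shorter than
    the window.
    """
    n, m = values.size, kernel.size
    num = np.convolve(values, kernel, mode="full")[m // 2 : m // 2 + n]
    den = np.convolve(np.ones(n), kernel, mode="full")[m // 2 : m // 2 + n]
    return num / den


def score_track(pileup: Pileup, weights: WindowWeights) -> ScoreTrack:
    """Gaussian-weighted variation score at every site."""
    p = pileup.proportions()
    scores = _windowed_average(p, weights.weights)
    np.clip(scores, 0.0, 1.0, out=scores)
    return ScoreTrack(pileup.contig, 1, scores)


def smooth_track(track: ScoreTrack, win: int) -> ScoreTrack:
    """Centred moving average with half-window `win` (truncated at edges)."""
    if win < 0:
        raise ValueError("win must be >= 0")
    kernel = np.ones(2 * win + 1)
    track.smooth_scores = _windowed_average(track.scores, kernel)
    track.win = win
    return track


@dataclass
class CandidateRegion:
    """Maximal run of sites whose smoothed score exceeds the threshold."""

    contig: str
    l: int  # 1-based inclusive
    r: int
    peak_score: float
    threshold_used: float

    def __len__(self) -> int:
        return self.r - self.l + 1


def call_candidate_regions(
    track: ScoreTrack, T: float, merge_gap: int = 0
) -> List[CandidateRegion]:
    """Threshold the smoothed track into candidate regions.

    Runs require a strictly greater score (ties at exactly T break runs);
    regions separated by fewer than `merge_gap` sites are merged.
    """
    if not (0.0 < T < 1.0):
        raise ValueError(f"threshold T must lie in (0, 1), got {T}")
    s = track.smooth_scores
    if s is None:
        raise ValueError("smooth_track must be applied before region calling")
    above = s > T
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(s) - 1]])
    merged = [[int(starts[0]), int(ends[0])]]
    for a, b in zip(starts[1:], ends[1:]):
        if a - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = int(b)
        else:
            merged.append([int(a), int(b)])
    off = track.start
    return [
        CandidateRegion(track.contig, a + off, b + off, float(s[a : b + 1].max()), T)
        for a, b in merged
    ]
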