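"""Configuration objects for the simulator and the calling pipeline.

Both configs are plain dataclasses with eager validation so that a bad YAML
key or an impossible parameter combination fails before any compute starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


@dataclass
class SimConfig:
    """Parameters of the diploid-genome / CLR-read simulator.

    The defaults describe the scaled-down study condition used throughout the
    test-suite: a 1 Mbp genome carrying 20 heterozygous delins of 500-1000 bp,
    sequenced at 25x with 15 kb +- 1.5 kb reads at a 15% error rate dominated
    by spurious insertions and deletions.
    """

    ref_length: int = 1_000_000
    n_delins: int = 20
    delins_len_range: Tuple[int, int] = (500, 1000)
    n_ins: int = 0
    n_del: int = 0
    snv_rate: float = 1e-3
    depth: float = 25.0
    read_len_mean: float = 15_000.0
    read_len_sd: float = 1_500.0
    error_rate: float = 0.15
    error_mix: Tuple[float, float, float] = (0.45, 0.40, 0.15)  # ins, del, sub
    seed: int = 0
    # Aligner-behaviour emulation: probability that a read crossing a
    # delins/insertion is soft-clipped (shorter-anchor side) instead of being
    # bridged with I/D operations.  Scaled by error_rate/0.15 so that a
    # noise-free alignment bridges every variant, as a real aligner would.
    clip_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.ref_length <= 0:
            raise ConfigError(f"ref_length must be positive, got {self.ref_length}")
        if not (0.0 <= self.error_rate < 0.5):
            raise ConfigError(f"error_rate must be in [0, 0.5), got {self.error_rate}")
        mix = tuple(float(x) for x in self.error_mix)
        if len(mix) != 3 or any(x < 0 for x in mix):
            raise ConfigError(f"error_mix needs 3 nonnegative fractions, got {self.error_mix}")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ConfigError(f"error_mix must sum to 1, got sum={sum(mix)!r}")
        lo, hi = self.delins_len_range
        if not (0 < lo <= hi):
            raise ConfigError(f"delins_len_range min must be <= max, got {self.delins_len_range}")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.read_len_mean <= 0:
            raise ConfigError("read_len_mean must be positive")
        if not (0.0 <= self.clip_prob <= 1.0):
            raise ConfigError("clip_prob must be in [0, 1]")
        if self.snv_rate < 0 or self.snv_rate >= 1:
            raise ConfigError("snv_rate must be in [0, 1)")
        self.error_mix = mix
        self.delins_len_range = (int(lo), int(hi))


@dataclass
class PipelineConfig:
    """Tunables of the five calling/phasing stages.

    windows_len
        Half-window (in sites) of the Gaussian variation-score kernel.
    smooth_win
        Half-window of the moving-average smoother; defaults to windows_len.
    threshold_T
        Smoothed-score threshold for candidate regions.  The noise floor at a
        15% error rate sits near 0.15 while a heterozygous delins plateau sits
        near 0.4-0.5 (the non-variant haplotype keeps covering the span), so
        0.25 separates the two with a wide margin on both sides.
    merge_gap
        Candidate regions closer than this many sites are merged.
    min_clip
        Soft clips must be strictly longer than this to count as breakpoint
        evidence.
    min_del_run
        CIGAR deletion runs at least this long also contribute breakpoint
        candidates (exact at zero noise, where an aligner bridges the variant
        and leaves no clips).
    min_anchor / kmer_k
        Exact-match anchor length and seed size for insert-source tracing.
    het_min
        Alternate-allele-frequency gate: variants with p outside
        [het_min, 1 - het_min] are treated as homozygous/noise and left
        unphased.
    min_shared / min_L
        Read-backed junction support and LD splicing acceptance threshold.
    match_tolerance
        Breakpoint distance (bases) within which a call matches a truth
        record during evaluation.
    """

    windows_len: int = 50
    smooth_win: Optional[int] = None
    threshold_T: float = 0.25
    merge_gap: Optional[int] = None
    site_unmatched_thresh: float = 0.3
    min_clip: int = 50
    min_del_run: int = 100
    min_support: int = 1
    min_anchor: int = 20
    kmer_k: int = 13
    max_iterations: int = 3
    het_min: float = 0.2
    min_shared: int = 2
    min_L: float = 0.0
    match_tolerance: int = 100
    sv_pad: int = 20
    clip_tol: int = 20
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.windows_len < 1:
            raise ConfigError("windows_len must be >= 1")
        if self.smooth_win is None:
            self.smooth_win = self.windows_len
        if self.smooth_win < 0:
            raise ConfigError("smooth_win must be >= 0")
        if not (0.0 < self.threshold_T < 1.0):
            raise ConfigError(f"threshold_T must lie in (0, 1), got {self.threshold_T}")
        if self.merge_gap is None:
            self.merge_gap = 2 * self.windows_len
        if not (0.0 < self.het_min < 0.5):
            raise ConfigError("het_min must lie in (0, 0.5)")
        if self.min_shared < 1:
            raise ConfigError("min_shared must be >= 1")
        if self.match_tolerance < 0:
            raise ConfigError("match_tolerance must be >= 0")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)


def _fields(cls) -> set:
    return {f.name for f in dataclasses.fields(cls)}


def load_config(path: str) -> PipelineConfig:
    """Load a PipelineConfig from YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _fields(PipelineConfig)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    sim_raw = raw.get("sim", {})
    if sim_raw:
        bad = set(sim_raw) - _fields(SimConfig)
        if bad:
            raise ConfigError(f"unknown sim config keys: {sorted(bad)}")
        sim_raw = {k: tuple(v) if isinstance(v, list) else v for k, v in sim_raw.items()}
        raw = dict(raw, sim=SimConfig(**sim_raw))
    return PipelineConfig(**raw)


def dump_config(cfg: PipelineConfig, path: str) -> None:
    """Write the fully-resolved configuration next to a run's outputs."""
    data = dataclasses.asdict(cfg)
    data["sim"]["error_mix"] = list(cfg.sim.error_mix)
    data["sim"]["delins_len_range"] = list(cfg.sim.delins_len_range)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
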