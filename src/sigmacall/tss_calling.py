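"""Transcription start site (TSS) calling from per-position 5'-end read counts.

The input is the 5'-end read-start profile of a Cappable-seq style library: for
every genomic position and strand, the number of reads whose first transcribed
base maps there.  Positions are scored as RRS (relative read score, reads per
million mapped reads), clustered to absorb the +-few-bp imprecision of TSS
determination, optionally normalized against a non-enriched control library,
and finally intersected across biological replicates.

Coordinates are 1-based and inclusive throughout; minus-strand positions refer
to the same forward coordinate system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence

__all__ = [
    "ReadStartProfile",
    "TssCandidate",
    "TssRecord",
    "TssCallingConfig",
    "compute_rrs",
    "cluster_positions",
    "score_candidates",
    "merge_replicates",
    "call_tss",
]


class InvalidInputError(ValueError):
    """Raised when an operation receives input violating its preconditions."""


@dataclass
class ReadStartProfile:
    """Per-position, per-strand 5'-end read counts for one library/replicate.

    ``total_reads`` is the total number of mapped reads of the library across
    all replicons and strands (the RRS denominator), which may exceed the sum
    of the counts stored here when the profile covers only part of the genome.
    """

    replicon_id: str
    strand: str
    counts: Dict[int, int]
    total_reads: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvalidInputError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.total_reads < 0:
            raise InvalidInputError("total_reads must be non-negative")
        for pos, n in self.counts.items():
            if pos < 1:
                raise InvalidInputError(f"position {pos} is not 1-based")
            if n < 0:
                raise InvalidInputError(f"negative count at position {pos}")

    def validate_against_length(self, replicon_length: int) -> None:
        for pos in self.counts:
            if pos > replicon_length:
                raise InvalidInputError(
                    f"position {pos} exceeds replicon length {replicon_length}"
                )


@dataclass
class TssCandidate:
    """A clustered TSS peak from a single replicate.

    ``rrs`` is the pooled RRS of the cluster (reads per million); ``score`` is
    the per-replicate TSS quality score (RRS ratio against the control, or the
    RRS itself in control-free mode).
    """

    replicon_id: str
    strand: str
    position: int
    rrs: float
    rrs_control: Optional[float] = None
    score: float = 0.0
    control_floored: bool = False


@dataclass
class TssRecord:
    """A replicate-consensus TSS with its mean quality score."""

    name: str
    replicon_id: str
    strand: str
    position: int
    mean_score: float
    score_sd: float
    replicate_scores: List[float] = field(default_factory=list)


@dataclass
class TssCallingConfig:
    """Cutoffs and modes for TSS calling.

    ``rrs_cutoff`` (inclusive, keep RRS >= cutoff) removes sparse background
    read starts; ``cluster_radius`` pools RRS within +-radius bp into the local
    maximum; the per-replicate and consensus score cutoffs are strict (keep
    score > cutoff).  ``control_mode`` selects the quality score: ``ratio``
    divides the enriched RRS by the pooled control RRS, ``control_free`` uses
    the enriched RRS directly.
    """

    rrs_cutoff: float = 5.0
    cluster_radius: int = 5
    consensus_score_cutoff: float = 10.0
    per_replicate_score_cutoff: float = 5.0
    control_mode: str = "control_free"

    def __post_init__(self) -> None:
        if self.cluster_radius < 0:
            raise InvalidInputError("cluster_radius must be >= 0")
        for name in ("rrs_cutoff", "consensus_score_cutoff", "per_replicate_score_cutoff"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.control_mode not in ("ratio", "control_free"):
            raise InvalidInputError("control_mode must be 'ratio' or 'control_free'")


def compute_rrs(profile: ReadStartProfile) -> Dict[int, float]:
    """RRS_io = (n_io / N) * 1e6 for every position with a nonzero count."""
    if profile.total_reads <= 0:
        raise InvalidInputError("total_reads must be positive to compute RRS")
    scale = 1e6 / profile.total_reads
    return {pos: n * scale for pos, n in profile.counts.items() if n > 0}


def cluster_positions(rrs: Mapping[int, float], radius: int) -> List[TssCandidate]:
    """Greedy clustering of RRS values into local maxima.

    Repeatedly takes the unconsumed position with the highest RRS (ties broken
    toward the smaller coordinate), sums all unconsumed RRS within +-radius bp
    into it, and marks those positions consumed.  Every input position belongs
    to exactly one cluster, so pooled RRS mass is conserved, and returned peaks
    are pairwise more than ``radius`` apart.

    Replicon and strand of the returned candidates are left empty; callers
    embed the result into its track context.
    """
    if radius < 0:
        raise InvalidInputError("radius must be >= 0")
    order = sorted(rrs, key=lambda p: (-rrs[p], p))
    positions = sorted(rrs)
    consumed: set = set()
    peaks: List[TssCandidate] = []
    import bisect

    for peak in order:
        if peak in consumed:
            continue
        lo = bisect.bisect_left(positions, peak - radius)
        hi = bisect.bisect_right(positions, peak + radius)
        pooled = 0.0
        for p in positions[lo:hi]:
            if p not in consumed:
                pooled += rrs[p]
                consumed.add(p)
        peaks.append(TssCandidate(replicon_id="", strand="", position=peak, rrs=pooled))
    peaks.sort(key=lambda c: c.position)
    return peaks


def _pooled_control_rrs(
    control_rrs: Mapping[int, float], position: int, radius: int
) -> float:
    return sum(
        v for p, v in control_rrs.items() if position - radius <= p <= position + radius
    )


def score_candidates(
    tss: Sequence[TssCandidate],
    control_rrs: Optional[Mapping[int, float]],
    cfg: TssCallingConfig,
) -> List[TssCandidate]:
    """Attach per-replicate quality scores and apply per-replicate cutoffs.

    In ``ratio`` mode the score at each peak is its pooled RRS divided by the
    control RRS pooled with the same cluster radius around the peak; a zero
    pooled control is replaced by a pseudo-count floor equal to the smallest
    nonzero control RRS in the track (flagged via ``control_floored``).  In
    ``control_free`` mode the score is the pooled RRS itself.

    Candidates with ``rrs < rrs_cutoff`` or ``score <= per_replicate_score_cutoff``
    are dropped.
    """
    if cfg.control_mode == "ratio" and control_rrs is None:
        raise InvalidInputError("ratio mode requires a control track")
    if cfg.control_mode == "control_free" and control_rrs is not None:
        control_rrs = None  # control is ignored without error in control-free mode

    floor = None
    if control_rrs:
        nonzero = [v for v in control_rrs.values() if v > 0]
        floor = min(nonzero) if nonzero else None

    out: List[TssCandidate] = []
    for cand in tss:
        if cand.rrs < cfg.rrs_cutoff:
            continue
        if cfg.control_mode == "ratio":
            pooled = _pooled_control_rrs(control_rrs, cand.position, cfg.cluster_radius)
            floored = False
            if pooled <= 0:
                if floor is None:
                    raise InvalidInputError(
                        "control track has no nonzero RRS; cannot form a ratio floor"
                    )
                pooled = floor
                floored = True
            scored = replace(
                cand, rrs_control=pooled, score=cand.rrs / pooled, control_floored=floored
            )
        else:
            scored = replace(cand, score=cand.rrs)
        if scored.score > cfg.per_replicate_score_cutoff:
            out.append(scored)
    return out


def format_tss_name(position: int, strand: str, replicon_digit: int) -> str:
    """Names follow the schema ``TSS_<position><strand><replicon digit>``."""
    return f"TSS_{position}{strand}{replicon_digit}"


def _replicon_digit(replicon_id: str) -> int:
    last = replicon_id.rstrip()[-1:]
    if not last.isdigit():
        raise InvalidInputError(
            f"cannot derive a replicon digit from id {replicon_id!r}; "
            "ids must end in a digit (e.g. an accession like CP000352)"
        )
    return int(last)


def merge_replicates(
    replicates: Sequence[Sequence[TssCandidate]], cfg: TssCallingConfig
) -> List[TssRecord]:
    """Intersect per-replicate peak lists into consensus TSS records.

    Only peaks present at the same (replicon, strand, clustered position) in
    every replicate are kept; per-replicate +-radius jitter has already been
    absorbed by clustering.  The mean quality score must strictly exceed the
    consensus cutoff.  Output is sorted by descending mean score (ties by
    replicon, position, strand for determinism).
    """
    if not replicates:
        raise InvalidInputError("at least one replicate is required")

    keyed = [
        {(c.replicon_id, c.strand, c.position): c for c in rep} for rep in replicates
    ]
    shared = set(keyed[0])
    for k in keyed[1:]:
        shared &= set(k)

    records: List[TssRecord] = []
    for key in shared:
        replicon_id, strand, position = key
        scores = [k[key].score for k in keyed]
        mean = sum(scores) / len(scores)
        if mean <= cfg.consensus_score_cutoff:
            continue
        if len(scores) > 1:
            var = sum((s - mean) ** 2 for s in scores) / (len(scores) - 1)
            sd = math.sqrt(var)
        else:
            sd = 0.0
        records.append(
            TssRecord(
                name=format_tss_name(position, strand, _replicon_digit(replicon_id)),
                replicon_id=replicon_id,
                strand=strand,
                position=position,
                mean_score=mean,
                score_sd=sd,
                replicate_scores=scores,
            )
        )
    records.sort(key=lambda r: (-r.mean_score, r.replicon_id, r.position, r.strand))
    return records


def call_tss(
    tss_profiles: Sequence[ReadStartProfile],
    control_profiles: Optional[Sequence[ReadStartProfile]],
    cfg: TssCallingConfig,
) -> List[TssRecord]:
    """Full per-track pipeline: RRS, clustering, scoring, replicate consensus.

    ``tss_profiles`` holds one profile per replicate for a single replicon and
    strand; ``control_profiles`` (optional, same order) the matching control
    replicates.
    """
    if control_profiles is not None and len(control_profiles) != len(tss_profiles):
        raise InvalidInputError("one control profile per replicate is required")
    per_replicate: List[List[TssCandidate]] = []
    for i, prof in enumerate(tss_profiles):
        rrs = compute_rrs(prof)
        peaks = cluster_positions(rrs, cfg.cluster_radius)
        for p in peaks:
            p.replicon_id = prof.replicon_id
            p.strand = prof.strand
        ctrl = None
        if cfg.control_mode == "ratio" and control_profiles is not None:
            ctrl = compute_rrs(control_profiles[i])
        per_replicate.append(score_candidates(peaks, ctrl, cfg))
    return merge_replicates(per_replicate, cfg)
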