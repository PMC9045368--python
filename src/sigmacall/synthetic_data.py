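"""Synthetic genomes, planted promoters and replicate 5'-end read tracks.

The generator emulates the statistical structure the pipeline assumes so that
every stage can be exercised without sequencing data: a random high-GC genome
with promoters planted at known TSSs (-35 and -10 consensus hexamers written
into the sequence at positions drawn from the empirically observed
distributions, with per-position mutation), an enriched library whose reads
concentrate at the planted TSSs with small rounded-Gaussian start jitter
(truncated to +-5 bp, the cluster radius), a uniform processed-end background
on both strands, and a non-enriched control library in which true starts are
captured ``enrichment_factor`` times less efficiently.

The synthetic replicon is treated as a window of a larger genome: the library
size used for RRS normalization (``total_library_reads``) is configured
independently of the reads placed on the window, as in real data where most
reads map elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .promoters import RepliconSequence
from .rpod_scoring import DEFAULT_CONSTANTS, MotifMatchPair, rpod_score
from .tss_calling import ReadStartProfile

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

__all__ = ["SyntheticConfig", "PlantedPromoter", "SyntheticDataset", "generate"]


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate the study conditions.

    Promoter geometry follows the observed housekeeping-promoter statistics:
    the -10 model position is tightly constrained (-13.7 +- 0.9 bp) while the
    spacer varies (15.8 +- 1.4 nt) and the -35 position is derived from the
    two, which reproduces its observed spread of +-1.6 bp.  Mutation rates are
    calibrated to the per-position consensus identity of the housekeeping
    table (about 0.65 for TTGACA, about 0.85 for TATAAT).  Start jitter of
    about +-1 bp matches the reported positional accuracy of TSS
    determination and is truncated at +-5 bp, the clustering radius.
    """

    replicon_length: int = 50_000
    replicon_id: str = "SYN1"
    gc_fraction: float = 0.635
    n_promoters: int = 100
    m35_mutation_rate: float = 0.35
    m10_mutation_rate: float = 0.15
    m10_pos_mean: float = -13.7
    m10_pos_sd: float = 0.9
    spacer_mean: float = 15.8
    spacer_sd: float = 1.4
    tss_jitter_sd: float = 1.0
    reads_per_tss_mean: float = 500.0
    reads_per_tss_sigma: float = 0.5
    background_rate: float = 0.05
    n_replicates: int = 3
    enrichment_factor: float = 100.0
    total_library_reads: int = 10_000_000
    min_tss_separation: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be a probability")
        for name in ("m35_mutation_rate", "m10_mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.n_promoters < 0 or self.n_replicates < 1:
            raise ValueError("n_promoters must be >= 0 and n_replicates >= 1")
        if self.replicon_length < 300:
            raise ValueError("replicon must be long enough to hold a promoter window")


@dataclass
class PlantedPromoter:
    """Ground truth for one planted promoter.

    ``m35_start`` is the TSS-relative start of the -35 hexamer; ``m10_start``
    the start of the 10-mer -10 model match (two positions before the planted
    TATAAT hexamer, mirroring the extended -10 convention).
    """

    tss_name: str
    position: int
    strand: str
    m35_start: int
    m35_hexamer: str
    m10_start: int
    m10_hexamer: str
    spacer: int
    mean_reads: float
    score: float
    true_strength_class: str


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: RepliconSequence
    promoters: List[PlantedPromoter]
    tss_tracks: List[Dict[str, ReadStartProfile]] = field(default_factory=list)
    control_tracks: List[Dict[str, ReadStartProfile]] = field(default_factory=list)

    def ground_truth(self) -> pd.DataFrame:
        return pd.DataFrame([p.__dict__ for p in self.promoters])

    def write_files(self, out_dir) -> None:
        """FASTA genome, bedGraph tracks and ground-truth TSV (plain text)."""
        from . import io_formats

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_fasta({self.genome.id: self.genome.sequence}, out / "genome.fa")
        io_formats.write_table(
            self.ground_truth(), out / "ground_truth.tsv", schema="ground_truth"
        )
        for rep, (tss, ctrl) in enumerate(zip(self.tss_tracks, self.control_tracks), 1):
            for strand, label in (("+", "fwd"), ("-", "rev")):
                io_formats.write_bedgraph(
                    tss[strand], out / f"tss_rep{rep}_{label}.bedgraph"
                )
                io_formats.write_bedgraph(
                    ctrl[strand], out / f"control_rep{rep}_{label}.bedgraph"
                )


def _draw_geometry(rng: np.random.Generator, config: SyntheticConfig):
    """Draw (-35 10-mer start, -10 10-mer start, spacer), all TSS-relative.

    The -10 model position and the spacer are the primary draws; the -35
    start is derived (m35 = m10 - spacer - 6), mirroring the observed tight
    -10 positioning with a floating -35.  Clips keep the planted elements
    fully upstream of the TSS.
    """
    m10_start = int(np.clip(np.rint(rng.normal(config.m10_pos_mean, config.m10_pos_sd)), -16, -9))
    spacer = int(np.clip(np.rint(rng.normal(config.spacer_mean, config.spacer_sd)), 12, 19))
    m35_start = m10_start - spacer - 6
    return m35_start, m10_start, spacer


def _mutate(rng: np.random.Generator, consensus: str, rate: float) -> str:
    out = []
    for base in consensus:
        if rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != base]))
        else:
            out.append(base)
    return "".join(out)


def _write_relative(genome: List[str], position: int, strand: str, rel_start: int,
                    seq: str) -> None:
    """Write ``seq`` (5'->3' on the promoter strand) at a TSS-relative start."""
    for i, base in enumerate(seq):
        rel = rel_start + i
        if strand == "+":
            genome[position + rel - 1] = base
        else:
            genome[position - rel - 1] = _COMPLEMENT[base]


def _jittered_positions(
    rng: np.random.Generator, position: int, n_reads: int, sd: float, length: int
) -> np.ndarray:
    jitter = np.rint(rng.normal(0.0, sd, size=n_reads)).astype(int)
    jitter = np.clip(jitter, -5, 5)
    return np.clip(position + jitter, 1, length)


def _counts_from_positions(positions: np.ndarray) -> Dict[int, int]:
    vals, cnts = np.unique(positions, return_counts=True)
    return {int(p): int(c) for p, c in zip(vals, cnts)}


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a genome, planted promoters and replicate read tracks.

    Reproducible: identical configs (including the seed) give identical
    datasets and, through :meth:`SyntheticDataset.write_files`, byte-identical
    files.
    """
    rng = np.random.default_rng(config.seed)
    L = config.replicon_length
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = list(rng.choice(_BASES, size=L, p=probs))

    # --- promoter placement -------------------------------------------------
    margin = 110
    positions: List[int] = []
    strands: List[str] = []
    for _ in range(config.n_promoters):
        for attempt in range(1000):
            pos = int(rng.integers(margin + 1, L - margin))
            if all(abs(pos - p) >= config.min_tss_separation for p in positions):
                positions.append(pos)
                strands.append("+" if rng.random() < 0.5 else "-")
                break
        else:
            raise RuntimeError(
                "could not place a promoter without collision after 1000 attempts; "
                "lower n_promoters or min_tss_separation"
            )

    promoters: List[PlantedPromoter] = []
    k = DEFAULT_CONSTANTS
    for pos, strand in zip(positions, strands):
        m35_start, m10_start, spacer = _draw_geometry(rng, config)
        hex10_start = m10_start + 2  # planted TATAAT sits at model positions 3-8
        m35 = _mutate(rng, k.consensus_m35, config.m35_mutation_rate)
        m10 = _mutate(rng, k.consensus_m10, config.m10_mutation_rate)
        _write_relative(genome, pos, strand, m35_start, m35)
        _write_relative(genome, pos, strand, hex10_start, m10)
        mean_reads = float(
            rng.lognormal(np.log(config.reads_per_tss_mean), config.reads_per_tss_sigma)
        )
        # analytic score of the planted promoter (10-mers padded with the
        # surrounding genomic sequence, as the discovery stage would see them)
        call = rpod_score(
            MotifMatchPair(
                m35_start,
                _read_relative(genome, pos, strand, m35_start, 10),
                m10_start,
                _read_relative(genome, pos, strand, m10_start, 10),
            ),
            k,
        )
        digit = config.replicon_id[-1] if config.replicon_id[-1].isdigit() else "1"
        promoters.append(
            PlantedPromoter(
                tss_name=f"TSS_{pos}{strand}{digit}",
                position=pos,
                strand=strand,
                m35_start=m35_start,
                m35_hexamer=m35,
                m10_start=m10_start,
                m10_hexamer=m10,
                spacer=spacer,
                mean_reads=mean_reads,
                score=call.score,
                true_strength_class=call.strength,
            )
        )

    genome_str = "".join(genome)
    replicon = RepliconSequence(id=config.replicon_id, sequence=genome_str)

    # --- read tracks --------------------------------------------------------
    tss_tracks: List[Dict[str, ReadStartProfile]] = []
    control_tracks: List[Dict[str, ReadStartProfile]] = []
    for _rep in range(config.n_replicates):
        per_strand_tss: Dict[str, List[np.ndarray]] = {"+": [], "-": []}
        per_strand_ctrl: Dict[str, List[np.ndarray]] = {"+": [], "-": []}
        for prom in promoters:
            n_true = int(rng.poisson(prom.mean_reads))
            per_strand_tss[prom.strand].append(
                _jittered_positions(rng, prom.position, n_true, config.tss_jitter_sd, L)
            )
            n_ctrl = int(rng.poisson(prom.mean_reads / config.enrichment_factor))
            per_strand_ctrl[prom.strand].append(
                _jittered_positions(rng, prom.position, n_ctrl, config.tss_jitter_sd, L)
            )
        for strand in "+-":
            n_bg = int(rng.poisson(config.background_rate * L))
            per_strand_tss[strand].append(rng.integers(1, L + 1, size=n_bg))
            n_bg = int(rng.poisson(config.background_rate * L))
            per_strand_ctrl[strand].append(rng.integers(1, L + 1, size=n_bg))
        tss_tracks.append(
            {
                strand: ReadStartProfile(
                    replicon_id=config.replicon_id,
                    strand=strand,
                    counts=_counts_from_positions(np.concatenate(per_strand_tss[strand]))
                    if per_strand_tss[strand] else {},
                    total_reads=config.total_library_reads,
                )
                for strand in "+-"
            }
        )
        control_tracks.append(
            {
                strand: ReadStartProfile(
                    replicon_id=config.replicon_id,
                    strand=strand,
                    counts=_counts_from_positions(np.concatenate(per_strand_ctrl[strand]))
                    if per_strand_ctrl[strand] else {},
                    total_reads=config.total_library_reads,
                )
                for strand in "+-"
            }
        )

    return SyntheticDataset(
        config=config,
        genome=replicon,
        promoters=promoters,
        tss_tracks=tss_tracks,
        control_tracks=control_tracks,
    )


def generate_promoter_windows(
    n_windows: int = 500,
    major_fraction: float = 0.8,
    decoy_hexamer: str = "CGGCGA",
    plant_m35: bool = True,
    config: Optional[SyntheticConfig] = None,
    seed: Optional[int] = None,
) -> "tuple[List, pd.DataFrame]":
    """Promoter windows for motif-discovery benchmarks.

    A fraction ``major_fraction`` of the 100-nt windows carries a planted
    promoter (TATAAT at the -10, and unless ``plant_m35`` is false also
    TTGACA at the -35, with per-position mutation and positions drawn as in
    :func:`generate`); the rest carry a decoy -10-like element
    (``decoy_hexamer``, same positional distribution, no -35).  Returns the
    windows and a ground-truth table with the planted window indices
    (``m10_window_idx`` is the start of the planted -10 hexamer).
    """
    from .promoters import PromoterSequence, relative_to_window_index

    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    k = DEFAULT_CONSTANTS
    gc = cfg.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    n_major = int(round(n_windows * major_fraction))
    labels = np.array(["major"] * n_major + ["decoy"] * (n_windows - n_major))
    rng.shuffle(labels)

    windows, rows = [], []
    for i, label in enumerate(labels):
        seq = list(rng.choice(_BASES, size=100, p=probs))
        m35_start, m10_start, spacer = _draw_geometry(rng, cfg)
        hex10_start = m10_start + 2
        idx10 = relative_to_window_index(hex10_start)
        if label == "major":
            m10 = _mutate(rng, k.consensus_m10, cfg.m10_mutation_rate)
            m35 = None
            if plant_m35:
                m35 = _mutate(rng, k.consensus_m35, cfg.m35_mutation_rate)
                idx35 = relative_to_window_index(m35_start)
                seq[idx35 : idx35 + 6] = list(m35)
        else:
            m35 = None
            m10 = _mutate(rng, decoy_hexamer, cfg.m10_mutation_rate)
        seq[idx10 : idx10 + 6] = list(m10)
        name = f"synthprom_{i}_{label}"
        windows.append(PromoterSequence(tss_name=name, sequence="".join(seq)))
        rows.append(
            {
                "tss_name": name,
                "label": label,
                "m35_start": m35_start if m35 is not None else None,
                "m35_hexamer": m35,
                "m10_hexamer": m10,
                "m10_window_idx": idx10,
                "spacer": spacer,
            }
        )
    return windows, pd.DataFrame(rows)


def _read_relative(genome: List[str], position: int, strand: str, rel_start: int,
                   length: int) -> str:
    """Read ``length`` nt starting at a TSS-relative position, 5'->3' on the
    promoter strand (inverse of :func:`_write_relative`)."""
    out = []
    for i in range(length):
        rel = rel_start + i
        if strand == "+":
            out.append(genome[position + rel - 1])
        else:
            out.append(_COMPLEMENT[genome[position - rel - 1]])
    return "".join(out)
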