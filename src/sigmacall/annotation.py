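"""Linking TSSs to downstream genes and the transcript-responsibility heuristic.

A TSS is linked to the nearest gene start downstream on the same strand and
replicon.  Whether a TSS can account for the observed transcript level of its
gene is judged by comparing the TSS quality score with the gene's NPKM
(nucleotide activities per kilobase of exon model per million mapped reads):
genome-wide the two quantities agree within about a factor of three, so a
contributing or responsible promoter should have a TSS score between NPKM/3
and 3x NPKM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "GeneExpressionRecord",
    "PromoterAssignment",
    "assign_tss_to_genes",
    "responsibility",
    "read_gff_genes",
    "read_expression_table",
    "annotate_tss",
]

DEFAULT_MAX_DISTANCE = 5000


@dataclass
class GeneExpressionRecord:
    """One gene with its coordinates and transcript abundance."""

    locus_tag: str
    replicon_id: str
    strand: str
    start: int
    end: int
    npkm: float = float("nan")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.locus_tag}: start must be <= end")

    @property
    def gene_start(self) -> int:
        """The transcription-proximal coordinate (5' end of the gene)."""
        return self.start if self.strand == "+" else self.end


@dataclass
class PromoterAssignment:
    tss_name: str
    locus_tag: str
    distance_bp: Optional[int]
    responsible: Optional[bool] = None
    log_ratio: Optional[float] = None


def assign_tss_to_genes(
    tss: Sequence, genes: Sequence[GeneExpressionRecord],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> List[PromoterAssignment]:
    """Link each TSS to the nearest same-strand downstream gene start.

    Distance is measured from the TSS to the gene's 5' end and is never
    negative (a TSS inside or downstream of a gene is not linked to it).
    Equidistant genes are resolved toward the smaller locus tag.  TSSs with
    no gene within ``max_distance`` are emitted with an empty locus tag.
    """
    out: List[PromoterAssignment] = []
    for rec in tss:
        best: Optional[Tuple[int, str]] = None
        for gene in genes:
            if gene.replicon_id != rec.replicon_id or gene.strand != rec.strand:
                continue
            if rec.strand == "+":
                dist = gene.gene_start - rec.position
            else:
                dist = rec.position - gene.gene_start
            if dist < 0 or dist > max_distance:
                continue
            key = (dist, gene.locus_tag)
            if best is None or key < best:
                best = key
        if best is None:
            out.append(PromoterAssignment(rec.name, "", None))
        else:
            out.append(PromoterAssignment(rec.name, best[1], best[0]))
    return out


def responsibility(score: float, npkm: float) -> Tuple[bool, Optional[float]]:
    """Is a TSS of this score responsible for a transcript level of this NPKM?

    Responsible iff NPKM/3 <= score <= 3*NPKM.  The log ratio
    log10(NPKM)/log10(score) is reported only when both values exceed 1
    (both logs positive); otherwise it is undefined.
    """
    if score <= 0:
        raise ValueError("TSS score must be positive")
    if npkm < 0:
        raise ValueError("NPKM must be non-negative")
    if npkm == 0:
        return False, None
    responsible = npkm / 3.0 <= score <= 3.0 * npkm
    log_ratio = None
    if npkm > 1 and score > 1:
        log_ratio = math.log10(npkm) / math.log10(score)
    return responsible, log_ratio


def read_gff_genes(path, expression: Optional[pd.DataFrame] = None) -> List[GeneExpressionRecord]:
    """Read gene features from a GFF3 file, optionally joining NPKM values.

    Features of type ``gene`` (or ``CDS`` when no genes are present) are used;
    the locus tag is taken from the ``locus_tag`` attribute, falling back to
    ``ID``.  ``expression`` is a DataFrame with columns locus_tag and npkm.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    ftype = "gene" if any(True for _ in db.features_of_type("gene")) else "CDS"
    npkm_map = {}
    if expression is not None:
        npkm_map = dict(zip(expression["locus_tag"], expression["npkm"]))
    genes = []
    for feat in db.features_of_type(ftype):
        locus = feat.attributes.get("locus_tag", feat.attributes.get("ID", ["?"]))[0]
        genes.append(
            GeneExpressionRecord(
                locus_tag=locus,
                replicon_id=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                npkm=float(npkm_map.get(locus, float("nan"))),
            )
        )
    return genes


def read_expression_table(path) -> pd.DataFrame:
    """TSV with at least the columns locus_tag and npkm."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"locus_tag", "npkm"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table lacks columns: {sorted(missing)}")
    return df


def annotate_tss(
    tss_records: Sequence,
    genes: Sequence[GeneExpressionRecord],
    rpod_calls: Optional[dict] = None,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> pd.DataFrame:
    """One merged row per TSS: position, score, RpoD tier, linked gene,
    distance, responsibility flag and log ratio.

    ``rpod_calls`` maps TSS name -> RpodCall (optional).
    """
    by_locus = {g.locus_tag: g for g in genes}
    assignments = assign_tss_to_genes(tss_records, genes, max_distance=max_distance)
    rows = []
    for rec, asn in zip(tss_records, assignments):
        responsible = log_ratio = npkm = None
        if asn.locus_tag and asn.locus_tag in by_locus:
            npkm = by_locus[asn.locus_tag].npkm
            if npkm is not None and not math.isnan(npkm):
                responsible, log_ratio = responsibility(rec.mean_score, npkm)
        call = (rpod_calls or {}).get(rec.name)
        rows.append(
            {
                "name": rec.name,
                "replicon": rec.replicon_id,
                "position": rec.position,
                "strand": rec.strand,
                "mean_score": rec.mean_score,
                "rpod_score": call.score if call else None,
                "rpod_tier": call.tier if call else None,
                "locus_tag": asn.locus_tag,
                "distance_bp": asn.distance_bp,
                "npkm": npkm,
                "responsible": responsible,
                "log_ratio": log_ratio,
            }
        )
    return pd.DataFrame(rows)
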