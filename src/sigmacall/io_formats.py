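"""Readers and writers shared by all pipeline stages.

Internal coordinates are 1-based and inclusive everywhere; conversion to and
from 0-based half-open intervals happens only at the bedGraph/BED boundary.
All tabular outputs are TSV files carrying a versioned schema header line
(``#sigmacall\tschema=<name>\tversion=<int>``); readers reject unknown
schemas or versions.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .tss_calling import InvalidInputError, ReadStartProfile, TssRecord

HEADER_TAG = "#sigmacall"

SCHEMA_VERSIONS = {
    "tss": 1,
    "annotations": 1,
    "rpod_calls": 1,
    "merged": 1,
    "ground_truth": 1,
    "housekeeping": 1,
    "histogram": 1,
    "logo": 1,
}

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "parse_tss_name",
    "read_fasta",
    "write_fasta",
    "write_table",
    "read_table",
    "write_tss_table",
    "read_tss_table",
    "write_annotations",
    "write_bed6",
]


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


_TSS_NAME_RE = re.compile(r"^TSS_(\d+)([+-])(\d)$")


def parse_tss_name(name: str) -> Tuple[int, str, int]:
    """Invert the ``TSS_<position><strand><replicon digit>`` naming schema."""
    m = _TSS_NAME_RE.match(name)
    if not m:
        raise ParseError(f"not a valid TSS name: {name!r}")
    return int(m.group(1)), m.group(2), int(m.group(3))


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(
    path, strand: str, total_reads: Optional[int] = None
) -> List[ReadStartProfile]:
    """Read a 4-column bedGraph into per-replicon read-start profiles.

    bedGraph intervals are 0-based half-open; multi-base intervals are
    expanded to one count per covered 1-based position.  ``total_reads``
    defaults to the sum of all counts in the file (appropriate when the file
    covers the whole library).
    """
    per_replicon: Dict[str, Dict[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, start_s, end_s, value_s = fields
            try:
                start, end = int(start_s), int(end_s)
                value = int(float(value_s))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric interval or count")
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative count {value}")
            if end <= start or start < 0:
                raise ParseError(f"{path}:{lineno}: bad interval {start}..{end}")
            counts = per_replicon.setdefault(chrom, {})
            for pos in range(start + 1, end + 1):  # 0-based half-open -> 1-based
                counts[pos] = counts.get(pos, 0) + value
    grand_total = sum(sum(c.values()) for c in per_replicon.values())
    total = total_reads if total_reads is not None else grand_total
    return [
        ReadStartProfile(replicon_id=chrom, strand=strand, counts=counts, total_reads=total)
        for chrom, counts in sorted(per_replicon.items())
    ]


def write_bedgraph(profile: ReadStartProfile, path) -> None:
    with open(path, "w") as fh:
        for pos in sorted(profile.counts):
            n = profile.counts[pos]
            if n:
                fh.write(f"{profile.replicon_id}\t{pos - 1}\t{pos}\t{n}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> Dict[str, str]:
    """Multi-record FASTA -> {id: uppercase sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# versioned TSV tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    if schema not in SCHEMA_VERSIONS:
        raise ValueError(f"unknown table schema {schema!r}")
    with open(path, "w") as fh:
        fh.write(f"{HEADER_TAG}\tschema={schema}\tversion={SCHEMA_VERSIONS[schema]}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path, schema: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().strip()
        m = re.match(rf"^{HEADER_TAG}\tschema=(\w+)\tversion=(\d+)$", header)
        if not m:
            raise ParseError(f"{path}:1: missing or malformed schema header")
        found, version = m.group(1), int(m.group(2))
        if found != schema:
            raise ParseError(f"{path}: schema {found!r}, expected {schema!r}")
        if version != SCHEMA_VERSIONS[schema]:
            raise ParseError(
                f"{path}: unsupported {schema} schema version {version} "
                f"(supported: {SCHEMA_VERSIONS[schema]})"
            )
        return pd.read_csv(fh, sep="\t")


def write_tss_table(records: List[TssRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "name": r.name,
                "replicon": r.replicon_id,
                "position": r.position,
                "strand": r.strand,
                "mean_score": r.mean_score,
                "score_sd": r.score_sd,
                "rank": i + 1,
            }
            for i, r in enumerate(records)
        ]
    )
    write_table(df, path, schema="tss")


def read_tss_table(path) -> List[TssRecord]:
    df = read_table(path, schema="tss")
    records = []
    for row in df.itertuples():
        pos, strand, _digit = parse_tss_name(row.name)
        if pos != row.position or strand != row.strand:
            raise ParseError(f"{path}: name {row.name} disagrees with its row")
        records.append(
            TssRecord(
                name=row.name,
                replicon_id=row.replicon,
                position=row.position,
                strand=row.strand,
                mean_score=row.mean_score,
                score_sd=row.score_sd,
            )
        )
    return records


def write_annotations(annotations, path) -> None:
    """Motif annotations TSV with window indices and TSS-relative starts."""
    from .promoters import window_index_to_relative

    rows = []
    for a in annotations:
        rows.append(
            {
                "tss_name": a.tss_name,
                "component_first": a.component_first,
                "component_second": a.component_second,
                "start_first": a.start_first,
                "start_second": a.start_second,
                "rel_first": None if a.start_first is None
                else window_index_to_relative(a.start_first),
                "rel_second": None if a.start_second is None
                else window_index_to_relative(a.start_second),
                "match_first": a.match_first,
                "match_second": a.match_second,
                "viterbi_logprob": a.viterbi_logprob,
                "llr": a.llr,
            }
        )
    write_table(pd.DataFrame(rows), path, schema="annotations")


def write_bed6(records: List[TssRecord], path) -> None:
    """BED6 of consensus TSSs; the BED score column is capped at 1000."""
    with open(path, "w") as fh:
        for r in records:
            score = min(int(round(r.mean_score)), 1000)
            fh.write(
                f"{r.replicon_id}\t{r.position - 1}\t{r.position}\t{r.name}\t{score}\t{r.strand}\n"
            )
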