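"""Strand-aware promoter window extraction around TSS positions.

A promoter window covers relative positions -90..-1,+1..+10 around the TSS
(TSS = +1, no position 0), i.e. 100 nt with 90 nt upstream and the TSS plus
9 nt downstream.  Minus-strand windows are reverse-complemented so that the
window always reads 5'->3' with the TSS-proximal end at the 3' side; all
downstream motif positions are therefore defined on this oriented window
regardless of genomic strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

from Bio.Seq import reverse_complement

WINDOW_UPSTREAM = 90
WINDOW_DOWNSTREAM = 10
WINDOW_LENGTH = WINDOW_UPSTREAM + WINDOW_DOWNSTREAM

_ALPHABET = set("ACGTN")

__all__ = [
    "RepliconSequence",
    "PromoterSequence",
    "WindowOutOfBoundsError",
    "extract_window",
    "extract_windows",
    "relative_to_window_index",
    "window_index_to_relative",
    "WINDOW_LENGTH",
]


class WindowOutOfBoundsError(ValueError):
    """The -90..+10 window would extend beyond the end of the replicon."""


@dataclass
class RepliconSequence:
    """One replicon's DNA sequence, canonicalized to uppercase ACGTN."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        extra = set(self.sequence) - _ALPHABET
        if extra:
            raise ValueError(
                f"replicon {self.id!r} contains non-ACGTN characters: {sorted(extra)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PromoterSequence:
    """The oriented 100-nt window around one TSS."""

    tss_name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError(
                f"promoter window must be {WINDOW_LENGTH} nt, got {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return WINDOW_LENGTH


def relative_to_window_index(rel: int) -> int:
    """Map a TSS-relative position (-90..-1, +1..+10) to a 0-based window index."""
    if -WINDOW_UPSTREAM <= rel <= -1:
        return rel + WINDOW_UPSTREAM
    if 1 <= rel <= WINDOW_DOWNSTREAM:
        return rel + WINDOW_UPSTREAM - 1
    raise ValueError(f"relative position {rel} outside -90..-1,+1..+10")


def window_index_to_relative(idx: int) -> int:
    """Inverse of :func:`relative_to_window_index`."""
    if 0 <= idx < WINDOW_UPSTREAM:
        return idx - WINDOW_UPSTREAM
    if WINDOW_UPSTREAM <= idx < WINDOW_LENGTH:
        return idx - WINDOW_UPSTREAM + 1
    raise ValueError(f"window index {idx} outside 0..{WINDOW_LENGTH - 1}")


def extract_window(
    replicon: RepliconSequence, position: int, strand: str, tss_name: str = ""
) -> PromoterSequence:
    """Extract the -90..+10 window around a TSS at a 1-based position.

    On the plus strand the window is the forward slice position-90..position+9;
    on the minus strand it is the reverse complement of position-9..position+90.
    Raises :class:`WindowOutOfBoundsError` when the window leaves the replicon
    (callers drop such TSSs rather than wrapping around).
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    n = len(replicon)
    if strand == "+":
        start, end = position - WINDOW_UPSTREAM, position + WINDOW_DOWNSTREAM - 1
    else:
        start, end = position - WINDOW_DOWNSTREAM + 1, position + WINDOW_UPSTREAM
    if start < 1 or end > n:
        raise WindowOutOfBoundsError(
            f"window {start}..{end} around TSS at {position}{strand} leaves "
            f"replicon {replicon.id!r} (length {n})"
        )
    raw = replicon.sequence[start - 1 : end]
    if strand == "-":
        raw = reverse_complement(raw)
    return PromoterSequence(tss_name=tss_name or f"TSS_{position}{strand}", sequence=raw)


def extract_windows(
    replicons: dict, tss_records: Iterable
) -> Tuple[List[PromoterSequence], List[str]]:
    """Extract windows for many TSS records; out-of-bounds TSSs are dropped.

    ``replicons`` maps replicon id -> :class:`RepliconSequence`.  Returns the
    extracted windows and the names of dropped TSSs.
    """
    windows: List[PromoterSequence] = []
    dropped: List[str] = []
    for rec in tss_records:
        replicon = replicons[rec.replicon_id]
        try:
            windows.append(
                extract_window(replicon, rec.position, rec.strand, tss_name=rec.name)
            )
        except WindowOutOfBoundsError:
            dropped.append(rec.name)
    return windows, dropped
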