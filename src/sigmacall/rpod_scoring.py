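"""Weighted RpoD (sigma-70) consensus scoring and promoter classification.

The score rewards matches to the -35 consensus TTGACA and the -10 consensus
TATAAT, weighted by per-position conservation, and penalizes displacement of
the -35 element from its mean position (-35.6) and deviation of the spacer
from its mean length (15.8 nt).  Motif matches come as 10-mers from the motif
discovery stage: the -35 hexamer is the first 6 nt of the upstream 10-mer,
while the TATAAT hexamer sits at positions 3-8 of the downstream 10-mer (its
leading two bases belong to the extended -10 "TGn" element, which is reported
but carries no score weight).

score = s35 + s10 - |m35_start + 35.6| - |spacer - 15.8|

with spacer = |m35_start| - 6 - |m10_start|, the number of nucleotides between
the 3' end of the -35 hexamer and the start of the -10 10-mer.  The maximum
over integer positions with perfect hexamers is 16.4 (m35 at -36, spacer 16).

Strength classes (strong/medium/weak/none) cut the score at 6.35, 3.28 and
0.21; positional categories compare the motif starts with the canonical
screening windows (-39..-31 for the -35, -18..-10 for the -10) and the
combination of both yields the RpoD-dependence probability tier.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "RpodScoringConstants",
    "MotifMatchPair",
    "RpodCall",
    "score_hexamer",
    "rpod_score",
    "classify_strength",
    "classify_position",
    "assign_tier",
    "call_rpod",
    "score_annotation",
    "housekeeping_summary",
    "load_housekeeping_table",
    "DEFAULT_CONSTANTS",
]


@dataclass(frozen=True)
class RpodScoringConstants:
    """Weights, consensus sequences, penalties and classification cutoffs."""

    consensus_m35: str = "TTGACA"
    consensus_m10: str = "TATAAT"
    w35: Tuple[float, ...] = (3.0, 1.5, 1.5, 1.0, 1.0, 1.0)
    w10: Tuple[float, ...] = (1.0, 2.0, 1.0, 1.0, 1.0, 2.0)
    mean_m35_pos: float = -35.6
    mean_spacer: float = 15.8
    strong_cutoff: float = 6.35
    medium_cutoff: float = 3.28
    weak_cutoff: float = 0.21
    window_m35: Tuple[int, int] = (-39, -31)
    window_m10: Tuple[int, int] = (-18, -10)
    nu_margin: int = 5
    nu_spacer_range: Tuple[int, int] = (13, 19)


DEFAULT_CONSTANTS = RpodScoringConstants()


@dataclass
class MotifMatchPair:
    """Matched 10-mers and their TSS-relative start positions (both negative)."""

    m35_start: int
    m35_seq: str
    m10_start: int
    m10_seq: str

    def __post_init__(self) -> None:
        if self.m35_start >= 0 or self.m10_start >= 0:
            raise ValueError("motif starts are TSS-relative and must be negative")
        if len(self.m35_seq) < 6 or len(self.m10_seq) < 8:
            raise ValueError("model matches must cover the scored hexamers")


@dataclass
class RpodCall:
    """Score breakdown and classification for one TSS."""

    tss_name: str
    score: float
    s35: float
    s10: float
    pos_penalty: float
    spacer: Optional[int]
    spacer_penalty: float
    strength: str
    category: str
    tier: str


def score_hexamer(observed: str, consensus: str, weights: Sequence[float]) -> float:
    """Sum of weights at positions where the observed base equals the consensus.

    N never matches.  Both sequences must be hexamers.
    """
    if len(observed) != 6 or len(consensus) != 6 or len(weights) != 6:
        raise ValueError("score_hexamer requires two hexamers and six weights")
    return sum(
        w for o, c, w in zip(observed.upper(), consensus.upper(), weights) if o == c != "N"
    )


def rpod_score(
    match: MotifMatchPair, k: RpodScoringConstants = DEFAULT_CONSTANTS
) -> RpodCall:
    """Compute the weighted consensus score for one -35/-10 match pair.

    Only the score fields are classified here: strength from the score, the
    positional category from the starts, and the tier from both.
    """
    s35 = score_hexamer(match.m35_seq[:6], k.consensus_m35, k.w35)
    s10 = score_hexamer(match.m10_seq[2:8], k.consensus_m10, k.w10)
    spacer = abs(match.m35_start) - 6 - abs(match.m10_start)
    pos_penalty = abs(match.m35_start - k.mean_m35_pos)
    spacer_penalty = abs(spacer - k.mean_spacer)
    score = s35 + s10 - pos_penalty - spacer_penalty
    strength = classify_strength(score, k)
    category = classify_position(match.m35_start, match.m10_start, spacer, k)
    return RpodCall(
        tss_name="",
        score=score,
        s35=s35,
        s10=s10,
        pos_penalty=pos_penalty,
        spacer=spacer,
        spacer_penalty=spacer_penalty,
        strength=strength,
        category=category,
        tier=assign_tier(strength, category),
    )


def classify_strength(score: float, k: RpodScoringConstants = DEFAULT_CONSTANTS) -> str:
    """strong > 6.35 >= medium > 3.28 >= weak > 0.21 >= none."""
    if score > k.strong_cutoff:
        return "strong"
    if score > k.medium_cutoff:
        return "medium"
    if score > k.weak_cutoff:
        return "weak"
    return "none"


def _in_window(pos: int, window: Tuple[int, int]) -> bool:
    return window[0] <= pos <= window[1]


def classify_position(
    m35_start: Optional[int],
    m10_start: Optional[int],
    spacer: Optional[int] = None,
    k: RpodScoringConstants = DEFAULT_CONSTANTS,
) -> str:
    """Positional category of a -35/-10 pair relative to the screening windows.

    ``in_window``: both motifs inside their windows.  ``sba``: only the -10 is
    inside ("sliding/blocking/another sigma factor").  ``ba``: only the -35 is
    inside ("blocking or used by another sigma factor").  ``nu`` ("not used by
    RpoD"): both outside but displaced toward the same side, each by at most
    ``nu_margin`` bp, with a regular -35/-10 spacing.  Everything else is
    ``all_wrong``; absent motifs give ``no_motif``.
    """
    if m35_start is None or m10_start is None:
        return "no_motif"
    if spacer is None:
        spacer = abs(m35_start) - 6 - abs(m10_start)
    in35 = _in_window(m35_start, k.window_m35)
    in10 = _in_window(m10_start, k.window_m10)
    if in35 and in10:
        return "in_window"
    if in10:
        return "sba"
    if in35:
        return "ba"
    both_upstream = m35_start < k.window_m35[0] and m10_start < k.window_m10[0]
    both_downstream = m35_start > k.window_m35[1] and m10_start > k.window_m10[1]
    if both_upstream or both_downstream:
        d35 = min(
            abs(m35_start - k.window_m35[0]), abs(m35_start - k.window_m35[1])
        )
        d10 = min(
            abs(m10_start - k.window_m10[0]), abs(m10_start - k.window_m10[1])
        )
        if (
            d35 <= k.nu_margin
            and d10 <= k.nu_margin
            and k.nu_spacer_range[0] <= spacer <= k.nu_spacer_range[1]
        ):
            return "nu"
    return "all_wrong"


_TIER_TABLE: Dict[Tuple[str, str], str] = {}
for _strength in ("strong", "medium", "weak", "none"):
    for _cat in ("in_window", "sba", "ba", "nu", "all_wrong", "no_motif"):
        _TIER_TABLE[(_strength, _cat)] = "none"
_TIER_TABLE.update(
    {
        ("strong", "in_window"): "high",
        ("medium", "in_window"): "high",
        ("strong", "sba"): "high",
        ("strong", "ba"): "high",
        ("weak", "in_window"): "low",
        ("medium", "sba"): "low",
        ("medium", "ba"): "low",
        ("medium", "nu"): "low",
        # strong+nu cannot occur: the positional penalties that define nu
        # already push the score below the strong cutoff.
    }
)


def assign_tier(strength: str, category: str) -> str:
    """RpoD-dependence probability tier from (strength, positional category)."""
    try:
        return _TIER_TABLE[(strength, category)]
    except KeyError:
        raise ValueError(f"unknown strength/category pair ({strength!r}, {category!r})")


def call_rpod(
    tss_name: str,
    m35_start: Optional[int],
    m35_seq: Optional[str],
    m10_start: Optional[int],
    m10_seq: Optional[str],
    k: RpodScoringConstants = DEFAULT_CONSTANTS,
) -> RpodCall:
    """Full call for one TSS, tolerating absent motifs."""
    if m35_start is None or m10_start is None or not m35_seq or not m10_seq:
        return RpodCall(
            tss_name=tss_name, score=float("-inf"), s35=0.0, s10=0.0,
            pos_penalty=0.0, spacer=None, spacer_penalty=0.0,
            strength="none", category="no_motif", tier="none",
        )
    call = rpod_score(MotifMatchPair(m35_start, m35_seq, m10_start, m10_seq), k)
    call.tss_name = tss_name
    return call


def score_annotation(annotation, k: RpodScoringConstants = DEFAULT_CONSTANTS) -> RpodCall:
    """Score a :class:`~sigmacall.motif_hmm.MotifAnnotation`.

    Window indices are converted to TSS-relative positions; a skipped motif
    set yields a ``no_motif`` call.
    """
    from .promoters import window_index_to_relative

    m35_start = (
        None if annotation.start_first is None
        else window_index_to_relative(annotation.start_first)
    )
    m10_start = (
        None if annotation.start_second is None
        else window_index_to_relative(annotation.start_second)
    )
    if (m35_start is not None and m35_start >= 0) or (
        m10_start is not None and m10_start >= 0
    ):
        # motif reaching into the transcribed region: no upstream promoter call
        return call_rpod(annotation.tss_name, None, None, None, None, k)
    return call_rpod(
        annotation.tss_name, m35_start, annotation.match_first,
        m10_start, annotation.match_second, k,
    )


def load_housekeeping_table() -> pd.DataFrame:
    """The bundled 48-row housekeeping promoter table (published values).

    Columns: rank, m35_model, m35_start, m35_seq, m10_start, m10_seq,
    locus_tag, gene, published_score.
    """
    ref = importlib.resources.files("sigmacall").joinpath(
        "data/housekeeping_promoters.tsv"
    )
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def housekeeping_summary(
    table: Optional[pd.DataFrame] = None,
    k: RpodScoringConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Recompute scores for a housekeeping-style table and summarize.

    Returns mean/SD/min/max of the -35 start, -10 start, spacer and recomputed
    score.  With no argument the bundled table is used.
    """
    if table is None:
        table = load_housekeeping_table()
    if len(table) == 0:
        raise ValueError("summary of an empty table is undefined")
    calls = [
        rpod_score(
            MotifMatchPair(r.m35_start, r.m35_seq, r.m10_start, r.m10_seq), k
        )
        for r in table.itertuples()
    ]
    df = pd.DataFrame(
        {
            "m35_start": table["m35_start"].to_numpy(),
            "m10_start": table["m10_start"].to_numpy(),
            "spacer": [c.spacer for c in calls],
            "score": [c.score for c in calls],
        }
    )
    summary = df.agg(["mean", "std", "min", "max"])
    summary.loc["std"] = summary.loc["std"].fillna(0.0)  # single-row tables: SD 0
    return summary
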