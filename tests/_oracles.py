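"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's vectorized code paths: clustering is
re-implemented with plain dict scans, and promoter-HMM decoding enumerates
every legal state path and sums log-probabilities term by term.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple


def brute_force_cluster(rrs: Dict[int, float], radius: int) -> List[Tuple[int, float]]:
    """Greedy clustering oracle: (peak position, pooled RRS), sorted by position."""
    remaining = dict(rrs)
    peaks = []
    while remaining:
        best = max(remaining.values())
        peak = min(p for p, v in remaining.items() if v == best)
        pooled = 0.0
        for p in [p for p in remaining if abs(p - peak) <= radius]:
            pooled += remaining.pop(p)
        peaks.append((peak, pooled))
    return sorted(peaks)


def oracle_viterbi(seq: str, model) -> Tuple[Optional[int], Optional[int],
                                             Optional[int], Optional[int], float]:
    """Exhaustive decoding of the constrained promoter HMM.

    Returns (c1, s1, c2, s2, logprob) with None for skipped sets, using the
    same tie-breaking convention as the package: skip preferred over use,
    then earlier starts, then lower component indices.
    """
    cfg = model.config
    K1, K2 = cfg.n_components_first, cfg.n_components_second
    L, O, G = cfg.motif_length, cfg.first_motif_offset, cfg.min_motif_gap
    W = len(seq)
    codes = ["ACGT".find(b) for b in seq.upper()]
    logbg = [math.log(p) for p in model.background]
    logt = math.log(model.stay_prob)
    log1mt = math.log(1.0 - model.stay_prob)
    la = [math.log(p) for p in model.trans_first]
    lb = [math.log(p) for p in model.trans_second]
    n_decisions = (K1 > 0) + (K2 > 0)

    def path_logprob(c1, s1, c2, s2) -> float:
        lp = n_decisions * log1mt
        if K1 > 0:
            lp += la[0] if c1 is None else la[c1 + 1]
        if K2 > 0:
            lp += lb[0] if c2 is None else lb[c2 + 1]
        if c1 is not None and c2 is not None:
            stays = s2 - O - L - G
        elif c1 is not None:
            stays = s1 - O
        elif c2 is not None:
            stays = s2 - O
        else:
            stays = 0
        lp += stays * logt
        motif_rows = {}
        if c1 is not None:
            for j in range(L):
                motif_rows[s1 + j] = model.components_first[c1][j]
        if c2 is not None:
            for j in range(L):
                motif_rows[s2 + j] = model.components_second[c2][j]
        for i, c in enumerate(codes):
            if c < 0:  # N emits with background probability everywhere
                continue
            row = motif_rows.get(i)
            lp += math.log(row[c]) if row is not None else logbg[c]
        return lp

    cands = []
    for c1 in [None] + list(range(K1)):
        s1_range = [None] if c1 is None else list(range(O, W - L + 1))
        for s1 in s1_range:
            for c2 in [None] + list(range(K2)):
                if c2 is None:
                    s2_range = [None]
                elif c1 is None:
                    s2_range = list(range(O, W - L + 1))
                else:
                    s2_range = list(range(s1 + L + G, W - L + 1))
                for s2 in s2_range:
                    cands.append((c1, s1, c2, s2, path_logprob(c1, s1, c2, s2)))
    best = max(c[4] for c in cands)
    tied = [c for c in cands if c[4] >= best - 1e-9]

    def key(c):
        c1, s1, c2, s2, _ = c
        return (
            0 if c1 is None else 1, s1 or 0, c1 or 0,
            0 if c2 is None else 1, s2 or 0, c2 or 0,
        )

    return min(tied, key=key)


def brute_force_max_rpod_score(score_fn, lo: int = -60, hi: int = -1):
    """Maximum RpoD score over all integer motif placements with perfect
    consensus hexamers.  ``score_fn(m35_start, m10_start)`` returns the score.
    """
    best = None
    for m35 in range(lo, hi + 1):
        for m10 in range(lo, hi + 1):
            s = score_fn(m35, m10)
            if best is None or s > best[0]:
                best = (s, m35, m10)
    return best
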