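"""Two-motif promoter HMM with Viterbi training and random restarts.

The model describes a promoter window as homogeneous background interrupted by
up to two fixed-length motifs: an upstream set (the -35 side) and a downstream
set (the -10 side).  Each set offers several alternative components (motifs
with position-specific emission probabilities); a path uses at most one
component per set and may skip a set entirely.  Switches between alternative
paths happen only between the two sets, never inside a motif.

Architecture constraints are structural, encoded as mandatory background
chains: the first motif may not start before ``first_motif_offset`` positions
into the window (when the first set is empty this constraint applies to the
second set's motif), and at least ``min_motif_gap`` background positions
separate the two motifs.  Transitions are parameterized by a single shared
background stay-probability ``t`` plus, per motif set, a categorical choice
over (skip, component 1..K) taken at the set's single "move on" decision.
Under this parameterization the Viterbi path depends only on the motif
placements, so decoding is performed by exact maximization over all legal
(component, start) placements -- equivalent to Viterbi over the constrained
state graph, but vectorizable.

Training is Viterbi training (segmental k-means): decode every sequence,
re-estimate emissions and transitions from the path-aligned counts with
pseudo-count smoothing, and iterate until no sequence changes its path.  As
this converges to local optima, training restarts from many random
initializations and keeps the restart with the highest total Viterbi
log-probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .promoters import PromoterSequence

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_N_INDEX = 4  # emits with background probability, i.e. log-odds 0 everywhere

__all__ = [
    "HmmConfig",
    "PromoterHmm",
    "MotifAnnotation",
    "TwoPhaseResult",
    "DegenerateResultError",
    "viterbi",
    "viterbi_decode",
    "viterbi_train",
    "two_phase_discovery",
    "positional_histogram",
    "consensus",
]


class DegenerateResultError(RuntimeError):
    """Raised when motif discovery collapses (no promoter uses any component)."""


@dataclass
class HmmConfig:
    """Architecture and training settings.

    ``first_motif_offset`` is the number of window positions (nt from the 5'
    end) before which no motif may start; with the 100-nt -90..+10 window and
    the default offset of 40 this confines the search to -50..+10.
    """

    motif_length: int = 10
    first_motif_offset: int = 40
    min_motif_gap: int = 10
    n_components_first: int = 0
    n_components_second: int = 5
    n_restarts: int = 100
    max_iterations: int = 100
    pseudo_count: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError("motif_length must be >= 1")
        if self.first_motif_offset < 0 or self.min_motif_gap < 0:
            raise ValueError("offsets and gaps must be >= 0")
        if not (0 <= self.n_components_first <= 5 and 0 <= self.n_components_second <= 5):
            raise ValueError("component counts must be in 0..5")
        if self.n_restarts < 1 or self.max_iterations < 1:
            raise ValueError("n_restarts and max_iterations must be positive")
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be positive")

    def min_window_length(self) -> int:
        L, O, G = self.motif_length, self.first_motif_offset, self.min_motif_gap
        k1, k2 = self.n_components_first, self.n_components_second
        if k1 > 0 and k2 > 0:
            return O + 2 * L + G
        if k1 > 0 or k2 > 0:
            return O + L
        return 1


@dataclass
class MotifAnnotation:
    """Viterbi result for one promoter window.

    Component indices are 0-based within their set; ``None`` means the set's
    skip path was taken.  Starts are 0-based window indices.  ``llr`` is the
    log-likelihood ratio of the Viterbi path against the all-background
    (both-sets-skipped) path of the same model.
    """

    tss_name: str
    component_first: Optional[int]
    component_second: Optional[int]
    start_first: Optional[int]
    start_second: Optional[int]
    match_first: Optional[str]
    match_second: Optional[str]
    viterbi_logprob: float
    llr: float


class PromoterHmm:
    """Parameter container for the two-motif promoter HMM.

    ``components_first`` / ``components_second`` are arrays of shape
    (K, motif_length, 4); ``background`` is the shared homogeneous emission
    distribution; ``trans_first`` / ``trans_second`` are categorical
    distributions over (skip, component 1..K); ``stay_prob`` is the shared
    background stay probability at decision points.
    """

    def __init__(
        self,
        config: HmmConfig,
        background: np.ndarray,
        components_first: np.ndarray,
        components_second: np.ndarray,
        trans_first: np.ndarray,
        trans_second: np.ndarray,
        stay_prob: float,
    ) -> None:
        self.config = config
        self.background = np.asarray(background, dtype=float)
        self.components_first = np.asarray(components_first, dtype=float).reshape(
            config.n_components_first, config.motif_length, 4
        )
        self.components_second = np.asarray(components_second, dtype=float).reshape(
            config.n_components_second, config.motif_length, 4
        )
        self.trans_first = np.asarray(trans_first, dtype=float)
        self.trans_second = np.asarray(trans_second, dtype=float)
        self.stay_prob = float(stay_prob)
        self._validate()

    def _validate(self) -> None:
        tol = 1e-9
        if abs(self.background.sum() - 1.0) > tol:
            raise ValueError("background distribution must sum to 1")
        for name, arr in (
            ("components_first", self.components_first),
            ("components_second", self.components_second),
        ):
            if arr.size and np.any(np.abs(arr.sum(axis=2) - 1.0) > tol):
                raise ValueError(f"every emission row of {name} must sum to 1")
        for name, arr, k in (
            ("trans_first", self.trans_first, self.config.n_components_first),
            ("trans_second", self.trans_second, self.config.n_components_second),
        ):
            if len(arr) != k + 1:
                raise ValueError(f"{name} must have length K+1 (skip + components)")
            if abs(arr.sum() - 1.0) > tol:
                raise ValueError(f"{name} must sum to 1")
        if not 0.0 < self.stay_prob < 1.0:
            raise ValueError("stay_prob must be in (0, 1)")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": self.config.__dict__,
            "background": self.background.tolist(),
            "components_first": self.components_first.tolist(),
            "components_second": self.components_second.tolist(),
            "trans_first": self.trans_first.tolist(),
            "trans_second": self.trans_second.tolist(),
            "stay_prob": self.stay_prob,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PromoterHmm":
        cfg = HmmConfig(**d["config"])
        return cls(
            cfg,
            np.array(d["background"]),
            np.array(d["components_first"]).reshape(cfg.n_components_first, cfg.motif_length, 4),
            np.array(d["components_second"]).reshape(cfg.n_components_second, cfg.motif_length, 4),
            np.array(d["trans_first"]),
            np.array(d["trans_second"]),
            d["stay_prob"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "PromoterHmm":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def consensus(emissions: np.ndarray) -> str:
    """Majority-base consensus string of one component's emission matrix."""
    return "".join(_BASES[i] for i in np.argmax(emissions, axis=1))


# ---------------------------------------------------------------------------
# sequence batching
# ---------------------------------------------------------------------------

SequenceLike = Union[str, PromoterSequence]


def _seq_string(seq: SequenceLike) -> Tuple[str, str]:
    if isinstance(seq, PromoterSequence):
        return seq.sequence, seq.tss_name
    return seq, ""


class _Batch:
    """Encoded, windowed view of a set of equal-length sequences."""

    def __init__(self, sequences: Sequence[SequenceLike], motif_length: int) -> None:
        strings, names = [], []
        for i, s in enumerate(sequences):
            string, name = _seq_string(s)
            strings.append(string.upper())
            names.append(name or f"seq{i}")
        lengths = {len(s) for s in strings}
        if len(lengths) != 1:
            raise ValueError(f"sequences must share one length, got {sorted(lengths)}")
        self.window = lengths.pop()
        self.names = names
        self.n = len(strings)
        self.strings = strings
        codes = np.full((self.n, self.window), _N_INDEX, dtype=np.int8)
        for i, s in enumerate(strings):
            for j, b in enumerate(s):
                codes[i, j] = _BASE_INDEX.get(b, _N_INDEX)
        self.codes = codes
        onehot = np.zeros((self.n, self.window, 4), dtype=float)
        valid = codes < 4
        onehot[np.nonzero(valid)[0], np.nonzero(valid)[1], codes[valid]] = 1.0
        self.onehot = onehot
        # (n, S, 4, L) windows for motif scoring
        self.S = self.window - motif_length + 1
        self.windows = sliding_window_view(onehot, motif_length, axis=1)
        self.base_counts = onehot.sum(axis=1)  # (n, 4), N excluded


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

_NEG_INF = -np.inf


def _motif_scores(batch: _Batch, components: np.ndarray, logbg: np.ndarray) -> np.ndarray:
    """Log-odds score of every component at every window start: (n, K, S)."""
    lo = np.log(components) - logbg[None, None, :]  # (K, L, 4)
    return np.einsum("nsal,kla->nks", batch.windows, lo)


def _first_max(arr2d: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row max of a (n, m) array with first-occurrence argmax."""
    idx = np.argmax(arr2d, axis=1)
    return arr2d[np.arange(arr2d.shape[0]), idx], idx, arr2d


def _decode_batch(batch: _Batch, model: PromoterHmm):
    """Exact Viterbi placements for every sequence in the batch.

    Returns ``(placements, path_scores, skip_score)`` where placements is an
    (n, 4) int array of (c1, s1, c2, s2) with -1 for skipped sets,
    ``path_scores`` excludes the shared background base term, and
    ``skip_score`` is the (placement-independent) score of the all-skip path.

    Ties are broken by preferring skip over motif use, then earlier starts,
    then lower component indices (lexicographic on the path signature).
    """
    cfg = model.config
    K1, K2 = cfg.n_components_first, cfg.n_components_second
    L, O, G = cfg.motif_length, cfg.first_motif_offset, cfg.min_motif_gap
    W, S, n = batch.window, batch.S, batch.n
    if W < cfg.min_window_length():
        raise ValueError(
            f"sequences of length {W} are shorter than the architecture's "
            f"minimum footprint {cfg.min_window_length()}"
        )

    logbg = np.log(model.background)
    logt = np.log(model.stay_prob)
    log1mt = np.log1p(-model.stay_prob)
    la = np.log(model.trans_first) if K1 > 0 else None
    lb = np.log(model.trans_second) if K2 > 0 else None

    const = 0.0
    if K1 > 0:
        const += log1mt
    if K2 > 0:
        const += log1mt
    skip_score = const + (la[0] if K1 > 0 else 0.0) + (lb[0] if K2 > 0 else 0.0)

    starts = np.arange(S, dtype=float)
    valid_from_offset = starts >= O

    # candidate paths per sequence: list of (score_array(n,), key_fn, placement)
    # assembled case by case; final comparison is lexicographic on ties.
    cand_scores: List[np.ndarray] = []
    cand_place: List[np.ndarray] = []  # (n, 4) per candidate

    # case: both sets skipped
    cand_scores.append(np.full(n, skip_score))
    cand_place.append(np.full((n, 4), -1, dtype=int))

    sc1 = _motif_scores(batch, model.components_first, logbg) if K1 > 0 else None
    sc2 = _motif_scores(batch, model.components_second, logbg) if K2 > 0 else None

    def single_motif_case(sc, ltrans, other_skip):
        # score(n,k,s) = lo + log trans[k] + (s-O) log t + const + other skip cost
        m = sc + ltrans[None, 1:, None] + (starts - O)[None, None, :] * logt
        m = m + const + other_skip
        m = np.where(valid_from_offset[None, None, :], m, _NEG_INF)
        # preference: earlier start then lower component -> axes (s, k)
        flat = m.transpose(0, 2, 1).reshape(n, -1)
        best, idx, _ = _first_max(flat)
        s_sel, k_sel = idx // m.shape[1], idx % m.shape[1]
        return best, k_sel, s_sel

    if K2 > 0:  # second motif only (first set skipped or empty)
        best, k_sel, s_sel = single_motif_case(sc2, lb, la[0] if K1 > 0 else 0.0)
        place = np.full((n, 4), -1, dtype=int)
        place[:, 2], place[:, 3] = k_sel, s_sel
        cand_scores.append(best)
        cand_place.append(place)

    if K1 > 0:  # first motif only (second set skipped or empty)
        best, k_sel, s_sel = single_motif_case(sc1, la, lb[0] if K2 > 0 else 0.0)
        place = np.full((n, 4), -1, dtype=int)
        place[:, 0], place[:, 1] = k_sel, s_sel
        cand_scores.append(best)
        cand_place.append(place)

    if K1 > 0 and K2 > 0 and W >= O + 2 * L + G:
        # both motifs: maximize over s2 >= s1 + L + G with stay cost folded
        # into the second motif's start (total stays = s2 - O - L - G).
        g2 = sc2 + lb[None, 1:, None] + (starts - O - L - G)[None, None, :] * logt
        h2 = np.max(g2, axis=1)  # (n, S)
        k2_at = np.argmax(g2, axis=1)  # lowest component on ties
        # suffix max over s2, preferring the earlier s2 on ties
        suff = np.full((n, S + 1), _NEG_INF)
        suff_s2 = np.zeros((n, S + 1), dtype=int)
        for s in range(S - 1, -1, -1):
            take = h2[:, s] >= suff[:, s + 1]
            suff[:, s] = np.where(take, h2[:, s], suff[:, s + 1])
            suff_s2[:, s] = np.where(take, s, suff_s2[:, s + 1])
        s1_max = W - 2 * L - G  # inclusive upper bound for the first start
        m1 = sc1 + la[None, 1:, None]
        valid_s1 = (starts >= O) & (starts <= s1_max)
        gap_idx = np.clip(np.arange(S) + L + G, 0, S)
        total = m1 + suff[:, gap_idx][:, None, :] + const
        total = np.where(valid_s1[None, None, :], total, _NEG_INF)
        flat = total.transpose(0, 2, 1).reshape(n, -1)
        best, idx, _ = _first_max(flat)
        s1_sel, k1_sel = idx // total.shape[1], idx % total.shape[1]
        s2_sel = suff_s2[np.arange(n), np.clip(s1_sel + L + G, 0, S)]
        k2_sel = k2_at[np.arange(n), s2_sel]
        place = np.stack([k1_sel, s1_sel, k2_sel, s2_sel], axis=1)
        cand_scores.append(best)
        cand_place.append(place)

    # final selection with lexicographic tie-breaking on the path signature:
    # skip < use, then earlier start, then lower component, first set first.
    def signature(p: np.ndarray) -> tuple:
        c1, s1, c2, s2 = p
        return (
            0 if c1 < 0 else 1, max(s1, 0), max(c1, 0),
            0 if c2 < 0 else 1, max(s2, 0), max(c2, 0),
        )

    scores_mat = np.stack(cand_scores, axis=1)  # (n, ncand)
    placements = np.empty((n, 4), dtype=int)
    path_scores = np.empty(n)
    order = np.argsort(-scores_mat, axis=1, kind="stable")
    for i in range(n):
        best_j = order[i, 0]
        best_score = scores_mat[i, best_j]
        best_sig = signature(cand_place[best_j][i])
        for j in order[i, 1:]:
            if scores_mat[i, j] < best_score - 1e-12:
                break
            sig = signature(cand_place[j][i])
            if sig < best_sig:
                best_j, best_sig = j, sig
        placements[i] = cand_place[best_j][i]
        path_scores[i] = scores_mat[i, best_j]
    return placements, path_scores, skip_score


def _annotations_from_placements(
    batch: _Batch, model: PromoterHmm, placements: np.ndarray, path_scores: np.ndarray,
    skip_score: float,
) -> List[MotifAnnotation]:
    logbg = np.log(model.background)
    base = batch.base_counts @ logbg
    L = model.config.motif_length
    out = []
    for i in range(batch.n):
        c1, s1, c2, s2 = (int(v) for v in placements[i])
        string = batch.strings[i]
        out.append(
            MotifAnnotation(
                tss_name=batch.names[i],
                component_first=None if c1 < 0 else c1,
                component_second=None if c2 < 0 else c2,
                start_first=None if c1 < 0 else s1,
                start_second=None if c2 < 0 else s2,
                match_first=None if c1 < 0 else string[s1 : s1 + L],
                match_second=None if c2 < 0 else string[s2 : s2 + L],
                viterbi_logprob=float(base[i] + path_scores[i]),
                llr=float(path_scores[i] - skip_score),
            )
        )
    return out


def viterbi_decode(
    sequences: Sequence[SequenceLike], model: PromoterHmm
) -> List[MotifAnnotation]:
    """Decode many sequences with a fixed model."""
    batch = _Batch(sequences, model.config.motif_length)
    placements, path_scores, skip_score = _decode_batch(batch, model)
    return _annotations_from_placements(batch, model, placements, path_scores, skip_score)


def viterbi(seq: SequenceLike, model: PromoterHmm) -> MotifAnnotation:
    """Decode a single sequence (see :func:`viterbi_decode`)."""
    return viterbi_decode([seq], model)[0]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _init_model(
    cfg: HmmConfig,
    batch: _Batch,
    rng: np.random.Generator,
    second_init: Optional[np.ndarray] = None,
) -> PromoterHmm:
    """Random initialization: Dirichlet(1) motif emissions, empirical background."""
    bg_counts = batch.base_counts.sum(axis=0) + cfg.pseudo_count
    background = bg_counts / bg_counts.sum()
    comp1 = rng.dirichlet(np.ones(4), size=(cfg.n_components_first, cfg.motif_length))
    comp2 = rng.dirichlet(np.ones(4), size=(cfg.n_components_second, cfg.motif_length))
    if second_init is not None:
        comp2 = comp2.copy()
        comp2[0] = second_init
    trans1 = np.full(cfg.n_components_first + 1, 1.0 / (cfg.n_components_first + 1))
    trans2 = np.full(cfg.n_components_second + 1, 1.0 / (cfg.n_components_second + 1))
    return PromoterHmm(cfg, background, comp1, comp2, trans1, trans2, stay_prob=0.9)


def _reestimate(cfg: HmmConfig, batch: _Batch, placements: np.ndarray) -> PromoterHmm:
    """Maximum a-posteriori re-estimation from path-aligned counts."""
    L, O, G = cfg.motif_length, cfg.first_motif_offset, cfg.min_motif_gap
    pc = cfg.pseudo_count
    codes = batch.codes

    def motif_counts(K: int, col_c: int, col_s: int) -> Tuple[np.ndarray, np.ndarray]:
        emis = np.zeros((K, L, 4))
        use = np.zeros(K + 1)
        taken = placements[:, col_c]
        use[0] = np.sum(taken < 0)
        for k in range(K):
            mask = taken == k
            use[k + 1] = mask.sum()
            if not use[k + 1]:
                continue
            starts = placements[mask, col_s]
            sub = codes[np.nonzero(mask)[0][:, None], starts[:, None] + np.arange(L)]
            for j in range(L):
                col = sub[:, j]
                np.add.at(emis[k, j], col[col < 4], 1.0)
        return emis, use

    emis1, use1 = motif_counts(cfg.n_components_first, 0, 1)
    emis2, use2 = motif_counts(cfg.n_components_second, 2, 3)

    # background: all non-motif positions
    bg = batch.base_counts.sum(axis=0).copy()
    bg -= emis1.sum(axis=(0, 1)) + emis2.sum(axis=(0, 1))

    # stay / move-on decisions
    c1, s1, c2, s2 = (placements[:, i] for i in range(4))
    stays = np.where(
        (c1 >= 0) & (c2 >= 0), s2 - O - L - G,
        np.where(c1 >= 0, s1 - O, np.where(c2 >= 0, s2 - O, 0)),
    )
    n_moveon = ((cfg.n_components_first > 0) + (cfg.n_components_second > 0)) * batch.n
    stay_total = float(stays.sum())
    stay_prob = (stay_total + pc) / (stay_total + n_moveon + 2 * pc)

    def norm(arr: np.ndarray, axis=-1) -> np.ndarray:
        arr = arr + pc
        return arr / arr.sum(axis=axis, keepdims=True)

    return PromoterHmm(
        cfg,
        background=norm(bg),
        components_first=norm(emis1, axis=2),
        components_second=norm(emis2, axis=2),
        trans_first=norm(use1),
        trans_second=norm(use2),
        stay_prob=stay_prob,
    )


@dataclass
class _Restart:
    model: PromoterHmm
    placements: np.ndarray
    path_scores: np.ndarray
    skip_score: float
    total: float
    history: List[float] = field(default_factory=list)
    iterations: int = 0


def _train_once(cfg: HmmConfig, batch: _Batch, rng: np.random.Generator,
                second_init: Optional[np.ndarray] = None) -> _Restart:
    model = _init_model(cfg, batch, rng, second_init=second_init)
    placements, path_scores, skip_score = _decode_batch(batch, model)
    logbg = np.log(model.background)
    total = float((batch.base_counts @ logbg + path_scores).sum())
    state = _Restart(model, placements, path_scores, skip_score, total, [total], 0)
    for it in range(cfg.max_iterations):
        new_model = _reestimate(cfg, batch, state.placements)
        new_p, new_s, new_skip = _decode_batch(batch, new_model)
        new_total = float((batch.base_counts @ np.log(new_model.background) + new_s).sum())
        if new_total < state.total:
            break  # smoothing can no longer improve the paths; keep previous model
        converged = np.array_equal(new_p, state.placements)
        state = _Restart(new_model, new_p, new_s, new_skip, new_total,
                         state.history + [new_total], it + 1)
        if converged:
            break
    return state


def viterbi_train(
    promoters: Sequence[SequenceLike], cfg: HmmConfig,
    second_init: Optional[np.ndarray] = None,
) -> Tuple[PromoterHmm, List[MotifAnnotation]]:
    """Viterbi training with random restarts; returns the best restart's model.

    Restart ``r`` draws its initialization from a generator seeded with
    ``cfg.seed + r``, making restarts individually reproducible.  The model
    with the highest total Viterbi log-probability wins (ties: lowest restart
    index).  The training history of the winning restart is attached to the
    returned model as ``model.training_history``.
    """
    if not promoters:
        raise ValueError("at least one promoter sequence is required")
    batch = _Batch(promoters, cfg.motif_length)
    best: Optional[_Restart] = None
    for r in range(cfg.n_restarts):
        rng = np.random.default_rng(cfg.seed + r)
        state = _train_once(cfg, batch, rng, second_init=second_init)
        if best is None or state.total > best.total:
            best = state
    best.model.training_history = best.history
    annotations = _annotations_from_placements(
        batch, best.model, best.placements, best.path_scores, best.skip_score
    )
    return best.model, annotations


@dataclass
class TwoPhaseResult:
    phase1_model: PromoterHmm
    phase1_annotations: List[MotifAnnotation]
    phase2_model: PromoterHmm
    phase2_annotations: List[MotifAnnotation]
    dominant_component: int
    selected_promoters: List[SequenceLike]


def two_phase_discovery(
    promoters: Sequence[SequenceLike],
    motif_length: int = 10,
    first_motif_offset: int = 40,
    min_motif_gap: int = 10,
    restarts_phase1: int = 100,
    restarts_phase2: int = 500,
    seed: int = 0,
    max_iterations: int = 100,
    pseudo_count: float = 0.5,
) -> TwoPhaseResult:
    """Two-phase motif discovery.

    Phase 1 trains a (0, 5)-component model, i.e. five alternative downstream
    motifs and no upstream set, so the search is confined to the window tail
    and targets the -10 region.  The second-set component matched by the
    largest number of promoters becomes the dominant (-10) component; the
    promoters whose Viterbi path uses it are the input of phase 2, which
    trains a (5, 1)-component model whose single downstream motif is
    initialized from the dominant component, to discover the upstream (-35)
    motifs.
    """
    cfg1 = HmmConfig(
        motif_length=motif_length, first_motif_offset=first_motif_offset,
        min_motif_gap=min_motif_gap, n_components_first=0, n_components_second=5,
        n_restarts=restarts_phase1, max_iterations=max_iterations,
        pseudo_count=pseudo_count, seed=seed,
    )
    model1, ann1 = viterbi_train(promoters, cfg1)
    counts = np.zeros(cfg1.n_components_second, dtype=int)
    for a in ann1:
        if a.component_second is not None:
            counts[a.component_second] += 1
    if counts.sum() == 0:
        raise DegenerateResultError("no promoter matched any phase-1 component")
    dominant = int(np.argmax(counts))
    selected = [p for p, a in zip(promoters, ann1) if a.component_second == dominant]

    cfg2 = HmmConfig(
        motif_length=motif_length, first_motif_offset=first_motif_offset,
        min_motif_gap=min_motif_gap, n_components_first=5, n_components_second=1,
        n_restarts=restarts_phase2, max_iterations=max_iterations,
        pseudo_count=pseudo_count, seed=seed + restarts_phase1,
    )
    model2, ann2 = viterbi_train(
        selected, cfg2, second_init=model1.components_second[dominant]
    )
    return TwoPhaseResult(model1, ann1, model2, ann2, dominant, selected)


def positional_histogram(
    annotations: Sequence[MotifAnnotation], motif: str = "second"
) -> Dict[int, Dict[int, int]]:
    """Counts of motif start positions per component (window indices)."""
    if motif not in ("first", "second"):
        raise ValueError("motif must be 'first' or 'second'")
    comp_attr = f"component_{motif}"
    start_attr = f"start_{motif}"
    hist: Dict[int, Dict[int, int]] = {}
    for a in annotations:
        comp = getattr(a, comp_attr)
        if comp is None:
            continue
        start = getattr(a, start_attr)
        hist.setdefault(comp, {})
        hist[comp][start] = hist[comp].get(start, 0) + 1
    return hist


def logo_matrix(emissions: np.ndarray) -> np.ndarray:
    """Information-content matrix (bits) of one component, for sequence logos."""
    p = np.asarray(emissions, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ic = 2.0 + np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=1)
    return p * ic[:, None]
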