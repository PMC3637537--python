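"""Residue-level alignment: greedy segment selection and iterative refinement.

Starting from each seed superposition produced by the SSE-level hashing
stage, a one-to-one C-alpha mapping is grown in three sweeps of increasing
distance cutoff (d1 = R0, d2 = 1.5 R0, d3 = 2.5 R0).  At each cutoff a
query x model similarity matrix is computed from the superposed distances
and the secondary-structure agreement; the alignment is the union of
non-overlapping runs along (anti-)diagonals, accepted greedily from the
highest-scoring run down, each accepted run blocking its rows and columns.
Because a run must consist of strictly positive entries and its score is
their sum, the best segment on a diagonal is always a *maximal* positive
run, which the search exploits.  The minimum segment score (2.2, with cell
values capped at 1) means accepted runs always span at least 3 residues,
which is what keeps these alignments free of 1-2 residue noise fragments.

Each alignment is scored by a modified TM-score (mTM): the similarity values
at the widest cutoff summed over aligned pairs, normalized by the query
length.  Refinement alternates least-squares superposition on the current
pairs with a fresh sweep, keeping the best-scoring iterate.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import NoSSEError
from .geometry import Superposition, apply_superposition, kabsch_superpose
from .structure_io import ProteinStructure

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"


@dataclasses.dataclass
class AlignParams:
    """Tunable parameters of the aligner (defaults are the trained set)."""

    r0: float = 3.2  # base distance cutoff, Angstrom
    voxel_h: float = 3.2  # hashing grid resolution, Angstrom
    w: float = 1.0  # weight of the SSE-type agreement factor
    s_min: float = 2.2  # minimum accepted segment score
    top_k_seeds: int = 50  # seed superpositions carried to residue level
    max_refine_iters: int = 30
    mode: str = "forward"  # 'forward' or 'mixed' (allow reverse segments)
    d_steps: tuple[float, ...] = (1.0, 1.5, 2.5)  # multipliers of r0
    normalization: str = "first_structure"  # or 'shorter'

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.s_min <= 0:
            raise ValueError("r0 and s_min must be positive")
        if list(self.d_steps) != sorted(set(self.d_steps)):
            raise ValueError("d_steps multipliers must be strictly increasing")
        if self.mode not in ("forward", "mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclasses.dataclass
class SimilarityMatrix:
    values: np.ndarray  # (N, M), in [0, 1]
    d_r: float
    d0: float
    superposition: Superposition


@dataclasses.dataclass(frozen=True)
class AlignedSegment:
    """A run of residue pairs (alpha+m, beta+m) or (alpha+m, beta-m)."""

    alpha: int  # query start (sequential_index)
    beta: int  # model start
    length: int
    direction: str  # FORWARD or REVERSE
    score: float = 0.0

    def pairs(self) -> list[tuple[int, int]]:
        step = 1 if self.direction == FORWARD else -1
        return [(self.alpha + m, self.beta + step * m) for m in range(self.length)]

    def key(self) -> tuple[int, int, int, str]:
        return (self.alpha, self.beta, self.length, self.direction)


@dataclasses.dataclass
class Alignment:
    segments: list[AlignedSegment]
    superposition: Superposition
    mtm: float = 0.0
    total_segment_score: float = 0.0
    n_refine_iters: int = 0
    seed_rank: int | None = None
    stats: object | None = None  # evaluation.AlignmentStats, filled by align_pair

    def pairs(self) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for seg in self.segments:
            out.extend(seg.pairs())
        return sorted(out)

    @property
    def n_pairs(self) -> int:
        return sum(seg.length for seg in self.segments)

    def segment_key(self) -> frozenset:
        return frozenset(seg.key() for seg in self.segments)


def compute_d0(length: int) -> float:
    """TM-score length normalization scale, clamped below at 0.5 Angstrom.

    The raw formula 1.24 (L - 15)^(1/3) - 1.8 goes non-positive for short
    chains (L <= 19); the clamp keeps the similarity well defined there.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    raw = 1.24 * np.cbrt(length - 15.0) - 1.8
    return float(max(raw, 0.5))


def similarity_matrix(
    query: ProteinStructure,
    model: ProteinStructure,
    query_labels: Sequence[str],
    model_labels: Sequence[str],
    sup: Superposition,
    d_r: float,
    params: AlignParams,
    d0: float | None = None,
) -> SimilarityMatrix:
    """Distance-and-SSE similarity of every (query i, model j) residue pair.

    M_ij = [1 / (1 + d_ij^2 / d0^2)] * [(delta_ij + w) / (1 + w)] for
    d_ij <= d_r, else 0; delta_ij = 1 iff the three-state labels agree.
    """
    if d0 is None:
        d0 = compute_d0(_norm_length(query, model, params))
    qc = query.coords
    mc = apply_superposition(model.coords, sup)
    d = cdist(qc, mc)
    base = 1.0 / (1.0 + (d / d0) ** 2)
    ql = np.asarray(query_labels)
    ml = np.asarray(model_labels)
    delta = (ql[:, None] == ml[None, :]).astype(float)
    values = base * (delta + params.w) / (1.0 + params.w)
    values[d > d_r] = 0.0
    return SimilarityMatrix(values=values, d_r=d_r, d0=d0, superposition=sup)


def _norm_length(
    query: ProteinStructure, model: ProteinStructure, params: AlignParams
) -> int:
    if params.normalization == "shorter":
        return min(len(query), len(model))
    return len(query)


# ---------------------------------------------------------------------------
# segment search


def _run_dp(
    eff: np.ndarray,
    pos: np.ndarray,
    qbreak: np.ndarray,
    mbreak: np.ndarray,
    reverse: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative scores/lengths of positive runs ending at each cell.

    Returns (S, L, ends): run score, run length, and a mask of cells at
    which a maximal run terminates.  Forward runs step (+1, +1); reverse
    runs step (+1, -1).  Runs never cross a chain break of either structure.
    """
    n, m = eff.shape
    score = eff.copy()
    length = pos.astype(np.int64)
    if reverse:
        for i in range(1, n):
            if qbreak[i]:
                continue
            cont = pos[i, :-1] & pos[i - 1, 1:] & ~mbreak[1:]
            score[i, :-1][cont] += score[i - 1, 1:][cont]
            length[i, :-1][cont] += length[i - 1, 1:][cont]
        ends = pos.copy()
        if n > 1 and m > 1:
            cont_next = pos[1:, :-1].copy()
            cont_next[qbreak[1:], :] = False
            cont_next[:, mbreak[1:]] = False
            ends[:-1, 1:] = pos[:-1, 1:] & ~cont_next
    else:
        for i in range(1, n):
            if qbreak[i]:
                continue
            cont = pos[i, 1:] & pos[i - 1, :-1] & ~mbreak[1:]
            score[i, 1:][cont] += score[i - 1, :-1][cont]
            length[i, 1:][cont] += length[i - 1, :-1][cont]
        ends = pos.copy()
        if n > 1 and m > 1:
            cont_next = pos[1:, 1:].copy()
            cont_next[qbreak[1:], :] = False
            cont_next[:, mbreak[1:]] = False
            ends[:-1, :-1] = pos[:-1, :-1] & ~cont_next
    return score, length, ends


def _best_in_direction(
    eff: np.ndarray,
    pos: np.ndarray,
    qbreak: np.ndarray,
    mbreak: np.ndarray,
    direction: str,
) -> AlignedSegment | None:
    reverse = direction == REVERSE
    score, length, ends = _run_dp(eff, pos, qbreak, mbreak, reverse)
    masked = np.where(ends, score, -np.inf)
    best = masked.max() if masked.size else -np.inf
    if not np.isfinite(best) or best <= 0.0:
        return None
    candidates = []
    for i, j in np.argwhere(masked == best):
        l = int(length[i, j])
        if reverse:
            alpha, beta = int(i) - l + 1, int(j) + l - 1
        else:
            alpha, beta = int(i) - l + 1, int(j) - l + 1
        candidates.append(AlignedSegment(alpha, beta, l, direction, float(best)))
    candidates.sort(key=lambda s: (s.alpha, s.beta))
    return candidates[0]


def best_segment(
    matrix: SimilarityMatrix,
    blocked_query: np.ndarray,
    blocked_model: np.ndarray,
    qbreak: np.ndarray,
    mbreak: np.ndarray,
    mode: str = "forward",
) -> AlignedSegment | None:
    """Highest-scoring maximal run of positive, unblocked entries.

    Runs follow forward diagonals, and anti-diagonals too in mixed mode;
    they terminate at zero entries, blocked rows/columns, and chain breaks.
    Ties prefer forward over reverse, then the smallest (alpha, beta).
    """
    eff = matrix.values.copy()
    eff[blocked_query, :] = 0.0
    eff[:, blocked_model] = 0.0
    pos = eff > 0.0
    best_fwd = _best_in_direction(eff, pos, qbreak, mbreak, FORWARD)
    if mode != "mixed":
        return best_fwd
    best_rev = _best_in_direction(eff, pos, qbreak, mbreak, REVERSE)
    if best_fwd is None:
        return best_rev
    if best_rev is None or best_rev.score <= best_fwd.score:
        return best_fwd
    return best_rev


def greedy_select(
    matrix: SimilarityMatrix,
    s_min: float,
    carried_segments: Sequence[AlignedSegment],
    mode: str,
    qbreak: np.ndarray,
    mbreak: np.ndarray,
) -> list[AlignedSegment]:
    """Greedy non-overlapping segment selection.

    Rows and columns used by carried segments are blocked first (the
    carried segments stay in the output); then the best remaining segment
    is accepted while its score reaches ``s_min``, blocking as it goes.
    """
    n, m = matrix.values.shape
    blocked_q = np.zeros(n, dtype=bool)
    blocked_m = np.zeros(m, dtype=bool)
    out = list(carried_segments)
    for seg in carried_segments:
        for qi, mi in seg.pairs():
            blocked_q[qi] = True
            blocked_m[mi] = True
    while True:
        seg = best_segment(matrix, blocked_q, blocked_m, qbreak, mbreak, mode)
        if seg is None or seg.score < s_min:
            break
        out.append(seg)
        for qi, mi in seg.pairs():
            blocked_q[qi] = True
            blocked_m[mi] = True
    return out


# ---------------------------------------------------------------------------
# stepwise sweep, scoring, refinement


def _segment_score_on(matrix: SimilarityMatrix, seg: AlignedSegment) -> float:
    return float(sum(matrix.values[qi, mi] for qi, mi in seg.pairs()))


def stepwise_alignment(
    query: ProteinStructure,
    model: ProteinStructure,
    query_labels: Sequence[str],
    model_labels: Sequence[str],
    sup: Superposition,
    params: AlignParams,
) -> Alignment:
    """Grow an alignment through the increasing-cutoff sweep under one superposition."""
    qbreak = query.break_mask()
    mbreak = model.break_mask()
    d0 = compute_d0(_norm_length(query, model, params))
    segments: list[AlignedSegment] = []
    matrix: SimilarityMatrix | None = None
    for mult in params.d_steps:
        matrix = similarity_matrix(
            query, model, query_labels, model_labels, sup, mult * params.r0, params, d0
        )
        segments = greedy_select(
            matrix, params.s_min, segments, params.mode, qbreak, mbreak
        )
    assert matrix is not None
    final = [
        dataclasses.replace(seg, score=_segment_score_on(matrix, seg))
        for seg in segments
    ]
    total = float(sum(seg.score for seg in final))
    aln = Alignment(segments=final, superposition=sup, total_segment_score=total)
    aln.mtm = mtm_score(aln, query, model, query_labels, model_labels, params)
    return aln


def mtm_score(
    alignment: Alignment,
    query: ProteinStructure,
    model: ProteinStructure,
    query_labels: Sequence[str],
    model_labels: Sequence[str],
    params: AlignParams,
) -> float:
    """Similarity at the widest cutoff summed over aligned pairs / query length."""
    pairs = alignment.pairs()
    if not pairs:
        return 0.0
    norm = _norm_length(query, model, params)
    d0 = compute_d0(norm)
    d3 = params.d_steps[-1] * params.r0
    qc = query.coords
    mc = apply_superposition(model.coords, alignment.superposition)
    total = 0.0
    ql, ml = list(query_labels), list(model_labels)
    for qi, mi in pairs:
        d = float(np.linalg.norm(qc[qi] - mc[mi]))
        if d > d3:
            continue
        delta = 1.0 if ql[qi] == ml[mi] else 0.0
        total += (1.0 / (1.0 + (d / d0) ** 2)) * (delta + params.w) / (1.0 + params.w)
    return total / norm


def refine(
    query: ProteinStructure,
    model: ProteinStructure,
    query_labels: Sequence[str],
    model_labels: Sequence[str],
    initial: Alignment,
    params: AlignParams,
) -> Alignment:
    """Alternate superposition on aligned pairs with a fresh sweep; keep the best.

    Stops as soon as the mTM-score fails to improve (tolerance 1e-6) or
    after ``max_refine_iters`` rounds.  The result is never worse than the
    input alignment.
    """
    if not initial.segments:
        return initial
    best = initial
    current = initial
    qc = query.coords
    mc = model.coords
    iters = 0
    for _ in range(params.max_refine_iters):
        iters += 1
        pairs = current.pairs()
        qi = [p[0] for p in pairs]
        mi = [p[1] for p in pairs]
        sup, _ = kabsch_superpose(qc[qi], mc[mi])
        candidate = stepwise_alignment(
            query, model, query_labels, model_labels, sup, params
        )
        if candidate.mtm > best.mtm + 1e-6:
            best = candidate
            current = candidate
        else:
            break
    best = dataclasses.replace(best, n_refine_iters=iters, seed_rank=initial.seed_rank)
    return best


# ---------------------------------------------------------------------------
# full pipeline


def _dedupe_seeds(seeds: Iterable[Superposition]) -> list[Superposition]:
    """Drop near-duplicate seed transforms (keeps the first = highest vote)."""
    seen: set[tuple] = set()
    out: list[Superposition] = []
    for sup in seeds:
        key = (
            tuple(np.round(sup.rotation, 2).ravel()),
            tuple(np.round(sup.translation / 0.5).astype(int)),
        )
        if key in seen:
            continue
        seen.add(key)
        out.append(sup)
    return out


def align_pair(
    query: ProteinStructure,
    model: ProteinStructure,
    params: AlignParams | None = None,
) -> list[Alignment]:
    """Full non-sequential alignment of two structures.

    Returns alignments ranked by mTM-score (best first), deduplicated by
    their residue-pair sets and annotated with reference-independent
    statistics.  An empty list signals that no seed produced an alignment
    (for example, when the two structures share no SSE type).
    """
    from . import evaluation
    from .geometric_hashing import build_hash_table, recognize, top_superpositions
    from .sse_cess import build_cess_set, build_frames, extract_sses
    from .sse_cess import assign_secondary_structure

    if params is None:
        params = AlignParams()
    q_labels = assign_secondary_structure(query)
    m_labels = assign_secondary_structure(model)
    q_ann = extract_sses(q_labels, query)
    m_ann = extract_sses(m_labels, model)
    q_cess = build_cess_set(query, q_ann)
    m_cess = build_cess_set(model, m_ann)
    if len(q_cess) < 2 or len(m_cess) < 2:
        raise NoSSEError(
            f"need >= 2 CESS descriptors per structure "
            f"(query has {len(q_cess)}, model has {len(m_cess)})"
        )
    q_frames = build_frames(q_cess)
    m_frames = build_frames(m_cess)
    mixed = params.mode == "mixed"
    table = build_hash_table(m_cess, m_frames, params.voxel_h)
    scores = recognize(q_cess, q_frames, table, reverse_mode=mixed)
    logger.info(
        "hashing: %d/%d CESS, %d table entries, %d voted frame pairs",
        len(q_cess),
        len(m_cess),
        len(table),
        len(scores),
    )
    if not scores:
        return []
    seeds = top_superpositions(
        scores, m_frames, q_frames, K=params.top_k_seeds, include_flipped=mixed
    )
    seeds = _dedupe_seeds(seeds)
    logger.info("%d unique seed superpositions", len(seeds))

    results: list[Alignment] = []
    for rank, sup in enumerate(seeds):
        initial = stepwise_alignment(query, model, q_labels, m_labels, sup, params)
        if not initial.segments:
            continue
        initial.seed_rank = rank
        refined = refine(query, model, q_labels, m_labels, initial, params)
        if refined.mtm < initial.mtm:  # keep-best contract
            refined = dataclasses.replace(initial, n_refine_iters=refined.n_refine_iters)
        results.append(refined)

    deduped: dict[frozenset, Alignment] = {}
    for aln in results:
        key = aln.segment_key()
        prev = deduped.get(key)
        if prev is None or aln.mtm > prev.mtm:
            deduped[key] = aln
    ranked = sorted(
        deduped.values(),
        key=lambda a: (-a.mtm, -a.n_pairs, a.seed_rank if a.seed_rank is not None else 0),
    )
    smaller = min(len(query), len(model))
    for aln in ranked:
        aln.stats = evaluation.alignment_stats(aln.pairs(), query, model, smaller)
    return ranked
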