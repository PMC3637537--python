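"""SSE-level geometric hashing: candidate rigid superpositions from votes.

Preprocessing stores, for every ordered pair of model CESSs (i, j), the
position and both direction vectors of j expressed in the reference frame
of i, binned on a cubic grid.  Recognition replays the same construction
for the query and votes for (model frame, query frame) pairs whenever a
query CESS lands in an occupied cell with matching SSE type; the vote
weight rewards parallel alignment of both the axis and the perpendicular
vectors.  The top-scoring frame pairs define seed superpositions for the
residue-level stage.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .geometry import Superposition
from .sse_cess import CESS, ReferenceFrame

#: default grid resolution in Angstrom
DEFAULT_VOXEL = 3.2
_COS60 = 0.5  # cos(pi/3), the angular cutoff of the vote terms


@dataclasses.dataclass
class HashEntry:
    sse_type: str
    basis_frame_index: int
    v_para_in_frame: np.ndarray
    v_perp_in_frame: np.ndarray
    source_cess: int  # j, useful for debugging / deduplication


@dataclasses.dataclass
class HashTable:
    voxel_size_h: float
    cells: dict[tuple[int, int, int], list[HashEntry]]

    def __len__(self) -> int:
        return sum(len(v) for v in self.cells.values())


@dataclasses.dataclass
class FramePairScore:
    model_frame_i: int
    query_frame_k: int
    total_vote: float


def bin_index(point: np.ndarray, h: float) -> tuple[int, int, int]:
    """Componentwise floor binning of a point onto the cubic grid."""
    return tuple(int(math.floor(c / h)) for c in point)


def build_hash_table(
    model_cesses: Sequence[CESS],
    frames: Sequence[ReferenceFrame],
    h: float = DEFAULT_VOXEL,
) -> HashTable:
    """Store every model CESS in every other model CESS's frame."""
    if h <= 0:
        raise ValueError("voxel size must be positive")
    cells: dict[tuple[int, int, int], list[HashEntry]] = {}
    n = len(model_cesses)
    for i, frame in enumerate(frames):
        for j in range(n):
            if j == i:
                continue
            cess_j = model_cesses[j]
            pos = frame.to_frame(cess_j.r_cess)
            entry = HashEntry(
                sse_type=cess_j.sse_type,
                basis_frame_index=i,
                v_para_in_frame=frame.vector_to_frame(cess_j.v_para),
                v_perp_in_frame=frame.vector_to_frame(cess_j.v_perp),
                source_cess=j,
            )
            cells.setdefault(bin_index(pos, h), []).append(entry)
    return HashTable(voxel_size_h=h, cells=cells)


def _angle_term(cosine: float) -> float:
    """(cos - cos60)/(1 - cos60) within the 60-degree cone, else 0."""
    if cosine < _COS60:
        return 0.0
    return (cosine - _COS60) / (1.0 - _COS60)


def voting_score(
    entry: HashEntry,
    query_v_para_in_frame: np.ndarray,
    query_v_perp_in_frame: np.ndarray,
    reverse_mode: bool = False,
) -> float:
    """Vote weight in [0, 2] for one matched pair of in-frame CESS descriptions.

    The axis term uses the angle between the parallel vectors; in reverse
    mode its cosine is replaced by its absolute value so anti-parallel SSEs
    (chains running in opposite directions) also vote.  The perpendicular
    term is unchanged in either mode.
    """
    cos_theta = float(np.dot(entry.v_para_in_frame, query_v_para_in_frame))
    if reverse_mode:
        cos_theta = abs(cos_theta)
    cos_phi = float(np.dot(entry.v_perp_in_frame, query_v_perp_in_frame))
    return _angle_term(cos_theta) + _angle_term(cos_phi)


def recognize(
    query_cesses: Sequence[CESS],
    query_frames: Sequence[ReferenceFrame],
    table: HashTable,
    reverse_mode: bool = False,
) -> list[FramePairScore]:
    """Accumulate votes for every (model frame, query frame) pair.

    Only entries whose SSE type matches the query CESS's type vote.
    Result is sorted by descending vote, ties broken by ascending
    (model frame, query frame).
    """
    votes: dict[tuple[int, int], float] = {}
    if not table.cells or not query_cesses:
        return []
    h = table.voxel_size_h
    n = len(query_cesses)
    for k, frame in enumerate(query_frames):
        for l in range(n):
            if l == k:
                continue
            cess_l = query_cesses[l]
            pos = frame.to_frame(cess_l.r_cess)
            bucket = table.cells.get(bin_index(pos, h))
            if not bucket:
                continue
            v_para = frame.vector_to_frame(cess_l.v_para)
            v_perp = frame.vector_to_frame(cess_l.v_perp)
            # one query CESS corresponds to at most one model CESS per
            # basis: keep only the best-scoring entry of each basis frame
            per_basis: dict[int, float] = {}
            for entry in bucket:
                if entry.sse_type != cess_l.sse_type:
                    continue
                s = voting_score(entry, v_para, v_perp, reverse_mode)
                i = entry.basis_frame_index
                if s > per_basis.get(i, 0.0):
                    per_basis[i] = s
            for i, s in per_basis.items():
                key = (i, k)
                votes[key] = votes.get(key, 0.0) + s
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    return [
        FramePairScore(model_frame_i=i, query_frame_k=k, total_vote=v)
        for (i, k), v in ranked
    ]


def frame_pair_superposition(
    model_frame: ReferenceFrame, query_frame: ReferenceFrame, flip: bool = False
) -> Superposition:
    """Rigid transform taking model coordinates into the query frame.

    With ``flip`` the model frame's x and z axes are negated before the
    match (a proper rotation), the seed appropriate for anti-parallel
    (reverse) SSE matches.
    """
    bm = model_frame.basis
    if flip:
        bm = bm * np.array([-1.0, 1.0, -1.0])
    bq = query_frame.basis
    rot = bq @ bm.T
    tra = query_frame.origin - rot @ model_frame.origin
    return Superposition(
        rot,
        tra,
        source_frame_pair=(model_frame.cess_index, query_frame.cess_index),
    )


def top_superpositions(
    scores: Sequence[FramePairScore],
    model_frames: Sequence[ReferenceFrame],
    query_frames: Sequence[ReferenceFrame],
    K: int = 50,
    include_flipped: bool = False,
) -> list[Superposition]:
    """Seed superpositions from the top-K voted frame pairs.

    In mixed (reverse-allowing) mode each frame pair contributes both the
    direct and the axis-flipped seed, since a high vote under the
    absolute-cosine axis term can come from either orientation.
    """
    out: list[Superposition] = []
    for fps in scores[: max(K, 0)]:
        mf = model_frames[fps.model_frame_i]
        qf = query_frames[fps.query_frame_k]
        out.append(frame_pair_superposition(mf, qf))
        if include_flipped:
            out.append(frame_pair_superposition(mf, qf, flip=True))
    return out
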