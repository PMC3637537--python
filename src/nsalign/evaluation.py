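"""Alignment quality statistics, reference-dependent and -independent.

Q-score measures agreement with a trusted reference mapping; the
reference-independent statistics (N_ali, N'_ali, N_gap, RMSD, TM-score,
fragment-length distribution) characterize an alignment on its own.  An
alignment here is simply a one-to-one set of (query, model) residue-index
pairs, so any aligner's output can be evaluated.

``N_gap`` is defined connectivity-free as (number of maximal consecutively
aligned fragments) - 1, the only reading that stays meaningful for
non-sequential alignments; a per-sequence gap-opening count can be chosen
via ``gap_definition``.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from typing import Iterable, Sequence

import numpy as np

from .errors import StructureInputError, UndefinedMetricError
from .geometry import apply_superposition, kabsch_superpose
from .residue_alignment import compute_d0
from .structure_io import ProteinStructure

PairSet = Sequence[tuple[int, int]]


@dataclasses.dataclass(frozen=True)
class ReferenceAlignment:
    """A gold-standard one-to-one residue mapping."""

    pairs: frozenset  # of (query sequential_index, model sequential_index)

    def __post_init__(self) -> None:
        qs = [p[0] for p in self.pairs]
        ms = [p[1] for p in self.pairs]
        if len(set(qs)) != len(qs) or len(set(ms)) != len(ms):
            raise ValueError("reference alignment is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclasses.dataclass
class AlignmentStats:
    n_pairs: int
    n_ali_percent: float
    n_ali_prime_percent: float
    rmsd: float | None  # None when undefined (empty alignment)
    n_gap: int
    tm_score: float | None
    fragment_lengths: Counter

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["fragment_lengths"] = dict(
            sorted(self.fragment_lengths.items())
        )
        return json.dumps(payload, indent=2)


def _as_pairs(test) -> list[tuple[int, int]]:
    if hasattr(test, "pairs"):
        p = test.pairs
        p = p() if callable(p) else p
    else:
        p = test
    return sorted((int(a), int(b)) for a, b in p)


def q_score(test, reference: ReferenceAlignment) -> float:
    """Percentage of reference pairs reproduced by the test alignment."""
    if len(reference) == 0:
        raise UndefinedMetricError("Q-score undefined for an empty reference")
    test_pairs = set(_as_pairs(test))
    return 100.0 * len(test_pairs & set(reference.pairs)) / len(reference)


def decompose_fragments(pairs: PairSet) -> list[list[tuple[int, int]]]:
    """Split a one-to-one pair set into maximal consecutively aligned runs.

    A run steps (+1, +1) (forward) or (+1, -1) (reverse); direction is
    fixed by its first two pairs.  The scan walks query indices in
    ascending order.
    """
    ordered = _as_pairs(pairs)
    fragments: list[list[tuple[int, int]]] = []
    current: list[tuple[int, int]] = []
    direction = 0  # 0 undecided, +1 forward, -1 reverse
    for pair in ordered:
        if current:
            lq, lm = current[-1]
            if pair[0] == lq + 1 and direction != 0 and pair[1] == lm + direction:
                current.append(pair)
                continue
            if pair[0] == lq + 1 and direction == 0 and abs(pair[1] - lm) == 1:
                direction = pair[1] - lm
                current.append(pair)
                continue
            fragments.append(current)
        current = [pair]
        direction = 0
    if current:
        fragments.append(current)
    return fragments


def tm_score(
    pairs: PairSet,
    query: ProteinStructure,
    model: ProteinStructure,
    normalization_length: int,
) -> float:
    """TM-score of a fixed residue mapping, maximized over superpositions.

    Iterates superposition on the subset of pairs closer than
    max(d0, 4.8 Angstrom), starting from all pairs, until the subset is
    stable, and keeps the best score seen.
    """
    ordered = _as_pairs(pairs)
    if len(ordered) < 3:
        raise UndefinedMetricError("TM-score needs at least 3 aligned pairs")
    d0 = compute_d0(normalization_length)
    cutoff = max(d0, 4.8)
    qc = query.coords[[p[0] for p in ordered]]
    mc = model.coords[[p[1] for p in ordered]]

    def score_under(sup) -> tuple[float, np.ndarray]:
        d = np.linalg.norm(qc - apply_superposition(mc, sup), axis=1)
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / normalization_length), d

    subset = np.ones(len(ordered), dtype=bool)
    best = 0.0
    for _ in range(30):
        sup, _rmsd = kabsch_superpose(qc[subset], mc[subset])
        score, d = score_under(sup)
        best = max(best, score)
        new_subset = d < cutoff
        if new_subset.sum() < 3 or np.array_equal(new_subset, subset):
            break
        subset = new_subset
    return best


def alignment_stats(
    test,
    query: ProteinStructure,
    model: ProteinStructure,
    smaller_length: int,
    gap_definition: str = "fragments",
) -> AlignmentStats:
    """Reference-independent statistics of one alignment.

    N_ali normalizes the aligned-pair count by the smaller protein's
    length; N'_ali additionally drops fragments shorter than 3 pairs.
    """
    pairs = _as_pairs(test)
    if not pairs:
        return AlignmentStats(0, 0.0, 0.0, None, 0, None, Counter())
    fragments = decompose_fragments(pairs)
    lengths = Counter(len(f) for f in fragments)
    n_pairs = len(pairs)
    n_prime = sum(len(f) for f in fragments if len(f) >= 3)
    if gap_definition == "fragments":
        n_gap = max(len(fragments) - 1, 0)
    else:
        raise ValueError(f"unknown gap definition {gap_definition!r}")
    qc = query.coords[[p[0] for p in pairs]]
    mc = model.coords[[p[1] for p in pairs]]
    _, rmsd = kabsch_superpose(qc, mc)
    tm = tm_score(pairs, query, model, smaller_length) if n_pairs >= 3 else None
    return AlignmentStats(
        n_pairs=n_pairs,
        n_ali_percent=100.0 * n_pairs / smaller_length,
        n_ali_prime_percent=100.0 * n_prime / smaller_length,
        rmsd=rmsd,
        n_gap=n_gap,
        tm_score=tm,
        fragment_lengths=lengths,
    )


# ---------------------------------------------------------------------------
# TSV interchange for reference alignments


def write_reference_tsv(
    pairs: Iterable[tuple[str, int, str, int]], path
) -> None:
    """Write (query_chain, query_resnum, model_chain, model_resnum) rows."""
    with open(path, "w") as fh:
        fh.write("# query_chain\tquery_resnum\tmodel_chain\tmodel_resnum\n")
        for qc, qn, mc, mn in pairs:
            fh.write(f"{qc}\t{qn}\t{mc}\t{mn}\n")


def read_reference_tsv(
    path, query: ProteinStructure, model: ProteinStructure
) -> ReferenceAlignment:
    """Read a reference alignment and resolve it to sequential indices."""

    def index_of(structure: ProteinStructure, chain: str, resnum: int, line: int) -> int:
        for rec in structure.residues:
            if rec.chain_id == chain and rec.residue_number == resnum:
                return rec.sequential_index
        raise StructureInputError(
            f"{path}:{line}: residue {chain}{resnum} not found in structure"
        )

    pairs = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise StructureInputError(
                    f"{path}:{lineno}: expected at least 4 tab-separated fields"
                )
            qc, qn, mc, mn = fields[:4]  # extra columns (distances etc.) ignored
            try:
                qn_i, mn_i = int(qn), int(mn)
            except ValueError as exc:
                raise StructureInputError(
                    f"{path}:{lineno}: residue numbers must be integers"
                ) from exc
            pairs.add(
                (index_of(query, qc, qn_i, lineno), index_of(model, mc, mn_i, lineno))
            )
    return ReferenceAlignment(frozenset(pairs))
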