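"""Synthetic benchmark structures: ideal toy folds and segment permutations.

Toy folds are built from ideal-geometry alpha-helices (2.3 A radius, 1.5 A
rise, 100 deg/residue) and near-straight beta-strand zigzags (3.3 A axial
rise, +/-0.9 A lateral alternation plus a small seeded perturbation),
connected by smooth loop arcs.  The segment-permutation generator cuts a
structure at the midpoints of its loops, shuffles the segment order with a
seeded generator (resampling until the order changes) while leaving every
coordinate untouched, and records the ground-truth residue bijection --
yielding non-sequential alignment test pairs whose correct answer is known
exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import CannotPermuteError, GenerationError
from .evaluation import ReferenceAlignment
from .sse_cess import assign_secondary_structure, extract_sses
from .structure_io import ProteinStructure, ResidueRecord, structure_from_coords

HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
STRAND_RISE = 3.3
STRAND_LATERAL = 0.9
STRAND_JITTER = 0.18  # max per-coordinate perturbation, Angstrom
MAX_LOOP_STEP = 4.4  # consecutive C-alpha limit inside generated loops


@dataclasses.dataclass
class ToyElement:
    sse_type: str  # 'H' or 'E'
    length: int
    origin: np.ndarray  # (3,)
    axis: np.ndarray  # unit (3,)


@dataclasses.dataclass
class ToyFoldSpec:
    elements: list[ToyElement]
    loop_length: int = 4
    seed: int = 0


@dataclasses.dataclass
class PermutationRecord:
    segment_boundaries: list[tuple[int, int]]  # inclusive, original indexing
    new_order: list[int]
    mapping: dict[int, int]  # original sequential_index -> permuted index


def _orthonormal_to(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(axis, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    p = ref - np.dot(ref, axis) * axis
    p = p / np.linalg.norm(p)
    return p, np.cross(axis, p)


def _helix_coords(element: ToyElement, rng: np.random.Generator | None = None) -> np.ndarray:
    u = element.axis / np.linalg.norm(element.axis)
    p, q = _orthonormal_to(u)
    t = np.arange(element.length)
    ang = np.deg2rad(HELIX_TWIST_DEG) * t
    coords = (
        element.origin
        + np.outer(HELIX_RISE * t, u)
        + HELIX_RADIUS * (np.outer(np.cos(ang), p) + np.outer(np.sin(ang), q))
    )
    if rng is not None:
        # break the exact on-axis degeneracy of ideal-helix window points
        coords = coords + rng.uniform(-STRAND_JITTER, STRAND_JITTER, coords.shape)
    return coords


def _strand_coords(element: ToyElement, rng: np.random.Generator) -> np.ndarray:
    u = element.axis / np.linalg.norm(element.axis)
    p, _ = _orthonormal_to(u)
    t = np.arange(element.length)
    lateral = STRAND_LATERAL * ((-1.0) ** t)
    coords = element.origin + np.outer(STRAND_RISE * t, u) + np.outer(lateral, p)
    coords = coords + rng.uniform(-STRAND_JITTER, STRAND_JITTER, coords.shape)
    return coords


def _loop_coords(
    start: np.ndarray,
    end: np.ndarray,
    n: int,
    bulge_dir: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """n interior points along a bulged quadratic arc from start to end."""
    chord = end - start
    mid = (start + end) / 2.0
    span = float(np.linalg.norm(chord))
    bulge = mid + bulge_dir * max(2.0, 0.25 * span)
    ts = np.linspace(0.0, 1.0, n + 2)[1:-1]
    pts = (
        np.outer((1 - ts) ** 2, start)
        + np.outer(2 * (1 - ts) * ts, bulge)
        + np.outer(ts**2, end)
    )
    if rng is not None:
        # a planar arc would make consecutive SSE windows exactly coplanar;
        # the perturbation removes that degeneracy
        pts = pts + rng.uniform(-STRAND_JITTER, STRAND_JITTER, pts.shape)
    return pts


def make_toy_structure(spec: ToyFoldSpec) -> ProteinStructure:
    """Realize a toy fold specification as a single-chain C-alpha trace."""
    rng = np.random.default_rng(spec.seed)
    pieces: list[np.ndarray] = []
    for idx, element in enumerate(spec.elements):
        if element.sse_type == "H":
            coords = _helix_coords(element, rng)
        elif element.sse_type == "E":
            coords = _strand_coords(element, rng)
        else:
            raise GenerationError(f"unknown element type {element.sse_type!r}")
        if pieces:
            prev_end = pieces[-1][-1]
            gap = float(np.linalg.norm(coords[0] - prev_end))
            needed = int(np.ceil(gap / 3.5))
            if spec.loop_length + 1 < needed - 1:
                raise GenerationError(
                    f"loop of {spec.loop_length} residues cannot bridge "
                    f"{gap:.1f} A between elements {idx - 1} and {idx}"
                )
            bulge_dir, _ = _orthonormal_to(
                (coords[0] - prev_end) / max(gap, 1e-9)
            )
            loop = _loop_coords(prev_end, coords[0], spec.loop_length, bulge_dir, rng)
            steps = np.linalg.norm(
                np.diff(np.vstack([prev_end, loop, coords[0]]), axis=0), axis=1
            )
            if np.any(steps > MAX_LOOP_STEP):
                raise GenerationError(
                    f"loop between elements {idx - 1} and {idx} needs a step of "
                    f"{steps.max():.1f} A (> {MAX_LOOP_STEP} A)"
                )
            pieces.append(loop)
        pieces.append(coords)
    coords = np.vstack(pieces)
    return structure_from_coords(coords, label=f"toy-{spec.seed}")


def sample_toy_spec(
    seed: int,
    n_elements: tuple[int, int] = (3, 6),
    loop_length: tuple[int, int] = (4, 6),
) -> ToyFoldSpec:
    """Draw a random compact toy fold (3-6 SSEs, ~40-120 residues).

    Elements are laid side by side with alternating up/down axes (an
    antiparallel bundle/sheet-like arrangement) with small seeded jitter in
    placement and orientation.
    """
    rng = np.random.default_rng(seed)
    k = int(rng.integers(n_elements[0], n_elements[1] + 1))
    loop = int(rng.integers(loop_length[0], loop_length[1] + 1))
    # element lengths leave >= 6 (helix) / 3 (strand) interior residues for
    # the distance-pattern labeler, which cannot classify the 2 residues at
    # each element edge
    kinds = ["H" if rng.random() < 0.5 else "E" for _ in range(k)]
    lengths = [
        int(rng.integers(11, 17)) if t == "H" else int(rng.integers(8, 13))
        for t in kinds
    ]
    total = sum(lengths) + (k - 1) * loop
    while total < 40:  # pad short draws into the intended 40-120 range
        lengths = [n + 1 for n in lengths]
        total = sum(lengths) + (k - 1) * loop
    while total > 120:
        lengths = [max(n - 1, 8) for n in lengths]
        new_total = sum(lengths) + (k - 1) * loop
        if new_total == total:
            break
        total = new_total
    elements: list[ToyElement] = []
    x = 0.0
    z = 0.0  # each element starts near the previous element's end
    for i, (sse_type, length) in enumerate(zip(kinds, lengths)):
        if sse_type == "H":
            spacing = 10.0
            extent = HELIX_RISE * (length - 1)
        else:
            spacing = 5.2
            extent = STRAND_RISE * (length - 1)
        direction = 1.0 if i % 2 == 0 else -1.0
        axis = np.array(
            [0.12 * rng.standard_normal(), 0.12 * rng.standard_normal(), direction]
        )
        axis = axis / np.linalg.norm(axis)
        origin = np.array([x, float(rng.uniform(-1.5, 1.5)), z])
        elements.append(ToyElement(sse_type, length, origin, axis))
        z = z + float(axis[2]) * extent
        x += spacing
    return ToyFoldSpec(elements=elements, loop_length=loop, seed=seed)


def make_random_toy_fold(seed: int, **kwargs) -> ProteinStructure:
    return make_toy_structure(sample_toy_spec(seed, **kwargs))


# ---------------------------------------------------------------------------
# segment permutation


def _cut_points(labels: Sequence[str], structure: ProteinStructure) -> list[int]:
    """One cut at the midpoint of each maximal coil run between SSEs."""
    annotation = extract_sses(labels, structure)
    sses = annotation.sses
    cuts: list[int] = []
    for (_, _, end_a), (_, start_b, _) in zip(sses, sses[1:]):
        if start_b <= end_a + 1:
            continue  # adjacent SSEs: no loop to cut
        cuts.append((end_a + 1 + start_b) // 2)
    return cuts


def permute_segments(
    structure: ProteinStructure,
    labels: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[ProteinStructure, PermutationRecord]:
    """Shuffle the chain's segments without moving any atom.

    The chain is split at every loop midpoint between consecutive SSEs;
    segment order is drawn from a seeded generator, resampled until it is
    not the identity.  The permuted structure keeps every coordinate,
    renumbers residues sequentially (with a numbering gap at each junction
    so the breaks survive a round trip through PDB), and records chain
    breaks at the junctions plus the original->permuted index bijection.
    """
    if labels is None:
        labels = assign_secondary_structure(structure)
    cuts = _cut_points(labels, structure)
    n = len(structure)
    starts = [0] + cuts
    boundaries = [
        (s, (cuts + [n])[i] - 1) for i, s in enumerate(starts)
    ]
    if len(boundaries) < 2:
        raise CannotPermuteError(
            "structure splits into fewer than two segments; nothing to permute"
        )
    rng = np.random.default_rng(seed)
    order = list(range(len(boundaries)))
    while True:
        perm = [int(v) for v in rng.permutation(len(boundaries))]
        if perm != order:
            break
    mapping: dict[int, int] = {}
    residues: list[ResidueRecord] = []
    breaks: set[int] = set()
    resnum = 0
    for seg_pos, seg_idx in enumerate(perm):
        start, end = boundaries[seg_idx]
        if residues:
            breaks.add(len(residues))
            resnum += 2  # numbering gap marks the junction in PDB output
        for orig in range(start, end + 1):
            resnum += 1
            new_index = len(residues)
            mapping[orig] = new_index
            residues.append(
                ResidueRecord(
                    chain_id="A",
                    residue_number=resnum,
                    insertion_code="",
                    ca_coordinate=structure.residues[orig].ca_coordinate,
                    sequential_index=new_index,
                )
            )
    breaks.add(0)
    permuted = ProteinStructure(residues, breaks, label=structure.label + "-perm")
    record = PermutationRecord(
        segment_boundaries=boundaries, new_order=perm, mapping=mapping
    )
    return permuted, record


def ground_truth_reference(record: PermutationRecord) -> ReferenceAlignment:
    """The exact residue bijection original -> permuted as an alignment."""
    return ReferenceAlignment(
        frozenset((orig, new) for orig, new in record.mapping.items())
    )


def remap_reference(
    reference: ReferenceAlignment, record: PermutationRecord
) -> ReferenceAlignment:
    """Push the model side of a reference through the permutation bijection."""
    out = set()
    for q, m in reference.pairs:
        if m not in record.mapping:
            raise ValueError(f"model index {m} not covered by the permutation")
        out.add((q, record.mapping[m]))
    return ReferenceAlignment(frozenset(out))


def inverse_record(record: PermutationRecord) -> PermutationRecord:
    inv = {v: k for k, v in record.mapping.items()}
    return PermutationRecord(
        segment_boundaries=record.segment_boundaries,
        new_order=list(np.argsort(record.new_order)),
        mapping=inv,
    )
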