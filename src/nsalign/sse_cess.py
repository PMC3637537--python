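"""Secondary structure from C-alpha geometry and SSE vector descriptors.

Residues are labeled helix (H), strand (E) or coil (C) purely from the
pattern of C-alpha--C-alpha distances in a five-residue window, the fast
assignment used by TM-score-family tools for C-alpha-only models.  Maximal
H/E runs become secondary structure elements (SSEs); each SSE is then
summarized by a ladder of overlapping short windows (6 residues per helix
window, 3 per strand window), every window contributing one comparing
element (CESS): a representative point plus parallel and perpendicular unit
vectors.  Multiple CESS per SSE is what lets the aligner follow bent or
twisted long elements.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .structure_io import ProteinStructure

logger = logging.getLogger(__name__)

#: minimum SSE length retained at the element level
MIN_HELIX_LEN = 6
MIN_STRAND_LEN = 3
#: short-window (SSSSE) sizes
HELIX_WINDOW = 6
STRAND_WINDOW = 3

# ideal C-alpha distance patterns (Angstrom) for the five-residue window:
# separations (i,i+2), (i,i+3), (i,i+4)
_HELIX_IDEAL = (5.45, 5.18, 6.37)
_HELIX_TOL = 2.1
_STRAND_IDEAL = (6.1, 10.4, 13.0)
_STRAND_TOL = 1.42


@dataclasses.dataclass
class SSEAnnotation:
    """Per-residue labels plus the filtered element list."""

    labels: list[str]  # 'H' / 'E' / 'C', one per residue
    sses: list[tuple[str, int, int]]  # (type, start, end) inclusive


@dataclasses.dataclass
class CESS:
    """Comparing element of one short SSE window."""

    sse_type: str  # 'H' or 'E'
    parent_sse: int
    start_residue_k: int  # sequential_index of the window's first residue
    r_cess: np.ndarray  # representative point (3,)
    v_para: np.ndarray  # unit vector, N->C direction of the window
    v_perp: np.ndarray  # unit vector orthogonal to v_para
    r_pdef: np.ndarray  # point defining the perpendicular direction


@dataclasses.dataclass
class ReferenceFrame:
    """Right-handed orthonormal frame anchored on one CESS."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    cess_index: int

    @property
    def basis(self) -> np.ndarray:
        """3x3 matrix whose columns are the frame axes."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def to_frame(self, coords: np.ndarray) -> np.ndarray:
        """Express world coordinates in this frame."""
        return (np.asarray(coords) - self.origin) @ self.basis

    def vector_to_frame(self, vec: np.ndarray) -> np.ndarray:
        """Express a direction (no origin shift) in this frame."""
        return np.asarray(vec) @ self.basis


def _window_pattern(coords: np.ndarray) -> str:
    """Classify a five-residue window by its C-alpha distance pattern."""
    d = lambda i, j: float(np.linalg.norm(coords[i] - coords[j]))
    sep2 = (d(0, 2), d(1, 3), d(2, 4))
    sep3 = (d(0, 3), d(1, 4))
    sep4 = (d(0, 4),)
    for ideal, tol, code in (
        (_HELIX_IDEAL, _HELIX_TOL, "H"),
        (_STRAND_IDEAL, _STRAND_TOL, "E"),
    ):
        ok = (
            all(abs(x - ideal[0]) < tol for x in sep2)
            and all(abs(x - ideal[1]) < tol for x in sep3)
            and abs(sep4[0] - ideal[2]) < tol
        )
        if ok:
            return code
    return "C"


def assign_secondary_structure(
    structure: ProteinStructure, smooth: bool = True
) -> list[str]:
    """Three-state secondary structure labels from C-alpha geometry alone.

    Residues whose five-residue window (i-2..i+2) leaves the continuous
    stretch (chain break or terminus) are labeled coil.  With ``smooth``
    a single pass relabels isolated singletons flanked by a common label.
    """
    n = len(structure)
    labels = ["C"] * n
    coords = structure.coords
    for start, end in structure.stretches():
        for i in range(start + 2, end - 1):
            labels[i] = _window_pattern(coords[i - 2 : i + 3])
        if smooth:
            for i in range(start + 1, end):
                if labels[i - 1] == labels[i + 1] != labels[i]:
                    labels[i] = labels[i - 1]
    return labels


def extract_sses(labels: Sequence[str], structure: ProteinStructure) -> SSEAnnotation:
    """Maximal H/E runs within continuous stretches, length-filtered.

    Helix runs shorter than 6 and strand runs shorter than 3 are dropped
    from the element list; their per-residue labels are kept (the residue
    level similarity still uses them).
    """
    if len(labels) != len(structure):
        raise ValueError("labels length must match structure length")
    sses: list[tuple[str, int, int]] = []
    for start, end in structure.stretches():
        i = start
        while i <= end:
            code = labels[i]
            j = i
            while j + 1 <= end and labels[j + 1] == code:
                j += 1
            if code == "H" and j - i + 1 >= MIN_HELIX_LEN:
                sses.append(("H", i, j))
            elif code == "E" and j - i + 1 >= MIN_STRAND_LEN:
                sses.append(("E", i, j))
            i = j + 1
    return SSEAnnotation(list(labels), sses)


_HELIX_END_W = np.array([0.74, 1.0, 1.0, 0.74]) / 3.48


def _window_ends(coords: np.ndarray, sse_type: str) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed N- and C-terminal anchor points of one short window."""
    if sse_type == "H":
        init = _HELIX_END_W @ coords[0:4]
        end = _HELIX_END_W @ coords[2:6]
    else:
        init = (coords[0] + coords[1]) / 2.0
        end = (coords[1] + coords[2]) / 2.0
    return init, end


def _perp_component(vec: np.ndarray, axis: np.ndarray) -> np.ndarray:
    return vec - np.dot(vec, axis) * axis


def build_cess_set(
    structure: ProteinStructure, annotation: SSEAnnotation
) -> list[CESS]:
    """One CESS per short window: n-5 per helix of length n, n-2 per strand.

    For each window starting at residue k the representative point is the
    midpoint of the smoothed window ends, the parallel vector points N->C
    along the window, and the perpendicular vector is the unit component of
    (window-center point - representative point) orthogonal to the axis.
    """
    coords = structure.coords
    out: list[CESS] = []
    for sse_idx, (sse_type, start, end) in enumerate(annotation.sses):
        win = HELIX_WINDOW if sse_type == "H" else STRAND_WINDOW
        for k in range(start, end - win + 2):
            block = coords[k : k + win]
            r_init, r_end = _window_ends(block, sse_type)
            axis = r_end - r_init
            norm = float(np.linalg.norm(axis))
            if norm < 1e-9:
                logger.warning(
                    "degenerate window axis at residue %d of SSE %d; skipped",
                    k,
                    sse_idx,
                )
                continue
            v_para = axis / norm
            r_cess = (r_init + r_end) / 2.0
            if sse_type == "H":
                r_pdef = (coords[k + 2] + coords[k + 3]) / 2.0
            else:
                r_pdef = coords[k + 1]
            perp = _perp_component(r_pdef - r_cess, v_para)
            pnorm = float(np.linalg.norm(perp))
            if pnorm < 1e-6:
                # perfectly straight synthetic strand: fall back to a fixed
                # global direction so the frame stays deterministic
                for fallback in (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0])):
                    perp = _perp_component(fallback, v_para)
                    pnorm = float(np.linalg.norm(perp))
                    if pnorm > 1e-6:
                        break
            v_perp = perp / pnorm
            out.append(
                CESS(
                    sse_type=sse_type,
                    parent_sse=sse_idx,
                    start_residue_k=k,
                    r_cess=r_cess,
                    v_para=v_para,
                    v_perp=v_perp,
                    r_pdef=r_pdef,
                )
            )
    return out


def build_reference_frame(cess: CESS, index: int = -1) -> ReferenceFrame:
    """Orthonormal frame: x along the window axis, y perpendicular, z = x cross y."""
    x = cess.v_para / np.linalg.norm(cess.v_para)
    y = _perp_component(cess.v_perp, x)
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    return ReferenceFrame(
        origin=np.array(cess.r_cess, dtype=float),
        x_axis=x,
        y_axis=y,
        z_axis=z,
        cess_index=index,
    )


def build_frames(cesses: Sequence[CESS]) -> list[ReferenceFrame]:
    return [build_reference_frame(c, i) for i, c in enumerate(cesses)]


def labels_to_string(labels: Sequence[str]) -> str:
    """Debug helper: one-letter label string."""
    return "".join(labels)
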