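"""Rigid-body mathematics: least-squares superposition and transforms."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import NSAlignError


@dataclasses.dataclass(frozen=True)
class Superposition:
    """A proper rigid transform x -> rotation @ x + translation (Angstrom)."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    source_frame_pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tra = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or tra.shape != (3,):
            raise NSAlignError("superposition needs a 3x3 rotation and 3-vector")
        if abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise NSAlignError("rotation matrix is not proper (det != +1)")
        if np.max(np.abs(rot @ rot.T - np.eye(3))) > 1e-6:
            raise NSAlignError("rotation matrix is not orthonormal")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @classmethod
    def identity(cls) -> "Superposition":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "Superposition":
        rot_inv = self.rotation.T
        return Superposition(rot_inv, -rot_inv @ self.translation)

    def compose(self, other: "Superposition") -> "Superposition":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return Superposition(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def apply_superposition(coords: np.ndarray, sup: Superposition) -> np.ndarray:
    """Apply a rigid transform to an (N, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    return coords @ sup.rotation.T + sup.translation


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[Superposition, float]:
    """Optimal proper-rotation superposition of ``coords_b`` onto ``coords_a``.

    Returns the rigid transform minimizing the RMSD between ``coords_a`` and
    the transformed ``coords_b``, together with that minimum RMSD.  The
    rotation is always proper (no reflections), preserving chirality.
    Rank-deficient inputs (a single point, collinear points) return one of
    the tied minimizers.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise NSAlignError(
            f"coordinate sets must both be (N, 3); got {a.shape} and {b.shape}"
        )
    if len(a) == 0:
        raise NSAlignError("cannot superpose empty point sets")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    if len(a) == 1:
        return Superposition(np.eye(3), cen_a - cen_b), 0.0
    with warnings.catch_warnings():
        # rank-deficient point sets make the optimum non-unique; any
        # minimizer is acceptable per the contract
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(a - cen_a, b - cen_b)
    matrix = rot.as_matrix()
    sup = Superposition(matrix, cen_a - matrix @ cen_b)
    rmsd = float(rssd) / np.sqrt(len(a))
    return sup, rmsd
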