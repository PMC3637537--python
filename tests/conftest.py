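import dataclasses

import numpy as np
import pytest

from nsalign import benchmark_gen as bg
from nsalign.geometry import Superposition, apply_superposition
from nsalign.structure_io import ProteinStructure, structure_from_coords


def ideal_helix(n: int, origin=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    el = bg.ToyElement("H", n, np.asarray(origin, float), np.asarray(axis, float))
    return bg._helix_coords(el)


def ideal_strand(n: int, origin=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0), seed=0) -> np.ndarray:
    el = bg.ToyElement("E", n, np.asarray(origin, float), np.asarray(axis, float))
    return bg._strand_coords(el, np.random.default_rng(seed))


def transform_structure(structure: ProteinStructure, sup: Superposition) -> ProteinStructure:
    moved = apply_superposition(structure.coords, sup)
    residues = [
        dataclasses.replace(r, ca_coordinate=c)
        for r, c in zip(structure.residues, moved)
    ]
    return ProteinStructure(residues, set(structure.chain_breaks), structure.label)


def random_rigid(rng: np.random.Generator) -> Superposition:
    from scipy.spatial.transform import Rotation

    return Superposition(
        Rotation.random(random_state=rng).as_matrix(), rng.uniform(-20.0, 20.0, 3)
    )


@pytest.fixture
def helix_structure() -> ProteinStructure:
    return structure_from_coords(ideal_helix(12), label="helix12")


@pytest.fixture
def toy_fold() -> ProteinStructure:
    return bg.make_random_toy_fold(1)


@pytest.fixture
def toy_pair():
    fold = bg.make_random_toy_fold(2)
    permuted, record = bg.permute_segments(fold, seed=1002)
    return fold, permuted, record
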