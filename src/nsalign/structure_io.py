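"""Read and write protein structures as ordered C-alpha traces.

Only C-alpha atoms of ATOM records are kept, so C-alpha-only models and
multi-chain complexes are first-class inputs.  Chains are concatenated in
file order and every loss of backbone continuity (chain change, gap in
author numbering, or a C-alpha--C-alpha jump beyond ``MAX_CA_CA``) is
recorded as a chain break.  All downstream algorithms address residues by
0-based ``sequential_index`` into the concatenated trace.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import EmptyStructureError, StructureInputError

#: two consecutive residues further apart than this (in Angstrom) are
#: treated as discontinuous even when the numbering is consecutive
MAX_CA_CA = 4.5


@dataclasses.dataclass(frozen=True)
class ResidueRecord:
    """One residue reduced to its C-alpha atom."""

    chain_id: str
    residue_number: int
    insertion_code: str
    ca_coordinate: np.ndarray  # shape (3,), Angstrom
    sequential_index: int

    def __post_init__(self) -> None:
        coord = np.asarray(self.ca_coordinate, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise StructureInputError(
                f"non-finite or malformed C-alpha coordinate for residue "
                f"{self.chain_id}{self.residue_number}{self.insertion_code}"
            )
        object.__setattr__(self, "ca_coordinate", coord)


@dataclasses.dataclass
class ProteinStructure:
    """An ordered C-alpha trace with recorded continuity breaks.

    ``chain_breaks`` holds the ``sequential_index`` of the *first* residue of
    every continuous stretch (index 0 is always a member for non-empty
    structures).
    """

    residues: list[ResidueRecord]
    chain_breaks: set[int]
    label: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of C-alpha coordinates in file order."""
        if not self.residues:
            return np.zeros((0, 3))
        return np.array([r.ca_coordinate for r in self.residues])

    def break_mask(self) -> np.ndarray:
        """Boolean (N,) mask, True where a new continuous stretch starts."""
        mask = np.zeros(len(self.residues), dtype=bool)
        for idx in self.chain_breaks:
            mask[idx] = True
        return mask

    def stretches(self) -> list[tuple[int, int]]:
        """Continuous stretches as (start, end) inclusive index pairs."""
        if not self.residues:
            return []
        starts = sorted(self.chain_breaks | {0})
        ends = [s - 1 for s in starts[1:]] + [len(self.residues) - 1]
        return list(zip(starts, ends))


def _first_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    # first C-alpha in file order == first alternate location
    for atom in residue:
        if atom.name == "CA":
            return atom
    return None


def structure_from_coords(
    coords: Sequence[Sequence[float]] | np.ndarray,
    chain_id: str = "A",
    chain_breaks: Iterable[int] = (0,),
    label: str = "",
    residue_numbers: Sequence[int] | None = None,
) -> ProteinStructure:
    """Build an in-memory structure directly from a coordinate array."""
    coords = np.asarray(coords, dtype=float)
    if residue_numbers is None:
        residue_numbers = list(range(1, len(coords) + 1))
    residues = [
        ResidueRecord(chain_id, int(num), "", c, i)
        for i, (num, c) in enumerate(zip(residue_numbers, coords))
    ]
    breaks = set(int(b) for b in chain_breaks)
    if residues:
        breaks.add(0)
    return ProteinStructure(residues, breaks, label)


def read_structure(
    path: str | os.PathLike,
    chain_filter: set[str] | None = None,
    model_index: int = 0,
) -> ProteinStructure:
    """Parse a PDB file into a C-alpha trace.

    Parameters
    ----------
    path:
        PDB file with fixed-column ATOM records.
    chain_filter:
        Optional set of chain identifiers to keep; order of the file is
        preserved.  Requesting an absent chain is an error.
    model_index:
        0-based index into the MODEL records (for multi-model files).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise StructureInputError(f"structure file not found: {path}")
    try:
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureInputError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path}")
    if model_index >= len(st):
        raise StructureInputError(
            f"model index {model_index} out of range ({len(st)} models in {path})"
        )
    model = st[model_index]

    present_chains = [ch.name for ch in model]
    if chain_filter is not None:
        missing = sorted(set(chain_filter) - set(present_chains))
        if missing:
            raise StructureInputError(
                f"requested chain(s) {', '.join(missing)} absent from {path}"
            )

    residues: list[ResidueRecord] = []
    breaks: set[int] = set()
    seen: set[tuple[str, int, str]] = set()
    prev: ResidueRecord | None = None
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for res in chain:
            if res.het_flag == "H":
                continue
            atom = _first_ca(res)
            if atom is None:
                continue
            icode = res.seqid.icode.strip()
            key = (chain.name, res.seqid.num, icode)
            if key in seen:
                continue
            seen.add(key)
            rec = ResidueRecord(
                chain_id=chain.name,
                residue_number=res.seqid.num,
                insertion_code=icode,
                ca_coordinate=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                sequential_index=len(residues),
            )
            if prev is None:
                breaks.add(rec.sequential_index)
            else:
                numbering_gap = (
                    rec.residue_number != prev.residue_number
                    and rec.residue_number != prev.residue_number + 1
                )
                chain_change = rec.chain_id != prev.chain_id
                jump = (
                    float(np.linalg.norm(rec.ca_coordinate - prev.ca_coordinate))
                    > MAX_CA_CA
                )
                if chain_change or numbering_gap or jump:
                    breaks.add(rec.sequential_index)
            residues.append(rec)
            prev = rec
    if not residues:
        raise EmptyStructureError(f"no C-alpha atoms found in {path}")
    return ProteinStructure(residues, breaks, label=os.path.basename(path))


def _to_gemmi_model(structure: ProteinStructure, name: str) -> gemmi.Model:
    model = gemmi.Model(name)
    chain: gemmi.Chain | None = None
    for rec in structure.residues:
        if chain is None or chain.name != rec.chain_id:
            chain = gemmi.Chain(rec.chain_id)
            model.add_chain(chain)
            chain = model[-1]
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(rec.residue_number, rec.insertion_code or " ")
        res.het_flag = "A"
        res.entity_type = gemmi.EntityType.Polymer
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.occ = 1.0
        atom.b_iso = 0.0
        x, y, z = (float(v) for v in rec.ca_coordinate)
        atom.pos = gemmi.Position(x, y, z)
        res.add_atom(atom)
        chain.add_residue(res)
    return model


def write_structure(structure: ProteinStructure, path: str | os.PathLike) -> None:
    """Write a single-model C-alpha-only PDB file."""
    st = gemmi.Structure()
    st.name = structure.label or "nsalign"
    st.add_model(_to_gemmi_model(structure, "1"))
    _write_gemmi(st, path)


def write_superposed_pair(query, model, sup, path) -> None:
    """Write a two-model PDB: model 1 = query as-is, model 2 = transformed model.

    ``sup`` maps the second structure's coordinates into the query frame.
    """
    from .geometry import apply_superposition

    st = gemmi.Structure()
    st.name = "superposed"
    st.add_model(_to_gemmi_model(query, "1"))
    moved_coords = apply_superposition(model.coords, sup)
    moved = ProteinStructure(
        [
            dataclasses.replace(rec, ca_coordinate=c)
            for rec, c in zip(model.residues, moved_coords)
        ],
        set(model.chain_breaks),
        model.label,
    )
    st.add_model(_to_gemmi_model(moved, "2"))
    _write_gemmi(st, path)


def _write_gemmi(st: gemmi.Structure, path: str | os.PathLike) -> None:
    try:
        st.write_pdb(
            os.fspath(path), gemmi.PdbWriteOptions(minimal=True, numbered_ter=False)
        )
    except (OSError, RuntimeError) as exc:
        raise StructureInputError(f"cannot write PDB file {path}: {exc}") from exc
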