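"""Cα coordinate containers and PDB/mmCIF reading and writing (via gemmi)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np


class StructureError(ValueError):
    """Unreadable or inconsistent coordinate data."""


@dataclass(frozen=True, eq=False)
class StructureCoords:
    """Ordered Cα trace of one chain, indexed by 1-based residue numbers."""

    residue_ids: np.ndarray  # strictly increasing ints
    ca: np.ndarray  # (N, 3) in Å
    source: str = ""

    def __post_init__(self) -> None:
        rid = np.asarray(self.residue_ids, dtype=int)
        xyz = np.asarray(self.ca, dtype=float)
        if rid.ndim != 1 or xyz.shape != (rid.size, 3):
            raise StructureError(
                f"shape mismatch: {rid.size} residue ids vs coords {xyz.shape}"
            )
        if rid.size and np.any(np.diff(rid) <= 0):
            raise StructureError("residue_ids must be strictly increasing")
        object.__setattr__(self, "residue_ids", rid)
        object.__setattr__(self, "ca", xyz)

    def __len__(self) -> int:
        return int(self.residue_ids.size)

    def subset(self, residues: set[int] | np.ndarray) -> "StructureCoords":
        mask = np.isin(self.residue_ids, list(residues))
        return StructureCoords(
            residue_ids=self.residue_ids[mask], ca=self.ca[mask], source=self.source
        )

    def coords_for(self, residues: np.ndarray) -> np.ndarray:
        """Coordinates for the given residue ids (must all be present)."""
        index = {int(r): i for i, r in enumerate(self.residue_ids)}
        try:
            rows = [index[int(r)] for r in residues]
        except KeyError as exc:
            raise StructureError(f"residue {exc} absent from {self.source}") from None
        return self.ca[rows]


def read_structure(
    path: str | Path, chain: str | None = None, model_index: int = 0
) -> StructureCoords:
    """Read the Cα trace of one chain from a PDB or mmCIF file.

    Takes altloc A (or blank); residues with insertion codes are rejected
    because downstream matching is by plain residue number.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"coordinate file not found: {path}")
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    if not len(structure):
        raise StructureError(f"{path}: no models")
    model = structure[model_index]
    if chain is None:
        if len(model) != 1:
            names = [ch.name for ch in model]
            raise StructureError(
                f"{path}: multiple chains {names}; specify one"
            )
        gchain = model[0]
    else:
        gchain = model.find_chain(chain)
        if gchain is None:
            raise StructureError(f"{path}: chain {chain!r} not found")
    rids, coords = [], []
    for residue in gchain:
        if residue.seqid.icode.strip("\x00 "):
            raise StructureError(
                f"{path}: residue {residue.seqid.num}{residue.seqid.icode} "
                "carries an insertion code; renumber before use"
            )
        ca = None
        for atom in residue:
            if atom.name == "CA" and (not atom.has_altloc() or atom.altloc == "A"):
                ca = atom
                break
        if ca is None:
            continue
        rids.append(residue.seqid.num)
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if not rids:
        raise StructureError(f"{path}: no Cα atoms in chain {gchain.name!r}")
    order = np.argsort(rids)
    return StructureCoords(
        residue_ids=np.asarray(rids)[order],
        ca=np.asarray(coords)[order],
        source=f"{path}:{gchain.name}",
    )


def write_structure(
    coords: StructureCoords,
    path: str | Path,
    chain: str = "A",
    bfactors: np.ndarray | None = None,
) -> None:
    """Write a Cα-only chain as PDB (poly-ALA; B-factor column optional)."""
    structure = gemmi.Structure()
    structure.name = Path(path).stem
    model = gemmi.Model("1")
    gchain = gemmi.Chain(chain)
    b = np.full(len(coords), 0.0) if bfactors is None else np.asarray(bfactors, float)
    for rid, xyz, bf in zip(coords.residue_ids, coords.ca, b):
        residue = gemmi.Residue()
        residue.name = "ALA"
        residue.seqid = gemmi.SeqId(int(rid), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        atom.b_iso = float(bf)
        residue.add_atom(atom)
        gchain.add_residue(residue)
    model.add_chain(gchain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))
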