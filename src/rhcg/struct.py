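"""Lightweight atom-table container shared by fragments, chains and
ensembles, with multi-model PDB I/O through biotite.

Residue numbering is 1-based construct numbering everywhere internally;
an offset can be applied on output to recover author numbering (e.g. tau
K18 = residues 244-372).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

BACKBONE_ATOMS = ("N", "CA", "C", "O")
CAP_RESNAMES = ("ACE", "NME")


@dataclass
class Structure:
    """One conformer: parallel per-atom arrays plus coordinates in Angstrom."""

    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.res_name = np.asarray(self.res_name, dtype="U3")
        self.atom_name = np.asarray(self.atom_name, dtype="U4")
        self.element = np.asarray(self.element, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.res_id)
        if not (len(self.res_name) == len(self.atom_name) == len(self.element) == n):
            raise ValueError("atom annotation arrays have inconsistent lengths")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must have shape ({n}, 3)")

    # -- selections ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.res_id)

    @property
    def is_cap(self) -> np.ndarray:
        return np.isin(self.res_name, CAP_RESNAMES)

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique non-cap residue ids."""
        return np.unique(self.res_id[~self.is_cap])

    def select(self, mask: np.ndarray) -> "Structure":
        return Structure(
            self.res_id[mask],
            self.res_name[mask],
            self.atom_name[mask],
            self.element[mask],
            self.coords[mask],
        )

    def without_caps(self) -> "Structure":
        return self.select(~self.is_cap)

    def atom_index(self, res: int, name: str) -> int:
        idx = np.flatnonzero((self.res_id == res) & (self.atom_name == name))
        if len(idx) != 1:
            raise KeyError(f"atom {name} of residue {res}: found {len(idx)}")
        return int(idx[0])

    def atom_coord(self, res: int, name: str) -> np.ndarray:
        return self.coords[self.atom_index(res, name)]

    def backbone_indices(self, residues) -> np.ndarray:
        """Indices of N, CA, C, O for each residue, in residue-major order."""
        return np.array(
            [self.atom_index(r, a) for r in residues for a in BACKBONE_ATOMS],
            dtype=int,
        )

    def sequence(self) -> str:
        from .constants import AA1

        out = []
        for r in self.residue_ids:
            name = self.res_name[self.res_id == r][0]
            out.append(AA1.get(str(name), "X"))
        return "".join(out)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def same_topology(self, other: "Structure") -> bool:
        return (
            len(self.res_id) == len(other.res_id)
            and bool(np.all(self.res_id == other.res_id))
            and bool(np.all(self.atom_name == other.atom_name))
            and bool(np.all(self.res_name == other.res_name))
        )


def concat(parts: list[Structure]) -> Structure:
    return Structure(
        np.concatenate([p.res_id for p in parts]),
        np.concatenate([p.res_name for p in parts]),
        np.concatenate([p.atom_name for p in parts]),
        np.concatenate([p.element for p in parts]),
        np.concatenate([p.coords for p in parts]),
    )


# -- biotite bridge ---------------------------------------------------------

def _to_atom_array(s: Structure, offset: int = 0) -> bst.AtomArray:
    arr = bst.AtomArray(s.n_atoms)
    arr.coord = s.coords.astype(np.float32)
    arr.res_id = s.res_id + offset
    arr.res_name = s.res_name
    arr.atom_name = s.atom_name
    arr.element = s.element
    arr.chain_id = np.full(s.n_atoms, "A", dtype="U4")
    arr.hetero = np.isin(s.res_name, CAP_RESNAMES)
    return arr


def _from_atom_array(arr: bst.AtomArray, offset: int = 0) -> Structure:
    return Structure(
        np.asarray(arr.res_id, dtype=int) - offset,
        np.asarray(arr.res_name, dtype="U3"),
        np.asarray(arr.atom_name, dtype="U4"),
        np.asarray(arr.element, dtype="U2"),
        np.asarray(arr.coord, dtype=float),
    )


def write_models(path, models: list[Structure], offset: int = 0) -> None:
    """Write conformers as a multi-model PDB (MODEL/ENDMDL records)."""
    if not models:
        raise ValueError("no models to write")
    template = models[0]
    for m in models[1:]:
        if not m.same_topology(template):
            raise ValueError("all models must share one atom table")
    stack = bst.stack([_to_atom_array(m, offset) for m in models])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_models(path, offset: int = 0) -> list[Structure]:
    """Read a multi-model PDB into a list of conformers."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, bst.AtomArray):  # single model
        stack = bst.stack([stack])
    first = stack[0]
    res_id = np.asarray(first.res_id, dtype=int) - offset
    res_name = np.asarray(first.res_name, dtype="U3")
    atom_name = np.asarray(first.atom_name, dtype="U4")
    element = np.asarray(first.element, dtype="U2")
    return [
        Structure(res_id, res_name, atom_name, element, np.asarray(stack.coord[i], dtype=float))
        for i in range(stack.stack_depth())
    ]
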