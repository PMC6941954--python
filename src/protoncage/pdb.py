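"""Protein-structure distance checks (PDB format).

Used for active-site geometry checks such as the carboxyl-oxygen-to-water
distances around D85/D96 in bacteriorhodopsin (pdb 1c3w; file supplied by
the user).  Parsing goes through biotite; waters (HOH) are retained and
only the first alternate location of each atom is kept.  Residues are
addressed by author numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = ["Structure", "AtomSelection", "read_structure", "atom_distance",
           "parse_selection"]


@dataclass(frozen=True)
class AtomSelection:
    """Atom address: residue name + author residue number + atom name (+ chain)."""

    res_name: str
    res_id: int
    atom_name: str
    chain: str | None = None

    def __str__(self) -> str:
        chain = f"{self.chain}:" if self.chain else ""
        return f"{chain}{self.res_name} {self.res_id} {self.atom_name}"


def parse_selection(text: str) -> AtomSelection:
    """Parse ``[CHAIN:]RESNAME RESID ATOMNAME`` (e.g. ``ASP 85 OD2``)."""
    chain = None
    if ":" in text:
        chain, _, text = text.partition(":")
        chain = chain.strip() or None
    parts = text.split()
    if len(parts) != 3:
        raise ValueError(
            f"selection {text!r} must be '[CHAIN:]RESNAME RESID ATOMNAME'")
    return AtomSelection(res_name=parts[0].upper(), res_id=int(parts[1]),
                         atom_name=parts[2].upper(), chain=chain)


@dataclass
class Structure:
    """Flat atom table of one model of a PDB entry."""

    chain_id: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    atom_name: np.ndarray
    coord: np.ndarray          # (n, 3) Angstrom
    source: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def select(self, sel: AtomSelection) -> np.ndarray:
        """Indices of atoms matching the selection."""
        mask = ((self.res_name == sel.res_name)
                & (self.res_id == sel.res_id)
                & (self.atom_name == sel.atom_name))
        if sel.chain is not None:
            mask &= self.chain_id == sel.chain
        return np.nonzero(mask)[0]


def read_structure(path) -> Structure:
    """Read ATOM/HETATM records of a PDB file (first model, first altloc).

    Waters (residue name HOH) are retained.

    Raises
    ------
    ValueError
        If no atoms can be parsed.
    """
    pdb = PDBFile.read(str(path))
    try:
        atoms = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:
        raise ValueError(f"{path}: no atoms parsed ({exc})") from exc
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no atoms parsed")
    return Structure(
        chain_id=np.asarray(atoms.chain_id),
        res_name=np.asarray(atoms.res_name),
        res_id=np.asarray(atoms.res_id),
        atom_name=np.asarray(atoms.atom_name),
        coord=np.asarray(atoms.coord, float),
        source=str(path),
    )


def atom_distance(structure: Structure, sel_a, sel_b) -> tuple[float, float]:
    """Euclidean distance between two uniquely selected atoms.

    Returns ``(distance, rounded)`` in Angstrom, where ``rounded`` is the
    distance at 0.1 A rounding as commonly printed for crystal structures.

    Raises
    ------
    ValueError
        If either selection resolves to zero or more than one atom.
    """
    if isinstance(sel_a, str):
        sel_a = parse_selection(sel_a)
    if isinstance(sel_b, str):
        sel_b = parse_selection(sel_b)
    out = []
    for sel in (sel_a, sel_b):
        idx = structure.select(sel)
        if idx.size != 1:
            raise ValueError(
                f"selection {sel} resolves to {idx.size} atoms (need exactly 1)")
        out.append(structure.coord[idx[0]])
    dist = float(np.linalg.norm(out[0] - out[1]))
    return dist, round(dist, 1)
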