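"""Reading and writing protein structures in PDB format.

A :class:`ProteinStructure` is an ordered list of residues — chains
concatenated in file order — each holding its atoms with coordinates in Å.
Parsing is deterministic: the first MODEL only, alternate locations resolved
to the highest-occupancy conformer (ties broken by first encounter), one
residue per (chain, residue number, insertion code) triple.  HETATM residues
are dropped unless they appear in a modified-amino-acid translation table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio.PDB import PDBParser, PDBIO
from Bio.PDB.Atom import Atom as _BioAtom
from Bio.PDB.Chain import Chain as _BioChain
from Bio.PDB.Model import Model as _BioModel
from Bio.PDB.Residue import Residue as _BioResidue
from Bio.PDB.Structure import Structure as _BioStructure

from .errors import StructureParseError, EmptySelectionError

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ProteinStructure",
    "read_pdb",
    "write_pdb",
    "extract_sequence",
    "THREE_TO_ONE",
    "DEFAULT_HETATM_MAP",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Modified amino acids kept during parsing (HETATM records), mapped to the
# one-letter code of their parent residue.  Extendable by the caller.
DEFAULT_HETATM_MAP = {
    "MSE": "M",  # selenomethionine
    "CSO": "C",  # S-hydroxycysteine
    "SEP": "S",  # phosphoserine
    "TPO": "T",  # phosphothreonine
    "PTR": "Y",  # phosphotyrosine
    "HYP": "P",  # hydroxyproline
}


@dataclass
class AtomRecord:
    """A single atom: PDB atom label, element symbol, coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray
    is_hydrogen: bool = field(default=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        self.element = self.element.strip().upper()
        self.is_hydrogen = self.element in ("H", "D")


@dataclass
class ResidueRecord:
    """One amino-acid residue with its atoms.

    ``seq_index`` is the 0-based position in the concatenated chain order of
    the parent :class:`ProteinStructure`.
    """

    aa_code: str
    chain_id: str
    seq_index: int
    atoms: list[AtomRecord]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError(f"residue {self.seq_index} ({self.aa_code}): no atoms")

    def get_atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class ProteinStructure:
    """Ordered residues of one protein (chains concatenated in file order)."""

    residues: list[ResidueRecord]
    source_id: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"structure {self.source_id!r} has no residues")
        for i, r in enumerate(self.residues):
            if r.seq_index != i:
                raise ValueError(
                    f"structure {self.source_id!r}: residue {i} has seq_index {r.seq_index}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen


def _element_of(bio_atom) -> str:
    el = (bio_atom.element or "").strip()
    if not el:
        # infer from the atom name, PDB convention: first alphabetic character
        for ch in bio_atom.get_name():
            if ch.isalpha():
                el = ch
                break
    return el.upper()


def read_pdb(
    path,
    chain_filter: Optional[Iterable[str]] = None,
    hetatm_map: Optional[dict] = None,
) -> ProteinStructure:
    """Parse a PDB file into a :class:`ProteinStructure`.

    Parameters
    ----------
    path:
        PDB file to read.
    chain_filter:
        If given, only residues whose chain label is in this set are kept.
    hetatm_map:
        Three-letter → one-letter table of modified amino acids to retain
        from HETATM records (default :data:`DEFAULT_HETATM_MAP`).

    Raises
    ------
    StructureParseError
        If the file is unreadable or contains no amino-acid residues.
    EmptySelectionError
        If ``chain_filter`` matches no residue.
    """
    path = Path(path)
    if hetatm_map is None:
        hetatm_map = DEFAULT_HETATM_MAP
    if not path.is_file():
        raise StructureParseError(f"cannot read PDB file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        bio_structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # malformed beyond Biopython's tolerance
        raise StructureParseError(f"failed to parse PDB file {path}: {exc}") from exc

    models = list(bio_structure.get_models())
    if not models:
        raise StructureParseError(f"no ATOM records in PDB file: {path}")
    model = models[0]  # first MODEL only

    wanted = set(chain_filter) if chain_filter is not None else None
    residues: list[ResidueRecord] = []
    any_residue = False
    for chain in model:
        for res in chain:
            hetflag = res.id[0]
            resname = res.get_resname().strip()
            if hetflag == " ":
                aa = THREE_TO_ONE.get(resname, "X")
            elif hetflag.startswith("H_") and resname in hetatm_map:
                aa = hetatm_map[resname]
            else:
                continue  # waters and unmapped heteroatoms
            any_residue = True
            if wanted is not None and chain.id not in wanted:
                continue
            atoms = []
            # iterating a residue yields the selected (highest-occupancy)
            # altloc conformer for disordered atoms; Biopython keeps the
            # first-encountered conformer on occupancy ties
            for bio_atom in res:
                atoms.append(
                    AtomRecord(
                        name=bio_atom.get_name(),
                        element=_element_of(bio_atom),
                        coords=np.array(bio_atom.coord, dtype=float),
                    )
                )
            if not atoms:
                continue
            residues.append(
                ResidueRecord(aa_code=aa, chain_id=chain.id, seq_index=len(residues), atoms=atoms)
            )

    if not any_residue:
        raise StructureParseError(f"no amino-acid ATOM records in PDB file: {path}")
    if not residues:
        raise EmptySelectionError(
            f"chain filter {sorted(wanted)} matches no chain in {path}"
        )
    return ProteinStructure(residues=residues, source_id=path.stem)


def extract_sequence(structure: ProteinStructure) -> str:
    """One-letter amino-acid sequence in residue order ('X' for unknowns)."""
    return "".join(r.aa_code if r.aa_code in ONE_TO_THREE else "X" for r in structure.residues)


def write_pdb(structure: ProteinStructure, path) -> None:
    """Write a structure as a PDB file that round-trips through read_pdb.

    Residues are renumbered 1.. within each chain; coordinates are written to
    the PDB fixed-width precision (3 decimals).
    """
    if not structure.residues:
        raise ValueError("cannot write an empty structure")
    bio_structure = _BioStructure(structure.source_id or "pairsite")
    model = _BioModel(0)
    bio_structure.add(model)
    chains: dict[str, _BioChain] = {}
    per_chain_count: dict[str, int] = {}
    serial = 1
    for res in structure.residues:
        if res.chain_id not in chains:
            chains[res.chain_id] = _BioChain(res.chain_id)
            model.add(chains[res.chain_id])
            per_chain_count[res.chain_id] = 0
        per_chain_count[res.chain_id] += 1
        resname = ONE_TO_THREE.get(res.aa_code, "UNK")
        bio_res = _BioResidue((" ", per_chain_count[res.chain_id], " "), resname, " ")
        chains[res.chain_id].add(bio_res)
        for atom in res.atoms:
            name = atom.name
            # PDB column convention: element right-justified in cols 13-14
            fullname = name.rjust(4) if len(name) >= 4 else (" " + name).ljust(4)
            bio_atom = _BioAtom(
                name=name,
                coord=np.asarray(atom.coords, dtype=np.float32),
                bfactor=0.0,
                occupancy=1.0,
                altloc=" ",
                fullname=fullname,
                serial_number=serial,
                element=atom.element,
            )
            serial += 1
            bio_res.add(bio_atom)
    io = PDBIO()
    io.set_structure(bio_structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        io.save(str(path))
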