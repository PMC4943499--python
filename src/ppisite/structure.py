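"""Protein structure model and PDB reading.

The internal model is deliberately small: heavy atoms grouped into residues,
residues grouped into chains, chains into a complex.  Coordinates are numpy
arrays in Angstroms.  Only the information needed downstream (coordinates,
element, backbone/polar flags, van der Waals radii) is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "ResidueRecord",
    "ChainStructure",
    "ComplexStructure",
    "PdbParseError",
    "read_pdb",
    "get_ca_coords",
    "VDW_RADII",
    "THREE_TO_ONE",
]

# Element-keyed van der Waals radii (Angstrom).  Unknown heavy elements fall
# back to carbon.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
_DEFAULT_RADIUS = 1.70

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class PdbParseError(ValueError):
    """Raised for malformed ATOM records or empty structures."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    vdw_radius: float

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdw_radius must be positive")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    @property
    def is_polar(self) -> bool:
        # N/O polar; C and S treated non-polar.
        return self.element in ("N", "O")


@dataclass
class ResidueRecord:
    chain_id: str
    seq_index: int
    author_number: int
    aa: str
    atoms: list[Atom]
    ca_from_centroid: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("residue must contain at least one atom")
        if self.aa not in STANDARD_AA and self.aa != "X":
            raise ValueError(f"unknown amino acid code {self.aa!r}")

    @property
    def ca_coord(self) -> np.ndarray | None:
        """Calpha coordinate; heavy-atom centroid fallback if CA is missing."""
        for atom in self.atoms:
            if atom.name == "CA":
                return atom.coord
        if self.ca_from_centroid:
            return np.mean([a.coord for a in self.atoms], axis=0)
        return None

    @property
    def has_ca(self) -> bool:
        return any(a.name == "CA" for a in self.atoms)


@dataclass
class ChainStructure:
    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]


@dataclass
class ComplexStructure:
    pdb_id: str
    chains: list[ChainStructure] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain ids in complex")

    def chain(self, chain_id: str) -> ChainStructure:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def atoms(self) -> list[Atom]:
        return [a for c in self.chains for a in c.atoms()]


def _parse_atom_line(line: str, lineno: int) -> dict:
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or "_"
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().upper()
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    if not element:
        # Derive from the atom-name column when the element field is blank.
        element = name.lstrip("0123456789")[:1].upper()
    return {
        "name": name,
        "altloc": altloc,
        "resname": resname,
        "chain_id": chain_id,
        "resseq": resseq,
        "icode": icode,
        "coord": np.array([x, y, z]),
        "occupancy": occupancy,
        "element": element,
    }


def read_pdb(path, pdb_id: str | None = None) -> ComplexStructure:
    """Read a PDB file into a :class:`ComplexStructure`.

    Heavy atoms of standard ``ATOM`` records only: hydrogens, waters and
    HETATM ligands are dropped, alternate locations are resolved to the
    highest-occupancy (ties: first seen) conformer, and only the first model
    of a multi-model file is read.  Non-standard residue names map to 'X'.
    """
    path = str(path)
    # Keyed by (chain, resseq, icode) in file order; each value maps an atom
    # name to its best altloc candidate.
    residue_order: list[tuple[str, int, str]] = []
    residue_atoms: dict[tuple[str, int, str], dict] = {}

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6]
            if record == "ENDMDL":
                break  # first model only
            if record != "ATOM  ":
                continue
            fields = _parse_atom_line(line.rstrip("\n"), lineno)
            if fields["element"] in ("H", "D"):
                continue
            key = (fields["chain_id"], fields["resseq"], fields["icode"])
            if key not in residue_atoms:
                residue_order.append(key)
                residue_atoms[key] = {"resname": fields["resname"], "atoms": {}}
            existing = residue_atoms[key]["atoms"].get(fields["name"])
            if existing is None or fields["occupancy"] > existing["occupancy"]:
                residue_atoms[key]["atoms"][fields["name"]] = fields

    if not residue_atoms:
        raise PdbParseError(f"{path}: no ATOM records found")

    chains: dict[str, ChainStructure] = {}
    for key in residue_order:
        chain_id, resseq, _icode = key
        info = residue_atoms[key]
        chain = chains.setdefault(chain_id, ChainStructure(chain_id))
        atoms = [
            Atom(
                name=f["name"],
                element=f["element"],
                coord=f["coord"],
                vdw_radius=VDW_RADII.get(f["element"], _DEFAULT_RADIUS),
            )
            for f in info["atoms"].values()
        ]
        residue = ResidueRecord(
            chain_id=chain_id,
            seq_index=chain.length,
            author_number=resseq,
            aa=THREE_TO_ONE.get(info["resname"], "X"),
            atoms=atoms,
            ca_from_centroid=not any(a.name == "CA" for a in atoms),
        )
        chain.residues.append(residue)

    if pdb_id is None:
        import os

        pdb_id = os.path.splitext(os.path.basename(path))[0]
    return ComplexStructure(pdb_id=pdb_id, chains=list(chains.values()))


def get_ca_coords(chain: ChainStructure) -> list[np.ndarray | None]:
    """Per-residue Calpha coordinates in sequence order.

    Residues without a CA atom contribute their heavy-atom centroid (the
    residue is flagged via ``ca_from_centroid``); ``None`` only if the
    residue was built without the fallback.
    """
    if chain.length == 0:
        raise ValueError("chain is empty")
    return [r.ca_coord for r in chain.residues]
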