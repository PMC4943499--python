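"""Solvent-accessible surface area.

Areas are computed with the Shrake-Rupley rolling-probe quadrature over a
deterministic Fibonacci-spiral point set, per atom, then summed into
per-residue components: total, backbone/side-chain and polar/non-polar.
Each component pair partitions the same atom set, so the pairs sum exactly
to the total.

Two contexts are distinguished for multi-chain structures: *unbound*
(each chain computed with all partner chains removed) and *bound*
(all chains present).  Relative areas divide by per-amino-acid reference
maxima.  A DSSP file reader is provided as an optional bypass for total
areas.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    Atom,
    ChainStructure,
    ComplexStructure,
    STANDARD_AA,
    VDW_RADII,
)

__all__ = [
    "SasaTable",
    "shrake_rupley",
    "residue_asa",
    "relative_asa",
    "read_dssp_asa",
    "align_dssp",
    "MAX_ASA_TOTAL",
]

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

# Theoretical per-residue maximum total ASA (Angstrom^2), Tien et al. 2013.
MAX_ASA_TOTAL = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

ASA_COMPONENTS = ("total", "backbone", "sidechain", "polar", "nonpolar")


@lru_cache(maxsize=8)
def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci spiral)."""
    if n < 1:
        raise ValueError("n_points must be >= 1")
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley(
    atoms: list[Atom],
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom accessible surface area in Angstrom^2.

    Each atom's area is (accessible test points / n_points) x 4*pi*(r+probe)^2
    where test points are occluded by any neighbouring expanded sphere.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    unit = _sphere_points(n_points)
    coords = np.array([a.coord for a in atoms], dtype=float)
    radii = np.array([a.vdw_radius for a in atoms], dtype=float) + probe_radius
    n = len(atoms)
    areas = np.empty(n)
    if n == 0:
        return areas
    tree = cKDTree(coords)
    max_r = radii.max()
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        # Any atom whose expanded sphere can reach a test point lies within
        # radii[i] + max_r of the centre.
        neighbours = tree.query_ball_point(coords[i], radii[i] + max_r)
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        areas[i] = accessible.sum() / n_points * 4.0 * np.pi * radii[i] ** 2
    return areas


@dataclass
class SasaTable:
    """Per-residue ASA components, optionally with relative areas filled in."""

    chain_ids: list[str]
    seq_indices: list[int]
    author_numbers: list[int]
    aas: list[str]
    context: str  # "bound" | "unbound"
    total_asa: np.ndarray = field(default=None)
    backbone_asa: np.ndarray = field(default=None)
    sidechain_asa: np.ndarray = field(default=None)
    polar_asa: np.ndarray = field(default=None)
    nonpolar_asa: np.ndarray = field(default=None)
    total_rasa: np.ndarray | None = None
    backbone_rasa: np.ndarray | None = None
    sidechain_rasa: np.ndarray | None = None
    polar_rasa: np.ndarray | None = None
    nonpolar_rasa: np.ndarray | None = None
    rasa_flagged: np.ndarray | None = None  # True where 'X' fallback used

    def __len__(self) -> int:
        return len(self.chain_ids)

    def keys(self) -> list[tuple[str, int]]:
        return list(zip(self.chain_ids, self.seq_indices))

    def write_csv(self, path) -> None:
        cols = [
            "chain_id", "author_number", "aa", "context",
            "total_asa", "backbone_asa", "sidechain_asa", "polar_asa",
            "nonpolar_asa", "total_rasa", "backbone_rasa", "sidechain_rasa",
            "polar_rasa", "nonpolar_rasa",
        ]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(cols)
            for i in range(len(self)):
                row = [
                    self.chain_ids[i], self.author_numbers[i], self.aas[i],
                    self.context,
                    self.total_asa[i], self.backbone_asa[i],
                    self.sidechain_asa[i], self.polar_asa[i],
                    self.nonpolar_asa[i],
                ]
                for comp in ("total", "backbone", "sidechain", "polar", "nonpolar"):
                    rasa = getattr(self, f"{comp}_rasa")
                    row.append("" if rasa is None else rasa[i])
                writer.writerow(row)


def _accumulate(structure_chains: list[ChainStructure], probe: float, n_points: int):
    """Flatten chains to atoms, run the quadrature, sum per residue."""
    atoms: list[Atom] = []
    owner: list[tuple[int, Atom]] = []  # residue running index per atom
    meta = {k: [] for k in ("chain_ids", "seq_indices", "author_numbers", "aas")}
    r_idx = -1
    for chain in structure_chains:
        for res in chain.residues:
            r_idx += 1
            meta["chain_ids"].append(res.chain_id)
            meta["seq_indices"].append(res.seq_index)
            meta["author_numbers"].append(res.author_number)
            meta["aas"].append(res.aa)
            for atom in res.atoms:
                atoms.append(atom)
                owner.append((r_idx, atom))
    per_atom = shrake_rupley(atoms, probe, n_points)
    n_res = r_idx + 1
    comp = {c: np.zeros(n_res) for c in ASA_COMPONENTS}
    for area, (ri, atom) in zip(per_atom, owner):
        comp["total"][ri] += area
        comp["backbone" if atom.is_backbone else "sidechain"][ri] += area
        comp["polar" if atom.is_polar else "nonpolar"][ri] += area
    return meta, comp


def residue_asa(
    structure: ComplexStructure,
    context: str = "bound",
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaTable:
    """Per-residue ASA components for every residue of the complex.

    ``context="unbound"`` computes each chain in isolation (partner chains
    removed); ``context="bound"`` computes with all chains present.  Row
    order is chain order then sequence order, identical in both contexts.
    """
    if context not in ("bound", "unbound"):
        raise ValueError(f"context must be 'bound' or 'unbound', got {context!r}")
    if context == "bound":
        groups = [structure.chains]
    else:
        groups = [[chain] for chain in structure.chains]

    metas, comps = [], []
    for group in groups:
        meta, comp = _accumulate(group, probe_radius, n_points)
        metas.append(meta)
        comps.append(comp)
    meta = {k: sum((m[k] for m in metas), []) for k in metas[0]}
    comp = {c: np.concatenate([cm[c] for cm in comps]) for c in ASA_COMPONENTS}
    return SasaTable(
        chain_ids=meta["chain_ids"],
        seq_indices=meta["seq_indices"],
        author_numbers=meta["author_numbers"],
        aas=meta["aas"],
        context=context,
        total_asa=comp["total"],
        backbone_asa=comp["backbone"],
        sidechain_asa=comp["sidechain"],
        polar_asa=comp["polar"],
        nonpolar_asa=comp["nonpolar"],
    )


# ---------------------------------------------------------------------------
# Reference maxima for relative areas.
#
# Total references come from the Tien et al. theoretical set above.  The
# four component references are derived once per amino acid from an extended
# Gly-X-Gly-like pseudo-tripeptide (backbone N/CA/C/O plus one side-chain
# bead, none for Gly) evaluated with the same quadrature; values are cached.
# ---------------------------------------------------------------------------

_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.80, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.20, 0.80, 0.0]),
    "O": np.array([1.60, 1.95, 0.0]),
}
_CB_OFFSET = np.array([0.0, -1.53, 0.0])
_CA_SPACING = 3.8


def _pseudo_residue_atoms(origin: np.ndarray, aa: str, flip: float = 1.0) -> list[Atom]:
    atoms = []
    for name, off in _BACKBONE_OFFSETS.items():
        element = name[0]
        atoms.append(
            Atom(name=name, element=element, coord=origin + off * np.array([1, flip, 1]),
                 vdw_radius=VDW_RADII[element])
        )
    if aa != "G":
        atoms.append(
            Atom(name="CB", element="C",
                 coord=origin + _CB_OFFSET * np.array([1, flip, 1]),
                 vdw_radius=VDW_RADII["C"])
        )
    return atoms


@lru_cache(maxsize=32)
def _component_reference(aa: str) -> dict[str, float]:
    """Max component areas of residue `aa` in an extended G-X-G construction."""
    chain = []
    for k, res_aa in enumerate(["G", aa, "G"]):
        origin = np.array([k * _CA_SPACING, 0.0, 0.0])
        chain.append(_pseudo_residue_atoms(origin, res_aa, flip=1.0 if k % 2 == 0 else -1.0))
    flat = [a for res in chain for a in res]
    areas = shrake_rupley(flat)
    center = chain[1]
    start = len(chain[0])
    ref = {c: 0.0 for c in ASA_COMPONENTS}
    for atom, area in zip(center, areas[start:start + len(center)]):
        ref["total"] += area
        ref["backbone" if atom.is_backbone else "sidechain"] += area
        ref["polar" if atom.is_polar else "nonpolar"] += area
    # Floor at 1 A^2 so Gly side-chain (and any tiny component) never divides
    # by ~0; relative values stay finite and ordering is preserved.
    return {c: max(v, 1.0) for c, v in ref.items()}


def _reference_for(aa: str, component: str) -> float:
    if component == "total":
        if aa == "X":
            return float(np.mean(list(MAX_ASA_TOTAL.values())))
        return MAX_ASA_TOTAL[aa]
    key = aa if aa in STANDARD_AA else "A"
    return _component_reference(key)[component]


def relative_asa(table: SasaTable) -> SasaTable:
    """Fill the five relative-area columns of ``table`` in place (and return it).

    Each relative component is the absolute component divided by the
    amino-acid-specific reference maximum.  Unknown residues ('X') use the
    mean total reference and are flagged.
    """
    n = len(table)
    flagged = np.zeros(n, dtype=bool)
    for comp in ASA_COMPONENTS:
        absolute = getattr(table, f"{comp}_asa")
        rel = np.empty(n)
        for i, aa in enumerate(table.aas):
            rel[i] = absolute[i] / _reference_for(aa, comp)
            if aa == "X":
                flagged[i] = True
        setattr(table, f"{comp}_rasa", rel)
    table.rasa_flagged = flagged
    return table


# ---------------------------------------------------------------------------
# DSSP bypass
# ---------------------------------------------------------------------------

@dataclass
class DsspRow:
    chain_id: str
    author_number: int
    aa: str
    acc: float


def read_dssp_asa(path) -> list[DsspRow]:
    """Read per-residue total ASA (ACC column) from a DSSP v2/v3 text file.

    Chain-break marker lines ('!') are skipped without shifting alignment.
    """
    rows: list[DsspRow] = []
    in_body = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not in_body:
                if line.lstrip().startswith("#  RESIDUE"):
                    in_body = True
                continue
            if len(line) < 38:
                continue
            aa = line[13]
            if aa == "!":
                continue
            chain_id = line[11].strip() or "_"
            try:
                author_number = int(line[5:10])
                acc = float(line[34:38])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric residue number or ACC at line {lineno}"
                ) from exc
            rows.append(DsspRow(chain_id, author_number, aa, acc))
    if not in_body:
        raise ValueError(f"{path}: no DSSP residue table header found")
    return rows


def align_dssp(rows: list[DsspRow], chain: ChainStructure) -> np.ndarray:
    """Total ASA aligned to the residues of ``chain``.

    Raises if any chain residue has no matching (chain, author number) row.
    """
    lookup = {(r.chain_id, r.author_number): r.acc for r in rows}
    out = np.empty(chain.length)
    missing = []
    for i, res in enumerate(chain.residues):
        key = (res.chain_id, res.author_number)
        if key not in lookup:
            missing.append(key)
        else:
            out[i] = lookup[key]
    if missing:
        raise ValueError(f"DSSP alignment failed; unmatched residues: {missing}")
    return out
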