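"""Residue depth (DPX) and protrusion (CX) indices.

Depth of an atom is its Euclidean distance to the nearest solvent-accessible
atom (atoms with nonzero SASA have depth zero).  Protrusion of an atom is the
ratio of unoccupied to occupied volume within a 10 A sphere, with occupied
volume approximated as (number of heavy atoms inside) x mean atom volume.
Residue values are means over the residue's heavy atoms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import ComplexStructure

__all__ = ["GeometryTable", "depth_index", "protrusion_index"]

SPHERE_RADIUS = 10.0
MEAN_ATOM_VOLUME = 20.1


@dataclass
class GeometryTable:
    chain_ids: list[str]
    seq_indices: list[int]
    values: np.ndarray  # one value per residue

    def write_csv(self, path, name: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["chain_id", "seq_index", name])
            for c, s, v in zip(self.chain_ids, self.seq_indices, self.values):
                writer.writerow([c, s, v])


def _residue_atom_layout(structure: ComplexStructure):
    coords, owners, meta = [], [], {"chain_ids": [], "seq_indices": []}
    r_idx = -1
    for chain in structure.chains:
        for res in chain.residues:
            r_idx += 1
            meta["chain_ids"].append(res.chain_id)
            meta["seq_indices"].append(res.seq_index)
            for atom in res.atoms:
                coords.append(atom.coord)
                owners.append(r_idx)
    return np.asarray(coords), np.asarray(owners), meta, r_idx + 1


def depth_index(structure: ComplexStructure, per_atom_sasa: np.ndarray) -> GeometryTable:
    """Average depth per residue.

    ``per_atom_sasa`` must follow the same atom order as
    ``structure.atoms()``.  An atom with positive SASA has depth zero; other
    atoms take the distance to the nearest accessible atom.
    """
    coords, owners, meta, n_res = _residue_atom_layout(structure)
    per_atom_sasa = np.asarray(per_atom_sasa, dtype=float)
    if per_atom_sasa.shape[0] != coords.shape[0]:
        raise ValueError("per_atom_sasa length does not match atom count")
    accessible = per_atom_sasa > 0
    if not accessible.any():
        raise ValueError("no solvent-accessible atom in structure; depth undefined")
    depth = np.zeros(len(coords))
    buried = ~accessible
    if buried.any():
        tree = cKDTree(coords[accessible])
        depth[buried], _ = tree.query(coords[buried])
    values = np.zeros(n_res)
    counts = np.bincount(owners, minlength=n_res)
    np.add.at(values, owners, depth)
    values /= counts
    return GeometryTable(meta["chain_ids"], meta["seq_indices"], values)


def protrusion_index(
    structure: ComplexStructure,
    sphere_radius: float = SPHERE_RADIUS,
    mean_atom_volume: float = MEAN_ATOM_VOLUME,
) -> GeometryTable:
    """Average protrusion per residue.

    Per atom: V_int = (heavy atoms within sphere_radius, self included) x
    mean_atom_volume; V_ext = sphere volume - V_int (clamped at 0);
    cx = V_ext / V_int.
    """
    coords, owners, meta, n_res = _residue_atom_layout(structure)
    sphere_volume = 4.0 / 3.0 * np.pi * sphere_radius**3
    tree = cKDTree(coords)
    counts_in = np.array([len(idx) for idx in tree.query_ball_point(coords, sphere_radius)])
    v_int = np.maximum(counts_in, 1) * mean_atom_volume
    v_ext = np.maximum(sphere_volume - v_int, 0.0)
    cx_atom = v_ext / v_int
    values = np.zeros(n_res)
    counts = np.bincount(owners, minlength=n_res)
    np.add.at(values, owners, cx_atom)
    values /= counts
    return GeometryTable(meta["chain_ids"], meta["seq_indices"], values)
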