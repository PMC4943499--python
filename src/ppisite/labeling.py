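"""Surface/interface residue labeling and chain-level curation.

A residue is a surface residue when at least 16 % of its maximal accessible
area is exposed in the unbound chain.  A surface residue is an interface
residue when removing the partner chains changes its total accessible area
by at least 1 A^2 (|MASA - CASA| >= 1).  Chains shorter than 100 residues,
or with fewer interface residues than the per-complex-type minimum
(20 hetero / 30 homo), are rejected by curation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .sasa import SasaTable
from .structure import ChainStructure

__all__ = [
    "ResidueLabels",
    "CurationReport",
    "label_surface",
    "label_interface",
    "curate_chain",
    "SURFACE_RASA_THRESHOLD",
    "INTERFACE_DELTA_ASA",
    "MIN_CHAIN_LENGTH",
    "MIN_INTERFACE_COUNT",
]

SURFACE_RASA_THRESHOLD = 0.16
INTERFACE_DELTA_ASA = 1.0
MIN_CHAIN_LENGTH = 100
MIN_INTERFACE_COUNT = {"hetero": 20, "homo": 30}


@dataclass
class ResidueLabels:
    chain_ids: list[str]
    seq_indices: list[int]
    is_surface: np.ndarray
    is_interface: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.is_interface & ~self.is_surface):
            raise ValueError("interface residue must be a surface residue")

    def __len__(self) -> int:
        return len(self.chain_ids)

    def write_csv(self, path, aas: list[str] | None = None) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["chain_id", "seq_index", "aa", "is_surface", "is_interface"])
            for i in range(len(self)):
                writer.writerow([
                    self.chain_ids[i], self.seq_indices[i],
                    aas[i] if aas else "",
                    int(self.is_surface[i]), int(self.is_interface[i]),
                ])


def label_surface(
    rasa_unbound: SasaTable, threshold: float = SURFACE_RASA_THRESHOLD
) -> np.ndarray:
    """Boolean surface flags: total relative area >= threshold (inclusive)."""
    if rasa_unbound.total_rasa is None:
        raise ValueError("relative areas not computed; call relative_asa first")
    if rasa_unbound.context != "unbound":
        raise ValueError("surface definition uses the unbound-context table")
    return rasa_unbound.total_rasa >= threshold


def label_interface(
    masa: SasaTable,
    casa: SasaTable,
    surface: np.ndarray,
    delta: float = INTERFACE_DELTA_ASA,
) -> ResidueLabels:
    """Interface flags: surface residue with |MASA - CASA| >= delta (total ASA)."""
    if masa.keys() != casa.keys():
        raise ValueError("MASA and CASA tables are not residue-aligned")
    surface = np.asarray(surface, dtype=bool)
    if surface.shape[0] != len(masa):
        raise ValueError("surface flags not aligned with ASA tables")
    contact = np.abs(masa.total_asa - casa.total_asa) >= delta
    return ResidueLabels(
        chain_ids=list(masa.chain_ids),
        seq_indices=list(masa.seq_indices),
        is_surface=surface,
        is_interface=surface & contact,
    )


@dataclass
class CurationReport:
    chain_id: str
    length: int
    length_ok: bool
    interface_count: int
    interface_count_ok: bool

    @property
    def passed(self) -> bool:
        return self.length_ok and self.interface_count_ok


def curate_chain(
    chain: ChainStructure,
    labels: ResidueLabels,
    complex_type: str,
) -> CurationReport:
    """Apply the chain-length and interface-count filters to one chain."""
    if complex_type not in MIN_INTERFACE_COUNT:
        raise ValueError(f"complex_type must be 'hetero' or 'homo', got {complex_type!r}")
    mask = [c == chain.chain_id for c in labels.chain_ids]
    if not any(mask):
        raise ValueError(f"labels contain no rows for chain {chain.chain_id!r}")
    interface_count = int(labels.is_interface[np.asarray(mask)].sum())
    return CurationReport(
        chain_id=chain.chain_id,
        length=chain.length,
        length_ok=chain.length >= MIN_CHAIN_LENGTH,
        interface_count=interface_count,
        interface_count_ok=interface_count >= MIN_INTERFACE_COUNT[complex_type],
    )
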