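"""Synthetic desk-scale fixtures: toy complexes, profiles, labeled data.

The toy complex is two chains of pseudo-residues (backbone N/CA/C/O plus a
single side-chain bead) laid along smooth curves with idealized 3.8 A
Calpha spacing.  A designated contact patch on each chain is placed within
occlusion distance of the partner; all other residues bend away.  Ground
truth contact flags are returned with the structure, so the
surface/interface labeling rules can be validated end to end.

Synthetic profiles give interface residues lower entropy (sharper
substitution profiles), with a tunable effect size; the labeled-dataset
generator bypasses structure entirely and emits Gaussian feature matrices
with a controllable number of informative columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import AA_ORDER, ProfileRow, profile_entropy
from .structure import (
    Atom,
    ChainStructure,
    ComplexStructure,
    ONE_TO_THREE,
    ResidueRecord,
    VDW_RADII,
)

__all__ = [
    "ToyComplexSpec",
    "SignalSpec",
    "make_toy_complex",
    "make_synthetic_profiles",
    "make_labeled_dataset",
    "write_pdb",
]

CA_SPACING = 3.8
_RAMP_DZ = 3.0  # per-residue climb away from the interface outside the patch

_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.80, 0.0]),
    "C": np.array([1.20, 0.80, 0.0]),
    "O": np.array([1.60, 1.95, 0.0]),
}
_SIDE_BEAD_LENGTH = 1.5


@dataclass
class ToyComplexSpec:
    n_res_per_chain: int = 30
    contact_patch_size: int = 10
    inter_chain_gap: float = 4.0
    geometry: str = "extended"  # extended | helix
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_patch_size > self.n_res_per_chain:
            raise ValueError("contact patch larger than chain")
        if self.inter_chain_gap <= 0:
            raise ValueError("inter-chain gap must be positive")
        if self.geometry not in ("extended", "helix"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


@dataclass
class SignalSpec:
    n_informative: int = 10
    effect_size: float = 2.0
    class_balance: float = 0.5
    n_features: int = 550
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative outside [0, n_features]")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")


def _patch_bounds(n: int, patch: int) -> tuple[int, int]:
    start = (n - patch) // 2
    return start, start + patch


def _extended_ca_trace(n: int, patch_lo: int, patch_hi: int, base_z: float) -> np.ndarray:
    """Calpha positions with exact 3.8 A spacing, climbing away off-patch."""
    dz_steps = np.zeros(n - 1) if n > 1 else np.zeros(0)
    for i in range(n - 1):
        # Step i connects residues i and i+1; climb when either endpoint is
        # outside the patch.
        if i + 1 <= patch_lo - 1 and patch_lo > 0:
            dz_steps[i] = -_RAMP_DZ  # descending toward the patch
        elif i >= patch_hi - 1 and patch_hi < n:
            dz_steps[i] = _RAMP_DZ  # ascending after the patch
    dx_steps = np.sqrt(CA_SPACING**2 - dz_steps**2)
    xs = np.concatenate([[0.0], np.cumsum(dx_steps)])
    zs = np.concatenate([[0.0], np.cumsum(dz_steps)])
    zs -= zs[patch_lo] if patch_lo < n else 0.0  # patch sits at z = 0
    zs = np.abs(zs)  # both flanks climb away on the same side
    coords = np.column_stack([xs, np.zeros(n), zs + base_z])
    return coords


def _helix_ca_trace(n: int, patch_lo: int, patch_hi: int, base_z: float) -> np.ndarray:
    """Helical Calpha trace (axis along x), same off-patch climb in z."""
    radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    i = np.arange(n)
    coords = np.column_stack([
        i * rise,
        radius * np.cos(i * twist),
        radius * np.sin(i * twist),
    ])
    climb = np.zeros(n)
    for k in range(n):
        if k < patch_lo:
            climb[k] = _RAMP_DZ * (patch_lo - k)
        elif k >= patch_hi:
            climb[k] = _RAMP_DZ * (k - patch_hi + 1)
    coords[:, 2] += base_z + climb
    return coords


def _build_chain(
    chain_id: str,
    ca: np.ndarray,
    sequence: str,
    side_dir: float,
) -> ChainStructure:
    """Pseudo-residues around given Calpha positions; side bead along +-z."""
    chain = ChainStructure(chain_id)
    for i, (pos, aa) in enumerate(zip(ca, sequence)):
        atoms = [Atom("CA", "C", pos, VDW_RADII["C"])]
        for name, off in _BACKBONE_OFFSETS.items():
            atoms.append(Atom(name, name[0], pos + off, VDW_RADII[name[0]]))
        if aa != "G":
            bead = pos + np.array([0.0, 0.0, side_dir * _SIDE_BEAD_LENGTH])
            atoms.append(Atom("CB", "C", bead, VDW_RADII["C"]))
        chain.residues.append(ResidueRecord(
            chain_id=chain_id, seq_index=i, author_number=i + 1, aa=aa,
            atoms=atoms,
        ))
    return chain


def make_toy_complex(spec: ToyComplexSpec) -> tuple[ComplexStructure, dict[str, np.ndarray]]:
    """Two-chain toy complex plus ground-truth contact-patch flags per chain."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_res_per_chain
    lo, hi = _patch_bounds(n, spec.contact_patch_size)
    trace = _extended_ca_trace if spec.geometry == "extended" else _helix_ca_trace

    seq_a = "".join(rng.choice(list(AA_ORDER), size=n))
    seq_b = "".join(rng.choice(list(AA_ORDER), size=n))

    ca_a = trace(n, lo, hi, base_z=0.0)
    ca_a[:, 2] *= -1.0  # chain A bends away below the interface plane
    ca_b = trace(n, lo, hi, base_z=spec.inter_chain_gap)
    if spec.contact_patch_size > 0:
        # Align the patches in x so they face each other.
        ca_b[:, 0] += ca_a[lo, 0] - ca_b[lo, 0]

    chain_a = _build_chain("A", ca_a, seq_a, side_dir=+1.0)
    chain_b = _build_chain("B", ca_b, seq_b, side_dir=-1.0)
    complex_structure = ComplexStructure(pdb_id="TOY", chains=[chain_a, chain_b])

    flags = np.zeros(n, dtype=bool)
    flags[lo:hi] = True
    return complex_structure, {"A": flags.copy(), "B": flags.copy()}


def make_synthetic_profiles(
    L: int, labels: np.ndarray, signal: SignalSpec
) -> list[ProfileRow]:
    """Profile rows where flagged residues are more conserved (lower entropy).

    Rows are softmax draws over 20 logits; the logit scale grows with
    ``effect_size`` for flagged residues, sharpening their profiles.  With
    effect 0 both classes are drawn from the same distribution.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.shape[0] != L:
        raise ValueError("labels length must equal L")
    rng = np.random.default_rng(signal.seed)
    rows: list[ProfileRow] = []
    for i in range(L):
        scale = 1.0 + (0.75 * signal.effect_size if labels[i] else 0.0)
        logits = rng.normal(size=20) * scale
        p = np.exp(logits - logits.max())
        p /= p.sum()
        entropy, relent = profile_entropy(p)
        rows.append(ProfileRow(
            p=p,
            entropy=entropy,
            relative_entropy=relent,
            conservation_weight=float(np.clip(100.0 - relent, 0, 100)),
            sequence_variability=float(np.clip(relent + rng.normal(0, 5), 0, 100)),
            nocc=int(rng.integers(10, 100)),
            aa=AA_ORDER[int(np.argmax(p))],
        ))
    return rows


def make_labeled_dataset(
    n: int, signal: SignalSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian feature matrix with shifted informative columns for positives.

    Returns (X, y, informative_columns); deterministic given the spec seed.
    """
    rng = np.random.default_rng(signal.seed)
    y = (rng.random(n) < signal.class_balance).astype(int)
    X = rng.normal(size=(n, signal.n_features))
    cols = rng.choice(signal.n_features, size=signal.n_informative, replace=False)
    X[np.ix_(y == 1, cols)] += signal.effect_size
    return X, y, np.sort(cols)


def write_pdb(structure: ComplexStructure, path) -> None:
    """Write standard fixed-column ATOM records (occupancy 1, B-factor 0)."""
    serial = 0
    with open(path, "w") as fh:
        for chain in structure.chains:
            for res in chain.residues:
                resname = ONE_TO_THREE.get(res.aa, "UNK")
                for atom in res.atoms:
                    serial += 1
                    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3}"
                    x, y, z = atom.coord
                    fh.write(
                        f"ATOM  {serial:5d} {name}{'':1}{resname:>3} "
                        f"{chain.chain_id:1}{res.author_number:4d}{'':1}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2}\n"
                    )
            fh.write("TER\n")
        fh.write("END\n")
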