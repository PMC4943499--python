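"""Sequence-profile and physicochemical residue features.

Per residue this module provides 25 profile values (20 substitution
probabilities plus entropy, relative entropy, conservation weight, sequence
variability and the aligned-sequence count), 13 physicochemical values
(8 cluster indices + 5 summary factors), and assembles them with the
12 structure values into the fixed-order 50-dimensional residue vector.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from ._aadata import AA_FACTORS, HQI8, HQI8_ACCESSIONS, AA_FACTOR_NAMES

__all__ = [
    "AA_ORDER",
    "FEATURE_NAMES",
    "ProfileRow",
    "parse_hssp",
    "parse_profile_tsv",
    "write_profile_tsv",
    "profile_entropy",
    "physchem_lookup",
    "assemble_residue_vector",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

PROFILE_SUM_TOL = 0.02  # profiles are stored in integer percent

# Fixed 50-feature order: 25 profile, 12 structure, 13 physicochemical.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"p_{aa}" for aa in AA_ORDER)
    + ("entropy", "relative_entropy", "conservation_weight",
       "sequence_variability", "nocc")
    + ("total_asa", "backbone_asa", "sidechain_asa", "polar_asa", "nonpolar_asa",
       "total_rasa", "backbone_rasa", "sidechain_rasa", "polar_rasa",
       "nonpolar_rasa", "dpx", "cx")
    + tuple(f"hqi8_{acc}" for acc in HQI8_ACCESSIONS)
    + tuple(f"factor_{name}" for name in AA_FACTOR_NAMES)
)
assert len(FEATURE_NAMES) == 50

N_FEATURES = len(FEATURE_NAMES)


class ProfileFormatError(ValueError):
    """Raised when a profile file violates the expected format."""


@dataclass
class ProfileRow:
    p: np.ndarray  # 20 probabilities in AA_ORDER
    entropy: float
    relative_entropy: float
    conservation_weight: float
    sequence_variability: float
    nocc: int
    aa: str = "X"
    flagged: bool = False  # defaulted/estimated fields present

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (20,):
            raise ValueError("profile row needs exactly 20 probabilities")
        if np.any(self.p < 0):
            raise ValueError("negative substitution probability")
        if abs(self.p.sum() - 1.0) > PROFILE_SUM_TOL and self.p.sum() > 0:
            raise ValueError(
                f"probabilities sum to {self.p.sum():.4f}, outside tolerance"
            )
        if not 0 <= self.relative_entropy <= 100:
            raise ValueError("relative_entropy outside [0, 100]")
        if not 0 <= self.sequence_variability <= 100:
            raise ValueError("sequence_variability outside [0, 100]")

    @property
    def vector25(self) -> np.ndarray:
        return np.concatenate([
            self.p,
            [self.entropy, self.relative_entropy, self.conservation_weight,
             self.sequence_variability, float(self.nocc)],
        ])


def profile_entropy(p: np.ndarray) -> tuple[float, float]:
    """Shannon entropy (natural log) of a 20-way profile and its 0-100 scaling.

    The relative value normalizes by ln(20), the maximum over 20 states.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or p.sum() > 1.0 + PROFILE_SUM_TOL:
        raise ValueError("invalid probability vector")
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return entropy, 100.0 * entropy / math.log(20.0)


# ---------------------------------------------------------------------------
# HSSP reading
# ---------------------------------------------------------------------------

def parse_hssp(path) -> list[ProfileRow]:
    """Parse the sequence-profile section of an HSSP file.

    Percent columns are divided by 100.  Column positions are taken from the
    section's own header line, so dialect variations in ordering are
    tolerated.  Sequence variability defaults to 0 (flagged) when the file
    has no VAR column in the profile section.
    """
    rows: list[ProfileRow] = []
    header_idx: dict[str, int] | None = None
    in_section = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                in_section = "SEQUENCE PROFILE" in line
                header_idx = None
                continue
            if not in_section:
                continue
            tokens = line.split()
            if not tokens:
                continue
            if header_idx is None:
                if tokens[0] != "SeqNo":
                    raise ProfileFormatError(
                        f"{path}: expected SeqNo header in profile section"
                    )
                header_idx = {name: i for i, name in enumerate(tokens)}
                missing = [aa for aa in AA_ORDER if aa not in header_idx]
                if missing:
                    raise ProfileFormatError(
                        f"{path}: profile header lacks columns {missing}"
                    )
                continue
            if tokens[1] == "!":  # chain break
                continue
            p = np.array([float(tokens[header_idx[aa]]) for aa in AA_ORDER]) / 100.0

            def _col(name: str, default: float | None) -> tuple[float, bool]:
                if name in header_idx and header_idx[name] < len(tokens):
                    return float(tokens[header_idx[name]]), False
                if default is None:
                    raise ProfileFormatError(f"{path}: missing column {name}")
                return default, True

            entropy, e_flag = _col("ENTROPY", None if "ENTROPY" in (header_idx or {}) else 0)
            if "ENTROPY" not in header_idx:
                entropy, _ = profile_entropy(p)
                e_flag = True
            relent, r_flag = _col("RELENT", profile_entropy(p)[1])
            weight, w_flag = _col("WEIGHT", 1.0)
            var, v_flag = _col("VAR", 0.0)
            nocc, n_flag = _col("NOCC", 1.0)
            rows.append(ProfileRow(
                p=p,
                entropy=entropy,
                relative_entropy=relent,
                conservation_weight=weight,
                sequence_variability=var,
                nocc=int(nocc),
                flagged=e_flag or r_flag or w_flag or v_flag or n_flag,
            ))
    if header_idx is None:
        raise ProfileFormatError(f"{path}: no SEQUENCE PROFILE section found")
    return rows


# ---------------------------------------------------------------------------
# Simplified tab-separated profile dialect (fixture format)
# ---------------------------------------------------------------------------

TSV_COLUMNS = (
    tuple(f"p_{aa}" for aa in AA_ORDER)
    + ("entropy", "relative_entropy", "conservation_weight",
       "sequence_variability", "nocc")
)


def parse_profile_tsv(path) -> list[ProfileRow]:
    """Read the simplified 25-column profile dialect.

    Same contract as :func:`parse_hssp`.  A missing ``nocc`` column defaults
    to 1 with the row flagged; any other column deviation is a format error.
    """
    rows: list[ProfileRow] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ProfileFormatError(f"{path}: empty file")
        aa_col = "aa" in header
        expect = (("aa",) if aa_col else ()) + TSV_COLUMNS
        nocc_missing = tuple(header) == tuple(c for c in expect if c != "nocc")
        if tuple(header) != tuple(expect) and not nocc_missing:
            raise ProfileFormatError(
                f"{path}: bad header; expected {list(expect)} got {header}"
            )
        for lineno, rec in enumerate(reader, start=2):
            want = len(header)
            if len(rec) != want:
                raise ProfileFormatError(
                    f"{path}: line {lineno}: expected {want} fields, got {len(rec)}"
                )
            vals = dict(zip(header, rec))
            p = np.array([float(vals[f"p_{aa}"]) for aa in AA_ORDER])
            try:
                rows.append(ProfileRow(
                    p=p,
                    entropy=float(vals["entropy"]),
                    relative_entropy=float(vals["relative_entropy"]),
                    conservation_weight=float(vals["conservation_weight"]),
                    sequence_variability=float(vals["sequence_variability"]),
                    nocc=int(float(vals["nocc"])) if "nocc" in vals else 1,
                    aa=vals.get("aa", "X"),
                    flagged="nocc" not in vals,
                ))
            except ValueError as exc:
                raise ProfileFormatError(f"{path}: line {lineno}: {exc}") from exc
    return rows


def write_profile_tsv(path, rows: list[ProfileRow], with_aa: bool = True) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        header = (["aa"] if with_aa else []) + list(TSV_COLUMNS)
        writer.writerow(header)
        for row in rows:
            rec = ([row.aa] if with_aa else []) + [
                *(f"{v:.6g}" for v in row.p),
                f"{row.entropy:.6g}", f"{row.relative_entropy:.6g}",
                f"{row.conservation_weight:.6g}",
                f"{row.sequence_variability:.6g}", str(row.nocc),
            ]
            writer.writerow(rec)


# ---------------------------------------------------------------------------
# Physicochemical lookup and vector assembly
# ---------------------------------------------------------------------------

def physchem_lookup(aa: str) -> np.ndarray:
    """13 physicochemical values for one residue: 8 cluster indices + 5 factors.

    Unknown residues ('X') get the column-wise mean over the 20 amino acids.
    """
    if aa in HQI8:
        return np.concatenate([HQI8[aa], AA_FACTORS[aa]])
    hqi_mean = np.mean([HQI8[a] for a in HQI8], axis=0)
    fac_mean = np.mean([AA_FACTORS[a] for a in AA_FACTORS], axis=0)
    return np.concatenate([hqi_mean, fac_mean])


def assemble_residue_vector(
    profile: ProfileRow,
    structure_values: np.ndarray,
    physchem: np.ndarray,
) -> np.ndarray:
    """Concatenate the parts into the fixed 50-value residue descriptor.

    ``structure_values`` is the 12-vector (5 ASA, 5 RASA, dpx, cx) in the
    order of :data:`FEATURE_NAMES`.
    """
    if profile is None:
        raise ValueError("assembly error: profile row missing")
    structure_values = np.asarray(structure_values, dtype=float)
    if structure_values.shape != (12,):
        raise ValueError("assembly error: structure part must have 12 values")
    physchem = np.asarray(physchem, dtype=float)
    if physchem.shape != (13,):
        raise ValueError("assembly error: physicochemical part must have 13 values")
    vec = np.concatenate([profile.vector25, structure_values, physchem])
    assert vec.shape == (N_FEATURES,)
    return vec
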