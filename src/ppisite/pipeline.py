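"""End-to-end orchestration: structure -> features -> labels -> model -> metrics.

`run_extract` turns one complex (PDB + per-chain profiles) into the encoded
feature matrix, interface labels and chain groups.  `run_train_eval` splits
by chain, cross-validates the bagging ensemble on the training chains and
reports held-out metrics.  Both are deterministic given the config.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import encoding, ensemble, evaluation, geometry, labeling, profiles, sasa
from .structure import ComplexStructure, read_pdb

__all__ = ["RunConfig", "ExtractResult", "run_extract", "extract_from_structure",
           "group_train_test_split", "run_train_eval", "write_report"]


@dataclass
class RunConfig:
    window: int = 11
    surface_threshold: float = 0.16
    interface_delta: float = 1.0
    m: int = 10
    seed: int = 0
    folds: int = 5
    complex_type: str = "hetero"
    sort_by_distance: bool = True
    weight_by_distance: bool = True  # False: plain (unweighted) window encoding
    sasa_n_points: int = 960
    probe_radius: float = 1.4
    test_fraction: float = 0.3

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExtractResult:
    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray  # chain index per row
    chain_ids: list[str]
    labels: labeling.ResidueLabels
    manifest: dict = field(default_factory=dict)

    def write_csv(self, path) -> None:
        w50 = self.X.shape[1]
        header = ["chain", "label"] + [f"f{i}" for i in range(w50)]
        with open(path, "w") as fh:
            fh.write(",".join(header) + "\n")
            for ci, yi, row in zip(self.groups, self.y, self.X):
                fh.write(",".join(
                    [self.chain_ids[ci], str(int(yi))] + [f"{v:.8g}" for v in row]
                ) + "\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def extract_from_structure(
    structure: ComplexStructure,
    chain_profiles: dict[str, list[profiles.ProfileRow]],
    config: RunConfig,
) -> ExtractResult:
    """Feature extraction on an in-memory structure (no file I/O)."""
    for chain in structure.chains:
        rows = chain_profiles.get(chain.chain_id)
        if rows is None:
            raise ValueError(f"extract: missing profile for chain {chain.chain_id!r}")
        if len(rows) != chain.length:
            raise ValueError(
                f"extract: chain {chain.chain_id!r} has {chain.length} residues "
                f"but profile has {len(rows)} rows"
            )

    kw = {"probe_radius": config.probe_radius, "n_points": config.sasa_n_points}
    casa = sasa.residue_asa(structure, context="bound", **kw)
    masa = sasa.relative_asa(sasa.residue_asa(structure, context="unbound", **kw))

    per_atom_bound = sasa.shrake_rupley(structure.atoms(), **kw)
    dpx = geometry.depth_index(structure, per_atom_bound)
    cx = geometry.protrusion_index(structure)

    surface = labeling.label_surface(masa, config.surface_threshold)
    labels = labeling.label_interface(masa, casa, surface, config.interface_delta)

    # Per-chain 50-feature matrices in the documented order.
    chain_features, chain_ca, chain_masks, chain_labels = [], [], [], []
    row = 0
    for chain in structure.chains:
        L = chain.length
        feats = np.empty((L, profiles.N_FEATURES))
        for i, res in enumerate(chain.residues):
            r = row + i
            structure_part = np.array([
                masa.total_asa[r], masa.backbone_asa[r], masa.sidechain_asa[r],
                masa.polar_asa[r], masa.nonpolar_asa[r],
                masa.total_rasa[r], masa.backbone_rasa[r], masa.sidechain_rasa[r],
                masa.polar_rasa[r], masa.nonpolar_rasa[r],
                dpx.values[r], cx.values[r],
            ])
            feats[i] = profiles.assemble_residue_vector(
                chain_profiles[chain.chain_id][i],
                structure_part,
                profiles.physchem_lookup(res.aa),
            )
        chain_features.append(feats)
        chain_ca.append([res.ca_coord for res in chain.residues])
        chain_masks.append(surface[row:row + L])
        chain_labels.append(labels.is_interface[row:row + L])
        row += L

    X, y, groups = encoding.encode_dataset(
        chain_features, chain_ca, chain_masks, chain_labels,
        w=config.window,
        sort_by_distance=config.sort_by_distance,
        weight_by_distance=config.weight_by_distance,
    )
    return ExtractResult(
        X=X, y=y, groups=groups,
        chain_ids=[c.chain_id for c in structure.chains],
        labels=labels,
        manifest={"config": config.to_dict(),
                  "n_rows": int(X.shape[0]), "n_cols": int(X.shape[1])},
    )


def run_extract(pdb_path, profile_paths: dict[str, str], config: RunConfig) -> ExtractResult:
    """Extraction from files; the manifest records config and input hashes."""
    structure = read_pdb(pdb_path)
    chain_profiles = {}
    for chain in structure.chains:
        path = profile_paths.get(chain.chain_id)
        if path is None or not os.path.exists(path or ""):
            raise FileNotFoundError(
                f"extract: no profile file for chain {chain.chain_id!r}"
            )
        if path.endswith(".hssp"):
            chain_profiles[chain.chain_id] = profiles.parse_hssp(path)
        else:
            chain_profiles[chain.chain_id] = profiles.parse_profile_tsv(path)
    result = extract_from_structure(structure, chain_profiles, config)
    result.manifest["inputs"] = {
        "pdb": _sha256(pdb_path),
        **{c: _sha256(p) for c, p in profile_paths.items()},
    }
    return result


def group_train_test_split(
    y: np.ndarray, groups: np.ndarray, test_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean test mask keeping every group wholly on one side of the split.

    With a single group, falls back to a stratified per-sample split.
    """
    y = np.asarray(y)
    groups = np.asarray(groups)
    unique_groups = np.unique(groups)
    if len(unique_groups) >= 2:
        shuffled = unique_groups.copy()
        rng.shuffle(shuffled)
        n_test = max(1, int(round(test_fraction * len(shuffled))))
        test_mask = np.isin(groups, shuffled[:n_test])
        if test_mask.all():
            test_mask = np.zeros(len(y), dtype=bool)
        return test_mask
    test_mask = np.zeros(len(y), dtype=bool)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        test_mask[idx[: int(round(test_fraction * len(idx)))]] = True
    return test_mask


def run_train_eval(config: RunConfig, X: np.ndarray, y: np.ndarray,
                   groups: np.ndarray | None = None) -> dict:
    """Chain-grouped train/test split, CV on the training part, test metrics.

    All residues of one chain stay on the same side of the split (residue
    windows overlap, so residue-level splits would leak).  Returns a
    JSON-serializable report.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty feature matrix")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    rng = np.random.default_rng(config.seed)
    if groups is None:
        groups = np.zeros(len(y), dtype=int)
    test_mask = group_train_test_split(y, groups, config.test_fraction, rng)

    bag_config = ensemble.BaggingConfig(m=config.m, seed=config.seed)
    report: dict = {"config": config.to_dict()}

    X_train, y_train = X[~test_mask], y[~test_mask]
    folds, pooled, pooled_report = ensemble.cross_validate(
        X_train, y_train, k=config.folds, config=bag_config, seed=config.seed
    )
    report["cv"] = {
        "pooled": pooled_report.to_dict(),
        "folds": [f.report.to_dict() for f in folds],
    }

    model = ensemble.train_bagging(X_train, y_train, bag_config)
    if test_mask.any() and len(np.unique(y[test_mask])) == 2:
        pred, scores = ensemble.predict_vote(model, X[test_mask])
        counts = evaluation.confusion(y[test_mask], pred)
        test_report = evaluation.metrics(counts)
        roc = evaluation.roc_points(y[test_mask], scores)
        test_report.roc = roc
        test_report.auc = evaluation.auc(roc)
        report["test"] = test_report.to_dict()
        report["test"]["roc"] = roc
    else:
        report["test"] = None
    report["_model"] = model  # stripped before JSON serialization
    return report


def write_report(report: dict, path) -> None:
    payload = {k: v for k, v in report.items() if not k.startswith("_")}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
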