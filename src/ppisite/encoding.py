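"""Distance-weighted sliding-window residue descriptor.

A query residue is described by the 50-vectors of its sequential window
neighbours, each divided by the Calpha-Calpha Euclidean distance to the
query (the query's own distance is fixed at 1, leaving its block
unweighted).  Blocks are arranged in ascending distance order (ties broken
by sequence position) with zero blocks for window slots that fall off the
chain appended last, giving a fixed w x 50 layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import N_FEATURES

__all__ = [
    "WindowDescriptor",
    "window_indices",
    "euclidean_distance",
    "encode_residue",
    "encode_dataset",
    "PAD",
]

PAD = -1
DEFAULT_WINDOW = 11


def window_indices(query: int, w: int, length: int) -> list[int]:
    """Sequential window slot positions around ``query``; PAD marks off-chain.

    Slots run query-(w-1)/2 ... query+(w-1)/2 in sequence order.
    """
    if w % 2 == 0 or w < 1:
        raise ValueError("window size must be a positive odd number")
    if not 0 <= query < length:
        raise ValueError("query position outside chain")
    half = (w - 1) // 2
    return [
        pos if 0 <= (pos := query + off) < length else PAD
        for off in range(-half, half + 1)
    ]


def euclidean_distance(a: np.ndarray, b: np.ndarray, self_pair: bool = False) -> float:
    """Calpha distance in Angstrom; a residue's distance to itself is 1."""
    if self_pair:
        return 1.0
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(((a - b) ** 2).sum()))


@dataclass
class WindowDescriptor:
    query_index: int
    window_size: int
    values: np.ndarray  # w*50
    distances: np.ndarray  # w (padded slots: inf)
    padding_mask: np.ndarray  # w bools, True where padded

    def __post_init__(self) -> None:
        expected = self.window_size * N_FEATURES
        if self.values.shape != (expected,):
            raise ValueError(f"descriptor must have {expected} values")


def encode_residue(
    features: np.ndarray,
    ca_coords: list,
    query: int,
    w: int = DEFAULT_WINDOW,
    sort_by_distance: bool = True,
    weight_by_distance: bool = True,
) -> WindowDescriptor:
    """Encode one residue as its w x 50 distance-weighted window descriptor.

    ``features`` is the (L, 50) per-residue matrix and ``ca_coords`` the
    aligned Calpha coordinates.  ``sort_by_distance=False`` keeps plain
    sequence order; ``weight_by_distance=False`` sets every distance to 1
    (unweighted window encoding).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != N_FEATURES:
        raise ValueError(f"features must be (L, {N_FEATURES})")
    length = features.shape[0]
    slots = window_indices(query, w, length)
    if ca_coords[query] is None:
        raise ValueError(f"query residue {query} has no coordinates")

    real: list[tuple[float, int]] = []  # (distance, position)
    for pos in slots:
        if pos == PAD:
            continue
        if pos == query:
            d = 1.0
        else:
            if ca_coords[pos] is None:
                raise ValueError(f"window residue {pos} has no coordinates")
            d = euclidean_distance(ca_coords[query], ca_coords[pos])
        real.append((d, pos))
    if sort_by_distance:
        real.sort(key=lambda t: (t[0], t[1]))

    blocks, dists, mask = [], [], []
    for d, pos in real:
        weight = d if weight_by_distance else 1.0
        blocks.append(features[pos] / weight)
        dists.append(d)
        mask.append(False)
    for _ in range(w - len(real)):
        blocks.append(np.zeros(N_FEATURES))
        dists.append(np.inf)
        mask.append(True)
    return WindowDescriptor(
        query_index=query,
        window_size=w,
        values=np.concatenate(blocks),
        distances=np.array(dists),
        padding_mask=np.array(mask),
    )


def encode_dataset(
    chain_features: list[np.ndarray],
    chain_ca: list[list],
    chain_masks: list[np.ndarray],
    chain_labels: list[np.ndarray],
    w: int = DEFAULT_WINDOW,
    sort_by_distance: bool = True,
    weight_by_distance: bool = True,
):
    """Stack descriptors of the selected residues of several chains.

    ``chain_masks`` selects the residues to encode (typically the surface
    residues); ``chain_labels`` are the per-residue interface flags.
    Returns (X, y, groups) where groups carries one chain index per row.
    """
    rows, ys, groups = [], [], []
    for ci, (feats, ca, mask, labels) in enumerate(
        zip(chain_features, chain_ca, chain_masks, chain_labels)
    ):
        mask = np.asarray(mask, dtype=bool)
        labels = np.asarray(labels)
        for pos in np.nonzero(mask)[0]:
            desc = encode_residue(
                feats, ca, int(pos), w,
                sort_by_distance=sort_by_distance,
                weight_by_distance=weight_by_distance,
            )
            rows.append(desc.values)
            ys.append(int(labels[pos]))
            groups.append(ci)
    if rows:
        X = np.vstack(rows)
    else:
        X = np.empty((0, w * N_FEATURES))
    return X, np.array(ys, dtype=int), np.array(groups, dtype=int)
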