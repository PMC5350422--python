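"""Kennard-Stone training-set selection.

The Kennard-Stone algorithm picks a representative calibration subset
deterministically: start with the two most mutually distant samples, then
repeatedly add the sample whose nearest already-selected neighbour is
farthest away (max-min criterion).  The remaining samples form the test
set.  Distances are Euclidean on the preprocessed fingerprint matrix; ties
are broken by the lowest original index so the split is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .types import FingerprintMatrix

__all__ = ["KSSplit", "kennard_stone", "train_size_for_ratio"]


@dataclass
class KSSplit:
    """Result of a Kennard-Stone split; train order = selection order."""

    train_indices: list
    test_indices: list
    distance_metric: str = "euclidean"

    def to_dict(self) -> dict:
        return {"train_indices": [int(i) for i in self.train_indices],
                "test_indices": [int(i) for i in self.test_indices],
                "distance_metric": self.distance_metric}


def train_size_for_ratio(n_samples: int, ratio: float = 2.0 / 3.0) -> int:
    """Training-set size for a split ratio, rounding half up (72 -> 48 at 2/3)."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    return int(np.floor(ratio * n_samples + 0.5))


def kennard_stone(X: FingerprintMatrix | np.ndarray, n_train: int) -> KSSplit:
    """Select ``n_train`` calibration samples by the max-min distance rule."""
    arr = X.X if isinstance(X, FingerprintMatrix) else np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    n = arr.shape[0]
    if not 2 <= n_train <= n:
        raise ValueError(f"n_train must be in [2, {n}], got {n_train}")
    d = squareform(pdist(arr, metric="euclidean"))
    # seed pair: maximal distance, ties -> lexicographically smallest (i, j)
    best = np.unravel_index(np.argmax(d), d.shape)
    i0, j0 = int(min(best)), int(max(best))
    selected = [i0, j0]
    remaining = [i for i in range(n) if i not in (i0, j0)]
    min_dist = np.minimum(d[i0], d[j0])
    while len(selected) < n_train:
        cand_dists = min_dist[remaining]
        pick = remaining[int(np.argmax(cand_dists))]  # argmax keeps first (lowest index) on ties
        selected.append(pick)
        remaining.remove(pick)
        min_dist = np.minimum(min_dist, d[pick])
    return KSSplit(train_indices=selected, test_indices=sorted(remaining))
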