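"""Fingerprint similarity and panel homogeneity diagnostics.

Batch consistency of herbal extracts is conventionally summarised by a
similarity index (SI, %): each extract's fingerprint is compared against a
reference fingerprint — the pointwise median of its batch — and the
congruence (cosine) coefficient x 100 is reported.  On non-negative
chromatograms this lands in the familiar high-80s-to-high-90s range for
consistent batches.  A Pearson-correlation variant is available opt-in.

PCA on the mean-centred fingerprint matrix provides the complementary
homogeneity view: batches that differ systematically separate in score
space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .types import FingerprintMatrix

__all__ = ["SimilarityReport", "median_reference", "similarity_index",
           "group_similarity", "between_batch_similarity", "pca_scores"]


@dataclass
class SimilarityReport:
    """Per-batch similarity summary."""

    group_label: str
    reference: np.ndarray
    sample_ids: list
    si: np.ndarray  # per-sample similarity index, %
    mean: float
    sd: float | None  # sample sd (n-1); None when the group has < 2 members
    min: float
    max: float


def median_reference(X: FingerprintMatrix | np.ndarray, rows=None) -> np.ndarray:
    """Pointwise median fingerprint over the selected rows."""
    arr = X.X if isinstance(X, FingerprintMatrix) else np.asarray(X, dtype=float)
    if rows is not None:
        rows = np.asarray(rows, dtype=int)
        if rows.size == 0:
            raise ValueError("empty row selection")
        arr = arr[rows]
    if arr.shape[0] == 0:
        raise ValueError("empty row selection")
    return np.median(arr, axis=0)


def similarity_index(x: np.ndarray, reference: np.ndarray, method: str = "cosine") -> float:
    """Similarity index (%) of one fingerprint against a reference.

    ``cosine`` (default): 100 * x.ref / (||x|| ||ref||).  ``pearson``:
    100 * Pearson correlation of the two traces.  An all-zero ``x`` scores 0;
    an all-zero reference is an error.
    """
    x = np.asarray(x, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if x.shape != reference.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {reference.shape}")
    if method == "pearson":
        x = x - x.mean()
        reference = reference - reference.mean()
    elif method != "cosine":
        raise ValueError(f"unknown method {method!r}")
    ref_norm = np.linalg.norm(reference)
    if ref_norm == 0:
        raise ValueError("reference fingerprint is all-zero (or constant, for pearson)")
    x_norm = np.linalg.norm(x)
    if x_norm == 0:
        return 0.0
    return float(100.0 * (x @ reference) / (x_norm * ref_norm))


def group_similarity(X: FingerprintMatrix, groups=None, method: str = "cosine") -> list:
    """One :class:`SimilarityReport` per batch.

    Each batch's reference is the median fingerprint of that batch; every
    member is scored against it.  The SD is the sample (n-1) standard
    deviation; a single-member batch reports ``sd=None``.
    """
    labels = list(groups) if groups is not None else list(X.batch_ids)
    if len(labels) != X.n_samples:
        raise ValueError("one group label per sample required")
    reports = []
    for label in sorted(set(labels), key=str):
        idx = [i for i, g in enumerate(labels) if g == label]
        ref = median_reference(X, idx)
        si = np.array([similarity_index(X.X[i], ref, method=method) for i in idx])
        sd = float(np.std(si, ddof=1)) if len(si) >= 2 else None
        reports.append(SimilarityReport(
            group_label=str(label), reference=ref,
            sample_ids=[X.sample_ids[i] for i in idx], si=si,
            mean=float(si.mean()), sd=sd, min=float(si.min()), max=float(si.max())))
    return reports


def between_batch_similarity(X: FingerprintMatrix, method: str = "cosine") -> dict:
    """SI between the median reference fingerprints of each pair of batches."""
    reports = group_similarity(X, method=method)
    out = {}
    for i in range(len(reports)):
        for j in range(i + 1, len(reports)):
            a, b = reports[i], reports[j]
            out[(a.group_label, b.group_label)] = similarity_index(
                a.reference, b.reference, method=method)
    return out


def pca_scores(X: FingerprintMatrix | np.ndarray, k: int):
    """Top-k PCA scores of the mean-centred fingerprint matrix.

    Returns ``(scores, explained_variance_ratio)`` where scores is
    samples x k.  Used as a homogeneity diagnostic: tight batch clusters
    mean consistent fingerprints; separated centroids mean batch effects.
    """
    arr = X.X if isinstance(X, FingerprintMatrix) else np.asarray(X, dtype=float)
    limit = min(arr.shape[0] - 1, arr.shape[1])
    if not 1 <= k <= limit:
        raise ValueError(f"k must be in [1, {limit}] for a {arr.shape} matrix")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(arr)
    return scores, pca.explained_variance_ratio_
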