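"""Baseline correction, peak alignment and matrix assembly.

Raw chromatograms carry a slowly varying baseline (mobile-phase gradient
drift) and small run-to-run retention-time shifts.  Both must be removed
before whole-chromatogram regression: the baseline via an asymmetric
least-squares smoother, the shifts via a single global integer-step lateral
shift against a reference trace.  Aligned traces are then interpolated onto
a common grid to form the :class:`~qpar.types.FingerprintMatrix`.

Intensities are deliberately *not* area-normalised by default: absolute
region intensity is read downstream as "amount of compound", which
normalisation would distort.  An opt-in flag is provided.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .types import Chromatogram, FingerprintMatrix

__all__ = ["asls_baseline", "correct_baseline", "align_to_reference",
           "build_matrix", "preprocess_panel"]


def asls_baseline(y: np.ndarray, smoothness: float = 1e5, asymmetry: float = 0.01,
                  max_iter: int = 10) -> np.ndarray:
    """Estimate a smooth baseline by asymmetric least squares.

    Minimises ``sum_i w_i (y_i - z_i)^2 + smoothness * sum_i (d2 z)_i^2``
    where points above the current baseline get the small weight
    ``asymmetry`` and points below get ``1 - asymmetry``, so peaks (which
    stick up) barely pull the baseline while the off-peak floor anchors it.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 points to estimate a baseline")
    if not 0 < asymmetry < 1:
        raise ValueError("asymmetry must be in (0, 1)")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    d = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = smoothness * (d.T @ d)
    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        wmat = sp.diags(w, 0, format="csc")
        z = spsolve(wmat + penalty, w * y)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def correct_baseline(c: Chromatogram, smoothness: float = 1e5, asymmetry: float = 0.01,
                     max_iter: int = 10) -> Chromatogram:
    """Subtract the asymmetric-least-squares baseline from a chromatogram.

    The estimated baseline hugs the off-peak floor (it lies at or below the
    peak apexes), so subtracting it flattens drift while preserving peak
    heights.  The step and its parameters are appended to the trace history.
    """
    baseline = asls_baseline(c.intensity, smoothness=smoothness,
                             asymmetry=asymmetry, max_iter=max_iter)
    out = c.copy()
    out.intensity = c.intensity - baseline
    out.history.append({"step": "baseline_asls", "smoothness": smoothness,
                        "asymmetry": asymmetry, "max_iter": max_iter})
    return out


def align_to_reference(c: Chromatogram, reference: np.ndarray,
                       max_shift: float = 0.5) -> Chromatogram:
    """Laterally shift a trace to best match a reference on the same grid.

    Tries every integer-step shift within ``+/- max_shift`` minutes and
    keeps the one maximising the inner product with the reference;
    out-shifted edges are zero-filled.  A single global shift is used, not
    piecewise warping — sufficient to undo run-to-run retention drift.
    """
    reference = np.asarray(reference, dtype=float)
    if len(reference) != len(c.intensity):
        raise ValueError("reference must be on the same grid as the chromatogram")
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    step = float(np.median(np.diff(c.rt))) if len(c.rt) > 1 else 1.0
    span = c.rt[-1] - c.rt[0]
    if max_shift > span / 2:
        raise ValueError("max_shift exceeds half the grid span")
    k_max = int(np.floor(max_shift / step + 1e-9))
    best_k, best_score = 0, -np.inf
    y = c.intensity
    for k in range(-k_max, k_max + 1):
        if k >= 0:
            score = float(y[: len(y) - k] @ reference[k:]) if k < len(y) else -np.inf
        else:
            score = float(y[-k:] @ reference[: len(y) + k])
        if score > best_score:
            best_score, best_k = score, k
    shifted = np.zeros_like(y)
    if best_k >= 0:
        shifted[best_k:] = y[: len(y) - best_k]
    else:
        shifted[:best_k] = y[-best_k:]
    out = c.copy()
    out.intensity = shifted
    out.history.append({"step": "align", "shift_points": best_k,
                        "shift_minutes": best_k * step, "max_shift": max_shift})
    return out


def build_matrix(cs: list, target_grid: np.ndarray) -> FingerprintMatrix:
    """Interpolate chromatograms onto a shared grid and stack them.

    Linear interpolation; a sample whose observed retention range does not
    cover ``target_grid`` is an error (no extrapolation).  Row order follows
    input order.
    """
    target_grid = np.asarray(target_grid, dtype=float)
    if len(cs) == 0:
        raise ValueError("no chromatograms given")
    rows = np.empty((len(cs), len(target_grid)))
    log: list = []
    for i, c in enumerate(cs):
        if c.rt[0] > target_grid[0] + 1e-12 or c.rt[-1] < target_grid[-1] - 1e-12:
            raise ValueError(
                f"sample {c.sample_id!r}: observed range [{c.rt[0]}, {c.rt[-1]}] "
                f"does not cover target grid [{target_grid[0]}, {target_grid[-1]}]"
            )
        rows[i] = np.interp(target_grid, c.rt, c.intensity)
        log.extend({"sample_id": c.sample_id, **h} for h in c.history)
    log.append({"step": "build_matrix", "n_samples": len(cs),
                "n_points": len(target_grid)})
    return FingerprintMatrix(grid=target_grid, X=rows,
                             sample_ids=[c.sample_id for c in cs],
                             batch_ids=[c.batch_id for c in cs],
                             preprocessing_log=log)


def preprocess_panel(cs: list, smoothness: float = 1e5, asymmetry: float = 0.01,
                     max_iter: int = 10, max_shift: float = 0.5,
                     normalize_area: bool = False) -> FingerprintMatrix:
    """Full pipeline: baseline-correct, align to the panel median, stack.

    The alignment reference is the pointwise median of the baseline-corrected
    traces.  ``normalize_area=True`` additionally scales each row to unit
    total intensity (opt-in; see module docstring).
    """
    corrected = [correct_baseline(c, smoothness, asymmetry, max_iter) for c in cs]
    grid = corrected[0].rt
    stack = np.vstack([c.intensity for c in corrected])
    reference = np.median(stack, axis=0)
    aligned = [align_to_reference(c, reference, max_shift) for c in corrected]
    fm = build_matrix(aligned, grid)
    if normalize_area:
        totals = fm.X.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError("cannot area-normalise a trace with non-positive total")
        fm.X = fm.X / totals
        fm.preprocessing_log.append({"step": "area_normalize"})
    return fm
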