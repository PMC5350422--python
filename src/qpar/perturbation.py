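"""Region-perturbation sensitivity analysis.

Given a fitted linear fingerprint-activity model, scaling the intensity of
a chromatogram region (a putative compound group) on a base fingerprint and
re-predicting measures how much that region drives the predicted
bioactivity.  Because the model is affine, the response is exactly

    delta(region, s) = s * sum_{j in region} coef_j * base_j

for a fractional increase ``s`` — so deltas scale linearly with the dose
(a 200% increase gives 4x the 50% delta), disjoint regions add, and
zero-coefficient regions give exactly zero at every scale.  The analysis
still perturbs and re-predicts rather than evaluating the formula, so it
remains valid for any predictor with a ``predict`` method; the linear
identity is what the tests assert.

Regions are data-driven contiguous runs of same-sign model coefficients,
ranked by the magnitude of the aggregate coefficient.  The "coefficient"
reported per region is that aggregate — the quantity that actually
propagates into the prediction; a univariate Pearson correlation per region
can be reported alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import FingerprintMatrix

__all__ = ["RegionSpec", "mean_fingerprint", "select_regions",
           "select_regions_combined", "perturb_and_predict",
           "perturbation_table"]

ZERO_REL_TOL = 1e-8  # |coef| below this fraction of max|coef| counts as zero


@dataclass
class RegionSpec:
    """A contiguous grid interval with its aggregate model coefficient."""

    region_id: int
    start: int  # grid index, inclusive
    end: int  # grid index, exclusive
    category: str  # "positive" | "negative" | "zero"
    aggregate_coefficient: float

    @property
    def interval(self) -> tuple:
        return (self.start, self.end)


def mean_fingerprint(X: FingerprintMatrix | np.ndarray) -> np.ndarray:
    """Columnwise mean fingerprint of a panel."""
    arr = X.X if isinstance(X, FingerprintMatrix) else np.asarray(X, dtype=float)
    if arr.shape[0] == 0:
        raise ValueError("empty panel")
    return arr.mean(axis=0)


def _runs(signs: np.ndarray):
    """Yield (start, end, sign) for maximal constant-sign runs."""
    start = 0
    for i in range(1, len(signs) + 1):
        if i == len(signs) or signs[i] != signs[start]:
            yield start, i, int(signs[start])
            start = i


def select_regions(model, n_features: int, n_pos: int, n_neg: int, n_zero: int,
                   min_width: int = 5, _return_all_zero: bool = False) -> list:
    """Pick the strongest positive/negative and widest zero coefficient runs.

    The model's full-grid regression vector is segmented into maximal
    contiguous runs of constant coefficient sign (zero meaning
    ``|coef| < 1e-8 * max|coef|``).  Runs shorter than ``min_width`` are
    ignored.  Positive and negative runs are ranked by |aggregate
    coefficient|, zero runs by width; the requested numbers are returned as
    non-overlapping :class:`RegionSpec` entries ordered by start index.
    """
    coef = model.full_coef(n_features)
    max_abs = np.max(np.abs(coef))
    if max_abs == 0:
        if n_pos or n_neg:
            raise ValueError("all coefficients are zero: no positive/negative regions exist")
        ztol = 0.0
    else:
        ztol = ZERO_REL_TOL * max_abs
    signs = np.where(np.abs(coef) <= ztol, 0, np.sign(coef)).astype(int)
    pos, neg, zero = [], [], []
    for start, end, sign in _runs(signs):
        if end - start < min_width:
            continue
        agg = float(coef[start:end].sum())
        if sign > 0:
            pos.append((start, end, agg))
        elif sign < 0:
            neg.append((start, end, agg))
        else:
            zero.append((start, end, 0.0))
    pos.sort(key=lambda r: -abs(r[2]))
    neg.sort(key=lambda r: -abs(r[2]))
    zero.sort(key=lambda r: -(r[1] - r[0]))
    if _return_all_zero:
        return [RegionSpec(region_id=i + 1, start=s, end=e, category="zero",
                           aggregate_coefficient=0.0)
                for i, (s, e, _a) in enumerate(zero)]
    for name, runs, want in (("positive", pos, n_pos), ("negative", neg, n_neg),
                             ("zero", zero, n_zero)):
        if len(runs) < want:
            raise ValueError(
                f"only {len(runs)} qualifying {name} regions of width >= {min_width}, "
                f"but {want} requested")
    chosen = ([(s, e, a, "positive") for s, e, a in pos[:n_pos]]
              + [(s, e, a, "negative") for s, e, a in neg[:n_neg]]
              + [(s, e, a, "zero") for s, e, a in zero[:n_zero]])
    chosen.sort(key=lambda r: r[0])
    return [RegionSpec(region_id=i + 1, start=s, end=e, category=cat,
                       aggregate_coefficient=a)
            for i, (s, e, a, cat) in enumerate(chosen)]


def select_regions_combined(pls_model, en_model, n_features: int, n_pos: int,
                            n_neg: int, n_zero: int, min_width: int = 5) -> list:
    """Region set drawing on both models' coefficients.

    Positive and negative regions come from the (dense) plain-PLS
    regression vector; zero regions come from the EN-PLS vector, which is
    exactly zero outside the elastic-net support — a dense PLS vector has
    no true zero runs.  Zero candidates overlapping a chosen
    positive/negative region are discarded; regions are renumbered by start
    index.
    """
    signed = select_regions(pls_model, n_features, n_pos, n_neg, 0, min_width)
    zero_pool = select_regions(en_model, n_features, 0, 0, 0, min_width,
                               _return_all_zero=True)
    taken = [(r.start, r.end) for r in signed]
    zeros = []
    for r in zero_pool:
        if all(r.end <= s or r.start >= e for s, e in taken):
            zeros.append(r)
            taken.append((r.start, r.end))
        if len(zeros) == n_zero:
            break
    if len(zeros) < n_zero:
        raise ValueError(f"only {len(zeros)} non-overlapping zero regions of "
                         f"width >= {min_width} available, {n_zero} requested")
    merged = sorted(signed + zeros, key=lambda r: r.start)
    return [RegionSpec(region_id=i + 1, start=r.start, end=r.end,
                       category=r.category,
                       aggregate_coefficient=r.aggregate_coefficient)
            for i, r in enumerate(merged)]


def perturb_and_predict(model, base: np.ndarray, region: RegionSpec,
                        fractional_increase: float) -> float:
    """Predicted activity change when a region's intensity is scaled up.

    Multiplies the region's intensities by ``1 + fractional_increase`` on a
    copy of ``base`` and returns ``predict(perturbed) - predict(base)``.
    """
    base = np.asarray(base, dtype=float)
    if fractional_increase < 0:
        raise ValueError("fractional_increase must be >= 0")
    if not (0 <= region.start < region.end <= len(base)):
        raise ValueError(f"region [{region.start}, {region.end}) outside grid "
                         f"of {len(base)} points")
    perturbed = base.copy()
    perturbed[region.start:region.end] *= 1.0 + fractional_increase
    return float(model.predict(perturbed[None, :])[0] - model.predict(base[None, :])[0])


def perturbation_table(models: dict, base: np.ndarray, regions: list,
                       scales=(0.5, 1.0, 2.0), X=None, y=None) -> pd.DataFrame:
    """Full region x model x scale response table.

    One row per (region, model): the region's aggregate coefficient under
    that model and the predicted activity delta at each fractional
    increase.  If a panel ``X`` and activities ``y`` are supplied, a
    univariate Pearson correlation between the region's summed intensity
    and the activity is added for transparency.
    """
    base = np.asarray(base, dtype=float)
    rows = []
    for region in regions:
        for name, model in models.items():
            coef = model.full_coef(len(base))
            agg = float(coef[region.start:region.end].sum())
            row = {"region_id": region.region_id, "start": region.start,
                   "end": region.end, "category": region.category,
                   "model": name, "coefficient": agg}
            for s in scales:
                row[f"delta_{int(round(100 * s))}"] = perturb_and_predict(
                    model, base, region, s)
            if X is not None and y is not None:
                arr = X.X if isinstance(X, FingerprintMatrix) else np.asarray(X, dtype=float)
                region_total = arr[:, region.start:region.end].sum(axis=1)
                if np.std(region_total) > 0 and np.std(y) > 0:
                    row["pearson_r"] = float(np.corrcoef(region_total, y)[0, 1])
                else:
                    row["pearson_r"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
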