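"""Core containers for fingerprint-to-bioactivity modelling.

A *chemical fingerprint* is a full HPLC-DAD chromatogram treated as a
high-dimensional intensity vector over retention time.  The containers here
carry single chromatograms, the aligned sample x time-point matrix used as
the regression design, and the per-sample bioactivity response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Chromatogram", "FingerprintMatrix", "ActivitySeries"]


@dataclass
class Chromatogram:
    """One sample's retention-time trace.

    Parameters
    ----------
    sample_id, batch_id : str
        Sample label and production batch.
    rt : ndarray
        Retention-time grid in minutes, strictly increasing.
    intensity : ndarray
        Detector response (absorbance units), same length as ``rt``.
    extraction : tuple, optional
        ``(reflux_hours, solvent_mL)`` extraction conditions.
    history : list
        Ordered record of preprocessing steps applied to this trace.
    """

    sample_id: str
    batch_id: str
    rt: np.ndarray
    intensity: np.ndarray
    extraction: tuple | None = None
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("rt and intensity must be 1-D")
        if len(self.rt) != len(self.intensity):
            raise ValueError(
                f"rt and intensity length mismatch for sample {self.sample_id!r}: "
                f"{len(self.rt)} vs {len(self.intensity)}"
            )
        if len(self.rt) > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError(f"rt must be strictly increasing (sample {self.sample_id!r})")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError(f"non-finite intensities in sample {self.sample_id!r}")

    def copy(self) -> "Chromatogram":
        return Chromatogram(
            sample_id=self.sample_id,
            batch_id=self.batch_id,
            rt=self.rt.copy(),
            intensity=self.intensity.copy(),
            extraction=self.extraction,
            history=list(self.history),
        )


@dataclass
class FingerprintMatrix:
    """Aligned fingerprint panel: the model's X.

    Rows are samples, columns are shared retention-time grid points.
    ``preprocessing_log`` records every step (with parameters) that produced
    the matrix, for provenance.
    """

    grid: np.ndarray
    X: np.ndarray
    sample_ids: list
    batch_ids: list
    preprocessing_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x grid points)")
        if self.X.shape[1] != len(self.grid):
            raise ValueError("X column count does not match grid length")
        if self.X.shape[0] != len(self.sample_ids) or len(self.sample_ids) != len(self.batch_ids):
            raise ValueError("sample_ids/batch_ids length does not match X rows")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("FingerprintMatrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_points(self) -> int:
        return self.X.shape[1]

    def rows(self, indices) -> np.ndarray:
        return self.X[np.asarray(indices, dtype=int)]


@dataclass
class ActivitySeries:
    """Per-sample bioactivity: the model's y.

    The bioactivity is the percent change of CD80 surface expression on
    THP-1 cells relative to an untreated control.  Two equivalent scales are
    used in practice: the raw change ``delta`` (e.g. +8.33) and the
    offset scale ``offset + delta`` (e.g. 108.33 with the default offset of
    100).  ``offset`` records which scale ``values`` are on so reports can
    state it; 0 means the raw-change scale.
    """

    sample_ids: list
    values: np.ndarray
    offset: float = 100.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_ids):
            raise ValueError("values must be 1-D and match sample_ids")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.sample_ids, name="sample_id"), name="activity")

    def rescaled(self, offset: float) -> "ActivitySeries":
        """Return a copy shifted to a different offset convention."""
        return ActivitySeries(
            sample_ids=list(self.sample_ids),
            values=self.values + (offset - self.offset),
            offset=offset,
        )
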