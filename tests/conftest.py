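import numpy as np
import pytest

from qpar.preprocess import build_matrix, preprocess_panel
from qpar.simulate import (GenerationConfig, default_peak_library,
                           generate_peak_library, simulate_panel)


@pytest.fixture(scope="session")
def small_library():
    """Compact peak library (12 peaks, 0-20 min, 401 points) for fast tests."""
    return generate_peak_library(12, rt_range=(0.0, 20.0), grid_step=0.05, seed=3)


@pytest.fixture(scope="session")
def small_panel(small_library):
    """3 batches x 8 samples on the compact grid, default noise levels."""
    cfg = GenerationConfig(n_batches=3, n_per_batch=8, seed=11)
    chroms, activities, truth = simulate_panel(small_library, cfg)
    fm = build_matrix(chroms, chroms[0].rt)
    return {"chroms": chroms, "activities": activities, "truth": truth,
            "fm": fm, "config": cfg, "library": small_library}


@pytest.fixture(scope="session")
def default_panel():
    """Full study-scale panel: 3 batches x 24 extracts, 1401-point grid,
    preprocessed (baseline-corrected, median-aligned)."""
    library = default_peak_library(seed=0)
    cfg = GenerationConfig(seed=1)
    chroms, activities, truth = simulate_panel(library, cfg)
    fm = preprocess_panel(chroms)
    return {"chroms": chroms, "activities": activities, "truth": truth,
            "fm": fm, "config": cfg, "library": library}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def centered_orthonormal_design(n, p, seed=0):
    """Random design whose centred columns are exactly orthonormal."""
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, p))
    Xc = X - X.mean(axis=0)
    q, _ = np.linalg.qr(Xc)
    return q[:, :p]
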