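"""End-to-end orchestration: simulate/load -> preprocess -> similarity ->
Kennard-Stone split -> PLS and EN-PLS -> validation -> perturbation.

One :class:`RunConfig` drives the whole run; every stage's parameters are
echoed into the output bundle so a run is reproducible from its artefacts
alone.  Both models are validated against the *same* Kennard-Stone split.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io
from .elastic_net import ENPLSRegressor, default_lambda_grids, tune_en
from .metrics import validation_report
from .perturbation import (mean_fingerprint, perturbation_table,
                           select_regions_combined)
from .pls import PLSRegressionNIPALS, loo_cv
from .preprocess import preprocess_panel
from .similarity import group_similarity, pca_scores
from .simulate import GenerationConfig, default_peak_library, simulate_panel
from .split import kennard_stone, train_size_for_ratio
from .types import ActivitySeries, FingerprintMatrix

__all__ = ["RunConfig", "RunBundle", "run_qpar"]

log = logging.getLogger("qpar")


@dataclass
class RunConfig:
    """Everything a full run needs.

    Either ``matrix_path``+``activities_path`` (load real data) or
    ``generation`` (simulate) must be provided.
    """

    matrix_path: str | None = None
    activities_path: str | None = None
    generation: GenerationConfig | None = None
    preprocess: bool = True
    smoothness: float = 1e5
    asymmetry: float = 0.01
    baseline_max_iter: int = 10
    max_shift: float = 0.5
    normalize_area: bool = False
    train_ratio: float = 2.0 / 3.0
    max_components: int = 15
    tune_folds: int = 5
    lambda1_grid: list | None = None  # None -> data-driven geometric grid
    lambda2_grid: list | None = None
    n_lambda1: int = 20
    lambda1: float | None = None  # set both to skip tuning
    lambda2: float | None = None
    n_pos: int = 6
    n_neg: int = 5
    n_zero: int = 2
    min_region_width: int = 5
    scales: tuple = (0.5, 1.0, 2.0)
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix_path is None and self.generation is None:
            raise ValueError("config needs either input paths or a generation config")
        if not 0 < self.train_ratio < 1:
            raise ValueError("train_ratio must be in (0, 1)")


@dataclass
class RunBundle:
    """All artefacts of one run."""

    matrix: FingerprintMatrix
    activities: ActivitySeries
    similarity_reports: list
    pca: tuple
    ks_split: object
    pls_model: PLSRegressionNIPALS
    pls_report: object
    en_model: ENPLSRegressor
    en_report: object
    regions: list
    perturbations: object
    config: RunConfig
    timings: dict = field(default_factory=dict)


def _stage(name: str, timings: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", name, timings[name])
            else:
                log.error("stage %s failed: %s", name, exc)
            return False
    return _Timer()


def run_qpar(config: RunConfig) -> RunBundle:
    """Execute the full pipeline and (optionally) write every artefact."""
    timings: dict = {}

    with _stage("data", timings):
        if config.generation is not None:
            library = default_peak_library(seed=config.seed)
            gen = config.generation
            chroms, activities, truth = simulate_panel(library, gen)
        else:
            fm_loaded = io.read_matrix(config.matrix_path)
            activities = io.read_activities(config.activities_path)
            chroms, truth = None, None

    with _stage("preprocess", timings):
        if config.generation is not None:
            if config.preprocess:
                fm = preprocess_panel(chroms, smoothness=config.smoothness,
                                      asymmetry=config.asymmetry,
                                      max_iter=config.baseline_max_iter,
                                      max_shift=config.max_shift,
                                      normalize_area=config.normalize_area)
            else:
                from .preprocess import build_matrix
                fm = build_matrix(chroms, chroms[0].rt)
        else:
            fm = fm_loaded
        y = io.join_activities(fm, activities)

    with _stage("similarity", timings):
        sim_reports = group_similarity(fm)
        k = min(3, fm.n_samples - 1, fm.n_points)
        pca = pca_scores(fm, k)

    with _stage("split", timings):
        n_train = train_size_for_ratio(fm.n_samples, config.train_ratio)
        split = kennard_stone(fm, n_train)
        tr, te = split.train_indices, split.test_indices
        X_tr, X_te = fm.X[tr], fm.X[te]
        y_tr, y_te = y[tr], y[te]

    with _stage("fit_pls", timings):
        cap = int(min(config.max_components, len(tr) - 2, fm.n_points))
        rmsecv_curve, a_opt = loo_cv(X_tr, y_tr, cap)
        pls = PLSRegressionNIPALS(n_components=a_opt).fit(X_tr, y_tr)
        pls_report = validation_report(
            pls, X_tr, y_tr, X_te, y_te, rmsecv=rmsecv_curve[a_opt - 1],
            model_name="PLS", test_ids=[fm.sample_ids[i] for i in te])

    with _stage("fit_en_pls", timings):
        if config.lambda1 is not None and config.lambda2 is not None:
            lam1, lam2 = config.lambda1, config.lambda2
        else:
            l1_grid, l2_grid = config.lambda1_grid, config.lambda2_grid
            if l1_grid is None or l2_grid is None:
                auto1, auto2 = default_lambda_grids(X_tr, y_tr, config.n_lambda1)
                l1_grid = l1_grid or auto1
                l2_grid = l2_grid or auto2
            lam1, lam2, _ = tune_en(X_tr, y_tr, l1_grid, l2_grid,
                                    folds=config.tune_folds,
                                    max_components=config.max_components)
        en = ENPLSRegressor(lambda1=lam1, lambda2=lam2,
                            max_components=config.max_components).fit(X_tr, y_tr)
        en_rmsecv = float(en.rmsecv_[en.n_components_ - 1])
        en_report = validation_report(
            en, X_tr, y_tr, X_te, y_te, rmsecv=en_rmsecv,
            model_name="EN-PLS", test_ids=[fm.sample_ids[i] for i in te])

    with _stage("perturbation", timings):
        base = mean_fingerprint(fm)
        regions = select_regions_combined(pls, en, fm.n_points, config.n_pos,
                                          config.n_neg, config.n_zero,
                                          min_width=config.min_region_width)
        perturb = perturbation_table({"PLS": pls, "EN-PLS": en}, base, regions,
                                     scales=config.scales, X=fm, y=y)

    bundle = RunBundle(matrix=fm, activities=activities,
                       similarity_reports=sim_reports, pca=pca, ks_split=split,
                       pls_model=pls, pls_report=pls_report, en_model=en,
                       en_report=en_report, regions=regions,
                       perturbations=perturb, config=config, timings=timings)
    if config.output_dir is not None:
        _write_bundle(bundle, truth)
    return bundle


def _model_json(model, grid) -> dict:
    core = getattr(model, "pls_", model)
    subset = core.variable_subset
    return {"n_components": int(core.n_components_),
            "coef": core.coef_, "intercept": core.intercept_,
            "x_mean": core.x_mean_, "y_mean": core.y_mean_,
            "variable_subset": None if subset is None else np.asarray(subset),
            "scaling": "centering-only" if not core.scale else "autoscaled",
            "grid_hash": int(abs(hash(tuple(np.round(grid, 9)))) % 2**63)}


def _write_bundle(b: RunBundle, truth=None) -> None:
    out = Path(b.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_matrix(b.matrix, out / "matrix.csv", out / "grid.txt")
    io.write_activities(b.activities, out / "activities.csv")
    io.write_json([{"batch": r.group_label, "mean": r.mean, "sd": r.sd,
                    "min": r.min, "max": r.max,
                    "si": r.si, "sample_ids": r.sample_ids}
                   for r in b.similarity_reports], out / "similarity.json")
    io.write_json(b.ks_split.to_dict(), out / "ks_split.json")
    io.write_json(_model_json(b.pls_model, b.matrix.grid), out / "pls_model.json")
    io.write_json(_model_json(b.en_model, b.matrix.grid), out / "enpls_model.json")
    io.write_json(b.pls_report.to_dict(), out / "pls_report.json")
    io.write_json(b.en_report.to_dict(), out / "enpls_report.json")
    io.write_json([asdict(r) for r in b.regions], out / "regions.json")
    b.perturbations.to_csv(out / "perturbation_table.csv", index=False)
    cfg = asdict(b.config)
    if b.config.generation is not None:
        cfg["generation"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                             for k, v in asdict(b.config.generation).items()}
    io.write_json({"config": cfg, "timings": b.timings}, out / "run_config.json")
    if truth is not None:
        io.write_json({"true_beta": truth.true_beta,
                       "active_support": truth.active_support,
                       "seed": truth.seed}, out / "truth.json")
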