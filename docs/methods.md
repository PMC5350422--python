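# Methods

## The modelling problem

`qpar` implements quantitative pattern-activity relationship (QPAR)
modelling: predicting a bioactivity of a complex mixture from its whole
chromatographic fingerprint rather than from a handful of marker compounds.
The motivating setting is a panel of herbal extracts (three production
batches, twenty-four extracts each, prepared under varying reflux time and
solvent volume) whose HPLC-DAD chromatograms are regressed against the
percent change of CD80 surface expression they induce on THP-1 cells.  The
design matrix X is the aligned samples x retention-time-points intensity
matrix; the response y is the per-extract activity, conventionally reported
on a `100 + delta%` scale (100 = untreated control).

Two models are fitted and compared on one common train/test split:

* **PLS** — single-response partial least squares on the full grid, fitted
  by NIPALS deflation; the component count is chosen by leave-one-out
  cross-validation (minimum RMSECV, ties to the smaller count).
* **EN-PLS** — elastic-net variable selection followed by a PLS refit on
  the selected retention-time points only.  The elastic net minimises
  `||y - Xb||^2 + lambda1*||b||_1 + lambda2*||b||^2` by cyclic coordinate
  descent; only its support is consumed, so the "naive" (unrescaled)
  solution is used — the support is invariant to the (1+lambda2) rescaling.

## Synthetic panel generator

No raw chromatograms are distributed with the package; the generator
produces panels with the statistical structure the analysis assumes, plus a
recorded ground truth, so every stage is testable by parameter recovery.

A shared `PeakLibrary` (default: 40 Gaussian peaks, 0–70 min, 0.05 min
grid = 1401 points) defines the mixture.  Per batch, each peak's abundance
is scaled by a log-normal multiplier (`batch_effect_sd = 0.25`); per
sample, by a further log-normal multiplier (`within_batch_sd = 0.2`).  Each
sample additionally gets a global retention-time shift
(`rt_jitter_sd = 0.02` min), a smooth positive baseline
(`baseline_amplitude = 0.05` AU) and white detector noise
(`noise_sd = 0.01` AU).  Activities are exactly
`y = 100 + X @ beta_true + eps`, `eps ~ N(0, 4)` activity %, where
`beta_true` is sparse: six active peak regions (center ± 1.5 widths) with
constant within-region coefficients of alternating sign, normalised by
region size and peak height so regions contribute comparably and roughly
cancel in expectation.  These defaults were fixed once so that (a)
within-batch cosine similarity indices stay above 85% (the consistency
regime of real batch panels), (b) per-batch activity SDs land near 10–15
activity % with batch-mean shifts of the order tens of %, echoing the
reference panel's summary statistics.

What the generator does **not** emulate: peak tailing and co-elution shape
distortions, multi-wavelength DAD structure, heteroscedastic detector
noise, nonlinear concentration-activity effects, and matrix effects between
compounds.  Passing recovery tests therefore show the estimators work when
the sparse-linear model holds, not that real extract panels satisfy it.

## Preprocessing

The baseline is estimated by asymmetric least squares (Whittaker smoother
with asymmetric weights; knobs `smoothness = 1e5`, `asymmetry = 0.01`, 10
reweighting iterations) and subtracted.  Alignment applies one global
integer-step lateral shift per sample (±0.5 min window) maximising the
inner product with the panel-median reference trace; piecewise warping is
deliberately out of scope.  Traces are then linearly interpolated onto the
common grid; extrapolation is an error.  Intensities are **not**
area-normalised by default because the perturbation analysis reads absolute
region intensity as compound quantity; normalisation is an opt-in flag.
Every step and its parameters are appended to the matrix's preprocessing
log.

## Similarity and homogeneity

The similarity index of a fingerprint against its batch's pointwise-median
reference is the congruence (cosine) coefficient x 100 — the common choice
for chromatographic fingerprints, landing in the high-80s-to-high-90s range
for consistent batches; a Pearson variant is available.  Summary SDs use
the sample (n−1) convention.  PCA on the mean-centred matrix (full SVD)
provides the score-space view of batch structure.

## Splitting

Kennard–Stone max–min selection on Euclidean distances over the
preprocessed matrix; two-thirds training (48 of 72, rounding half up).
Ties break to the lowest original index so the split is reproducible and
permutation-robust.  The same split feeds both models.

## Numerical choices

* PLS: the NIPALS weight vector is computed directly as the normalised
  deflated covariance `X_d' y_d` (exact for a single response), so fitting
  is deterministic with no iterative inner loop.  Variables are centred but
  not autoscaled (all share one unit; coefficients stay on the raw
  intensity scale); autoscaling is a flag.  Component cap
  `min(15, n_train - 2)`.
* LOO-CV optimum: smallest component count whose RMSECV ties the minimum,
  where "tie" tolerates numerical noise (relative 1e-9 plus 1e-12 of the
  response RMS) — without this, machine-epsilon differences between exactly
  interpolating models defeat the parsimony rule.
* Elastic net: cyclic coordinate descent in fixed ascending index order on
  the Gram form, with active-set iterations between full sweeps and warm
  starts where available; `tol = 1e-6` on the maximum coordinate change,
  `max_iter = 1e4` sweeps; non-convergence is flagged, not raised.  The
  all-zero threshold is `lambda1_max = 2*max_j |x_j'(y - ybar)|`.
* Hyperparameters: `tune_en` does deterministic k-fold CV (contiguous
  blocks of the KS-ordered training rows) over
  `lambda2 in {0.01, 0.1, 1, 10}` and a 20-point geometric `lambda1` grid
  spanning three decades below `lambda1_max`; ties prefer the sparser
  model.  The multi-seed recovery experiments instead fix
  `lambda1 = 0.015 * lambda1_max`, `lambda2 = 10`: the strong ridge term
  exercises the grouping effect so whole correlated peak regions enter the
  support together, and a fixed pair keeps the experiment about recovery
  rather than tuning.
* Degenerate inputs: zero-variance y, empty elastic-net support, component
  counts beyond `min(n-1, p)`, and sub-10-point baselines all raise
  `ValueError` with actionable messages.

## Validation metrics

R² (train and test) is the squared Pearson correlation of predicted vs
experimental activities; RMSET/RMSECV/RMSEP are root-mean-squared errors of
fit, leave-one-out CV, and external prediction; q² = 1 − Σ(y_pred −
y_act)²/Σ(y_act − ȳ_act)².  q² and test R² are different quantities (R² is
blind to bias and scale) and both are reported.  Per-sample REP is the
plain difference predicted − actual, and PRESS its square — the convention
the packaged reference test-set table actually follows; a relative
(ratio-to-actual) REP variant sits behind a flag.  The invariant
`rmsep² * n = Σ press` holds exactly on every report.

## Region perturbation

Contiguous runs of same-sign model coefficients (minimum width 5 grid
points) are ranked by |aggregate coefficient|; the reported per-region
"coefficient" is that aggregate, the quantity that actually propagates
into predictions.  Zero-category regions require all coefficients within
`1e-8 * max|coef|` of zero — only the EN-PLS vector (exactly zero outside
its support) has such runs, so the combined selector takes
positive/negative regions from the dense PLS vector and zero regions from
EN-PLS.  Perturbation multiplies a region of the panel-mean fingerprint by
`1 + s` (s = 0.5, 1.0, 2.0 by default) and re-predicts; by model affinity
the response is exactly `s * Σ_region coef_j * base_j`, so deltas are
dose-linear, additive over disjoint regions, and exactly zero for
zero-coefficient regions — the invariants the tests assert.

## Problem sizes

Unit tests run mostly on compact panels (3x8 samples, 401-point grids);
the study-scale checks use 3x24 = 72 samples on the 1401-point default
grid.  The multi-seed recovery experiment uses 20 independent panels at
that scale, chosen as the smallest replication giving stable means for the
recovery and RMSEP-ordering comparisons.

## Known limitations

* The elastic net forms the p x p Gram matrix; beyond ~5000 variables a
  residual-update formulation would be preferable.
* Alignment is a single global shift; panels with differential drift along
  the gradient need warping methods out of scope here.
* The baseline smoother's boundary influence decays over a few hundred
  points, so shift-equivariance holds only away from the trace edges.
* Support recovery is reported against a ground truth in which active
  variables are strongly collinear; "recovered" means membership in the
  elastic-net support, not coefficient-magnitude fidelity.
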