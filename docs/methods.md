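# Methods

This note documents the models, algorithms, defaults and design choices in
`hyperssc`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Reflectance calibration and spectral extraction

Raw digital numbers are converted to relative reflectance by the standard
black/white correction `R = (I_r − I_d)/(I_w − I_d)`. Reference frames may be
full per-pixel/per-band cubes (default, one set per acquisition session) or
per-band vectors of spatially averaged references; every used location must
satisfy `white − dark > 0`, and violations are reported by index rather than
silently clipped.

Cubes are `(lines, samples, bands)` row-major arrays with 0-based, half-open
ROIs. The ENVI dialect supported is deliberately narrow — `key = value` text
headers, interleaves BIL/BSQ/BIP, data types 4 (float32) and 12 (uint16) —
and anything else is rejected explicitly rather than guessed at.

Band cropping keeps the closed interval [950, 1675] nm by default, discarding
the noisy spectral edges. ROI placement is a user input (the equatorial
position cannot be inferred from a cube); `center_roi_on_mask` centers the
default 15×30 window on the fruit-mask centroid as a convenience. The ROI
mean is a plain per-band arithmetic average.

## 2. Synthetic data generator

The generator stands in for undeposited fruit data. It emulates, per stage:

* **SSC distribution** — truncated normal with the published mean/SD/min/max
  (immature 13.61 ± 2.55 in [9.1, 17.8]; white-mature 19.85 ± 1.35 in
  [16.0, 22.9]; crisp-mature 27.30 ± 3.96 in [18.8, 37.6]; full-mature
  35.94 ± 3.33 in [24.2, 44.0] %). The truncated normal is the simplest
  distribution consistent with all four printed statistics; truncation
  shifts the mean by at most ≈ 0.1 % for these parameters.
* **Spectra** — a flat 0.85 baseline minus Gaussian absorption dips at
  980/1224/1450 nm (the water/O–H features of fruit tissue), minus an
  SSC-proportional decline of 0.004 reflectance units per % SSC over the
  1377–1672 nm sensitive window (trapezoid-tapered just outside its edges so
  the sensitivity is strictly negative at every in-window band), plus i.i.d.
  Gaussian noise (sd 0.002 inside 950–1675 nm, 6× outside, mimicking detector
  roll-off). 256 bands over 900–1700 nm — a typical InGaAs line-scan grid;
  the true instrument's band count is not public, so this is a declared
  default, not an inference.
* **Cubes** — an elliptical fruit on a dark (0.05 reflectance) background;
  the per-pixel SSC field is smoothed white noise plus a linear gradient
  (guaranteeing the asymmetric within-fruit variation seen in real fruit),
  rescaled to an exact masked mean and a configurable sd (default 1.5 %).
  Raw DNs encode reflectance as `R·(white − dark) + dark` with constant
  reference levels 0.05/0.90, so the calibration path is exercised and
  exactly invertible (to float32 precision).

**What passing tests do and do not show.** The generator's only
spectrum–SSC link is linear and its noise is i.i.d.; real fruit adds
scattering, surface geometry, biological covariates and instrument drift.
Consequently the pipeline's accuracy on synthetic data (RMSEP ≈ 0.1 %,
RPD ≫ 10) is an upper bound on what the same code would achieve on real
fruit (published real-data figures are RPD ≈ 7); the tests validate the
*mechanics* — calibration, splitting, selection, optimization, mapping — not
field-level accuracy.

## 3. Splitting workflow

Per stage: a seeded uniform draw without replacement reserves 30 samples for
independent verification; Kennard–Stone (KS) on the remaining 120 spectra
selects the 90 calibration samples (KS-ranked prefix), leaving 30 for
prediction. KS uses Euclidean distance on the cropped reflectance spectra
without autoscaling (standard usage; configurable by preprocessing the
matrix), and ties break to the lowest row index so the output is fully
deterministic. Applying KS per stage, then pooling, reproduces the
90/30/30-per-stage design.

Because KS picks extremes first, the calibration set brackets the prediction
set. The per-band min/max hull containment is exact for noiseless spectra;
under i.i.d. band noise it holds only approximately (noise extremes can land
in the prediction set), so the test suite asserts the exact version on
noiseless data and SSC-range containment on noisy data.

## 4. SPA wavelength selection

Columns are mean-centered (no autoscaling). A chain starting at column *s*
repeatedly appends the column with maximal residual norm after projection
onto the orthogonal complement of the selected span; numerically dependent
columns (residual norm ≤ 1e-10 relative) are never selected and exhausted
chains truncate with a warning. Chains are enumerated from **every** start
column for every size in `[n_min, n_max]` (defaults 3–24) and scored by the
validation RMSE of an OLS model with intercept; the validation set is the
prediction set, mirroring the original workflow (an internal-CV alternative
is a one-line change of inputs). Ties prefer the smaller subset, then the
lower start index. The winning chain's selection order is reported as
descending importance — the ordering semantics of the published 24-wavelength
list are not stated, so chain order is the documented assumption. No
backward-elimination refinement is applied.

## 5. LS-SVM and hyperparameter search

Training solves the dense `(n+1)` KKT system; a relative residual above
1e-8 raises rather than returning silently degraded coefficients. The RBF
convention is `exp(−d²/σ²)` — no factor of 2 — following the classic LS-SVM
toolbox parameterization; σ² values are therefore not interchangeable with
conventions that include the 2.

Grid search minimizes leave-one-out CV MSE over a 20×20 log-spaced grid on
[1, 5000]² (the stated search range; resolution is this package's choice).
LOO residuals use the closed-form identity `eᵢ = αᵢ/(A⁻¹)ᵢᵢ`, which is
algebraically identical to refitting *n* times; the explicit refit loop is
retained as `loo_mse_naive` and the equality is asserted in tests. Ties
prefer smaller γ, then smaller σ².

A documented inconsistency in the source results: the stated search range is
[1, 5000] for both parameters, yet the reported optima include γ ≈ 1.2×10⁴
and 5.0×10⁴. The defaults here keep the stated range; `WIDE_BOUNDS` extends
γ to 10⁵ for users who want the near-interpolation regime. On the synthetic
data the grid optimum indeed lands on the γ = 5000 boundary, consistent with
that tension.

## 6. Artificial bee colony

Control parameters follow the study settings: swarm 60, SN = 30 food
sources, limit 120, 30 iterations, 2 dimensions, 10 independent runs. The
neighbor rule is the classic single-coordinate Karaboga move
`v_ij = x_ij + φ(x_ij − x_kj)`, φ ~ U(−1, 1), clamped to bounds (the original
description cites Karaboga without writing the rule). Onlookers cycle
through the sources accepting source *i* with probability
`Pᵢ = 0.9·fitᵢ/max(fit) + 0.1` (the formula is not normalized, so it is used
as an acceptance probability, its standard usage); probabilities are fixed
during each onlooker phase. All sources whose trial counter exceeds the
limit are re-randomized by scouts each iteration. Initialization is uniform
(not log-uniform) in the bounds, matching standard ABC. Positions are
memoized on a 12-significant-digit key, and the cache is shared across the
10 runs (the objective is deterministic in the position), keeping repeated
runs cheap.

The objective is the prediction-set MSE of the LS-SVM trained on the
calibration set — faithfully reproducing the original design, which lets the
prediction set leak into model selection. The pipeline exposes
`abc_on_holdout=True` to tune on the verification set instead; the default
keeps the leaky-but-faithful behavior and the verification-set metrics in
the pipeline report provide the honest generalization check.

## 7. Evaluation metrics

R² is the squared Pearson correlation (the definition under which the
published R²/RMSEP/RPD triples are internally consistent); the
`1 − SS_res/SS_tot` variant is available via a flag. RPD divides the
reference set's n−1 standard deviation by the RMSE — this convention
reproduces all nine published SD/RMSEP → RPD rows to 2 decimal places, which
the acceptance suite checks. Bias is predicted-minus-reference; slope
regresses predicted on reference by default (direction flag provided, since
the published tables do not state it). The stage growth rate is
`(mean_next − mean_prev)/mean_prev × 100`.

## 8. Chemical imaging

Segmentation thresholds the band-averaged reflectance (default 0.2, between
the 0.05 synthetic background and ≥ 0.3 fruit tissue) and keeps the largest
connected component. The mask is applied *before* prediction — background
pixels are never fed to the model and carry NaN in the output array.
Requested wavelengths are matched to the nearest cube band within ±2 nm
(selection grids and cube grids rarely align exactly). Maps render with the
blue-to-red `jet` colormap pinned to 0–60 % SSC so maps of different stages
are directly comparable; out-of-range predictions are clipped in display
only, never in the numeric array, and encoder settings are fixed so
identical maps render byte-identically.

## 9. Problem sizes and numerical choices

Defaults throughout are the study-scale settings: 150 samples/stage
(600 total), 256 bands, 20×20 hyperparameter grid, 10 ABC runs of 30
iterations. Unit tests use scaled-down generators (64 bands, 20–30
samples/stage) where the property under test does not depend on scale; the
end-to-end acceptance checks run at full scale. Degenerate inputs
(identical KS rows, rank-deficient SPA designs, singular KKT systems,
all-background frames, empty crops) raise descriptive errors or warn and
truncate, as documented per function. All stochastic components accept an
integer seed and are reproducible bit-for-bit.

## 10. Known limitations

* The synthetic linear SSC–reflectance link makes the regression problem
  easier than real fruit; see §2.
* Only the plain ENVI dialect described above is read; BIP-interleaved
  uint16 with byte order 1 is the most exotic accepted combination.
* The SPA importance ordering and the published ordering may differ (§4).
* ABC's objective leaks the prediction set by design (§6); use
  `abc_on_holdout=True` for honest tuning.
* Single-fruit scenes only; no multi-fruit segmentation or registration.
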