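# Methods

## The analysis model

The classifier operates on per-cell reflectance spectra sampled at 26
equidistant wavelengths λ₁…λ₂₆ (500–1000 nm, 20 nm spacing).  For one
analysis unit (a donor, or the pooled cohort) with observations
x₁…x_n ∈ ℝ²⁶:

* **PCA** is performed on the mean-centered, *unscaled* matrix
  (covariance PCA): all bands share units, and standardizing would
  inflate noise-only bands.  Components come from the SVD of the
  centered matrix; explained variances are singular values squared over
  (n − 1).  Component signs are fixed by the convention that the
  largest-magnitude loading coefficient is positive, so results do not
  depend on the SVD implementation.
* **The separating component** is the component j ≤ 5 maximizing the
  absolute two-sample t statistic of its scores between the classes,
  oriented so the M1 mean score is positive.  This replaces a visual
  reading of score plots with a deterministic rule; |t| < 2 is flagged
  low-confidence.  A **half-plane classifier** labels a cell M1 iff its
  oriented score is positive (score 0 → M2) and its error rate is
  reported as a model-free baseline.
* **Band selection** takes the 14 wavelengths with largest |loading| on
  the separating component (ties toward the lower wavelength; an optional
  minimum-spacing constraint exists but is off by default).  Again a
  deterministic surrogate for a manual choice from a loading plot.
* **LDA** is the classic two-class rule: weight vector
  w = (S_pooled + εI)⁻¹ (m₁ − m₂), threshold w·(m₁ + m₂)/2 (equal
  priors, justified by the balanced 30 + 30 design).  The ridge ε
  defaults to 10⁻⁶ × mean diagonal of S_pooled; smooth spectra can make
  neighbouring bands near-collinear even though 54 training observations
  × 14 features is formally well-posed.  Exact ties at the threshold
  predict M2 (arbitrary but fixed).
* **Cross-validation** is stratified 10-fold with a seeded fold
  assignment (each class shuffled and dealt round-robin, so per-class
  counts differ by at most one across folds).  The confusion matrix is
  accumulated over the 10 test folds and accuracy computed from the
  summed matrix.

Donors are analysed individually first; the pooled analysis concatenates
all donors and selects bands once on the pooled PCA.

## Extraction from image cubes

A cell's spectrum is the per-band arithmetic mean over a circular disk
(pixel centers within diameter/2 of the ROI center, ≤ comparison —
deterministic and symmetric under quarter turns).  Coordinates are
0-based, x = column, y = row, pixel-center convention, in every file
format.  At the reference geometry (1 × 1 mm² field, 512 × 512 px) the
12-pixel ROI diameter corresponds to 23.4 µm.

Background is the mean spectrum over all pixels farther than
radius + 3 px from every ROI center (a per-cell annulus strategy is
available behind a config switch; the global mean has lower variance).
Background subtraction happens first, then Savitzky–Golay smoothing on
the native wavelength grid, then linear-interpolation resampling to the
26-λ analysis grid (no extrapolation; native samples coinciding with
targets are copied exactly).

The smoother defaults to window 7, order 3.  Endpoints are handled by
evaluating the polynomial fitted to the one-sided edge window, so
polynomials up to the filter order — constants in particular — are exact
fixed points.  The window was chosen so that the narrowest features the
generator produces (σ ≈ 16 nm) are attenuated by well under 1% on either
native grid (8 nm steps for the reduced test geometry, 1.6 nm for the
full geometry); window 11 on the coarse grid already distorts them by
~2%.

## The synthetic generator

No real cubes or spectra ship with the package, so the generator
reproduces the *statistical* structure the analysis relies on rather
than any optical physics (no scattering or interference model, no
z-sectioning):

* the mean spectrum of class c in donor d is
  `baseline(λ) + Σ_k (A_k + δ_{d,k}) g_k(λ) ± effect(λ)`,
  with a linear baseline, Gaussian bumps g_k, donor amplitude offsets
  δ_{d,k} ~ N(0, donor_sd²), and a Gaussian-mixture class effect added
  with opposite sign for M1 and M2 — so the pooled mean is
  class-independent and a zero-amplitude effect makes the classes
  distributionally identical;
* each cell scales its mean by exp(N(0, global_scale_sd²)) — a log-normal
  brightness factor standing in for focus/coupling variation — and adds
  independent N(0, noise_sd²) per band;
* rendered scenes place each cell as a filled disk (rejection sampling,
  center-to-center distance ≥ 2 diameters, hard failure after 10 000
  attempts rather than silent overlap) on a uniform dim background, and
  return ground-truth ROIs for round-trip testing.  Disk pixels carry
  the cell's spectrum; since the background offset is common to all
  cells of a scene, the extracted (background-subtracted) table differs
  from the source table by a constant spectrum only, which cancels in
  the centered PCA and in the LDA decision rule — cube-mode and
  table-mode analyses agree exactly.

Default geometry for desk-scale runs is a 128 px field at the same pixel
pitch (0.25 mm), ~8 nm native spectral step and 8 cells per class;
the full 512 px / 1.6 nm / 30-cells-per-class geometry is available via
`study_geometry()`.

### Calibrated defaults

The shipped `DEFAULT_MODEL` was fixed by `calibrate_defaults`, a grid
search over the class-effect amplitude scale and the brightness-factor
spread, subject to the performance windows the imaging study reports:
mean per-donor 10-fold CV accuracy ≥ 98%, mean half-plane error ≤ 10%,
separating-component variance fraction within 8–22%, pooled (4-donor)
accuracy ≥ 90% and strictly below the per-donor mean.  The result:

* baseline 0.45 with a slight negative slope; broad bumps at 600 and
  770 nm (σ 45/60 nm, amplitudes 0.12/0.08);
* narrow bumps at 560, 680 and 840 nm (σ 16–18 nm, amplitudes
  0.03–0.04) **co-located with the class-effect features** — donor
  offsets on their amplitudes put donor-to-donor variability exactly
  along the discriminative directions.  Within one donor the offset is a
  constant absorbed by centering, so per-donor analyses are untouched,
  but pooled LDA must treat those directions as noise, reproducing the
  observed pooled-accuracy penalty;
* class effect ±(0.024, −0.018, 0.0156) at those centers;
* global_scale_sd 0.035 (sets the dominant, non-discriminative PC1 and
  dilutes the separating component's variance share into the 8–22%
  window), donor_sd 0.03, noise_sd 0.02 per native band.

At these settings, over 20 seeds: per-donor accuracy ≈ 99.5%, half-plane
error ≈ 1–2%, separating component always PC2 with fraction ≈ 14%
(per-seed range ≈ 9–19%), pooled accuracy ≈ 94–95% against a per-donor
mean of ≈ 99.5%.  Per-seed pooled accuracy is noisy (sd ≈ 0.05) because
only 4 donor draws enter each replicate.

## What passing tests do and do not show

The generator makes the pipeline's assumptions true by construction:
Gaussian class features at fixed centers, donor effects purely additive
on feature amplitudes, band-independent noise, a single multiplicative
brightness factor.  Real reflectance spectra have correlated noise,
focus-dependent spectral shape, imperfect ROI centering on nuclei and
donor effects of unknown geometry.  Passing the calibration windows
therefore shows that the *implementation* reproduces the reported
behaviour under the assumed statistical structure — it is not evidence
about real macrophage data.  Conversely the oracle tests (PCA vs.
eigendecomposition, LDA vs. explicit solve, Savitzky–Golay polynomial
reproduction, brute-force disk masks, fold conservation) are
structure-independent.

## Numerical and design choices

* Covariance (not correlation) PCA; unit-norm loadings;
  largest-|coefficient|-positive sign convention.
* Separating-component search limited to the first 5 PCs (configurable);
  ties in |t| and in |loading| broken toward lower index / lower
  wavelength.
* Linear interpolation for resampling (nearest-channel would differ
  negligibly at 1.6 nm native sampling but interpolation is robust to
  coarser grids); no extrapolation ever.
* Background subtraction before smoothing (the natural order for an
  additive background estimated from the same cube).
* Folds, cohorts and scenes all take explicit integer seeds;
  identical seeds give bit-identical tables, cubes and reports
  (timestamps aside).
* Degenerate inputs fail loudly: single-class tables, classes smaller
  than k, singular stabilized covariances (with advice to raise the
  ridge), crowded scenes, ROIs touching the image border.

## Known limitations

* The generator's class effect is planted at three fixed centers; band
  recovery rates are measured against those plants, not against any
  externally validated wavelength set.
* ENVI I/O supports the band-sequential float32 layout this package
  writes, not the full format zoo.
* The half-plane and LDA stages assume exactly two classes; there is no
  multi-class extension, no QDA/shrinkage variants, and no probability
  calibration.
* ROI centers are inputs; there is no cell detection.
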