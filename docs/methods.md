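# Methods

## The analysis model

The package treats a hyperspectral Raman image as a cube `(row, col,
band)` on a shared strictly-ascending wavenumber axis, with an integer
mask marking cell regions (0 = substrate). The statistical model behind
the pipeline is:

* every pixel records cell (or substrate) Raman signal plus an additive
  per-image background (substrate glass, water, detector readout) plus
  noise;
* a cell's spectrum is the average of its pixels; after standardization
  it is a point in band space whose class-conditional distribution is
  approximately Gaussian in the leading principal subspace;
* the two states of interest (e.g. naive vs activated T cells) differ in
  the relative intensity of a handful of bands, so a linear discriminant
  on a low-dimensional PC projection separates them even though the raw
  dimension (hundreds of bands) exceeds the cell count.

### Preprocessing

Background: the mean spectrum of the `n = 25` zero-mask pixels with the
greatest Euclidean distance to the nearest cell pixel (distance
transform, row-major tie-break — "far from the cells" made precise and
deterministic). One estimate per image; subtracted from every pixel.
If fewer than 25 background pixels exist, all are used and a warning is
logged.

SNV: per spectrum, subtract the mean and divide by the *population*
(ddof = 0) standard deviation; the divisor convention is irrelevant
downstream (it cancels in PCA directions) but is fixed for
reproducibility. Constant spectra are rejected with the cell id in the
error.

Crop: wavenumber ranges are half-open `[lo, hi)` so adjacent crops tile
without overlap. The fingerprint default is 600–1800 cm⁻¹; the bounds
are a package choice, as is keeping the axis fixed per dataset (no
resampling between instruments in v1).

### NIPALS PCA

Components are extracted sequentially: initialize the score vector with
the maximal-variance column of the residual, alternate `p ← Rᵀt/(tᵀt)`
(normalized) and `t ← Rp`, stop when the relative L2 change of `t` drops
below `tol = 1e-8` (cap `max_iter = 500`; hitting the cap keeps the
component, flags it, and logs a warning — on noise-floor components with
near-degenerate eigenvalues the direction is arbitrary anyway), then
deflate `R ← R − tpᵀ`. The matrix is column-mean-centered first:
row-standardization (SNV) does not center columns, and PCA of uncentered
data conflates the grand mean with PC 1. Projection of new spectra
subtracts the stored column mean. Signs are fixed (largest-|·| loading
element positive) so results are deterministic; `k = 7` by default.

### Discriminant and QDA probabilities

F1 is `S_w⁻¹(μ₂ − μ₁)` normalized to unit length, with the sign chosen
so the second-listed class (by convention "activated") has the higher
mean projection; the decision threshold is the midpoint of the projected
class means (equal-cost rule; exact ties go to the higher-prior class,
then the first-listed). Per-class Gaussians use sample means,
ddof-1 covariances with shrinkage `Σ ← (1−ε)Σ + ε·tr(Σ)/k·I`
(`ε = 1e-3`), needed when a class size approaches `k`, and empirical
priors. "Probability" maps to `log prior + log N(t; μ_c, Σ_c)`; class
posteriors are exposed via log-sum-exp normalization.

### Leave-one-out error

For each held-out cell the *entire* post-preprocessing chain is refitted
(NIPALS on the remaining rows, then the discriminant), so no information
about the held-out cell leaks into the PC space; `mode="fixed"` fits the
PCA once for speed at the cost of that guarantee. The estimate is
deterministic for a fixed dataset.

Two statistical properties of LOO worth knowing when reading results:
at chance-level separation the fold predictions are strongly correlated
and slightly anti-correlated with the held-out point, so the null error
concentrates near 50% but has a heavy upper tail (observed up to ~60%
when the class sample means nearly coincide); and training-set LDA
scores are systematically inflated relative to held-out projections of
the same distribution (optimism), which is why trajectory endpoints are
compared against held-out draws, not training scores.

### Frozen state space and time courses

Supervisor data (the two endpoint classes) define the PC loadings,
column mean, F1 axis, QDA parameters and the preprocessing provenance
(crop bounds, axis) once; the bundle is immutable afterwards.
Stage datasets are standardized with the same SNV rule, projected by
inner products only, and summarized per timepoint as mean/sd/n of the
LDA scores (sd of a single observation is reported as 0 to keep tables
total).

### State maps

Every pixel (including substrate) is cropped to the bundle's range,
SNV-standardized, projected, and scored by the two class
log-probabilities. Each class's value is mapped linearly from a clip
range `[lo, hi]` to 0–255: the first-listed class into the synchronized
blue and green channels, the second into red; values outside the range
clip, and zero-variance (flat) pixels render black. The default clip
range per class is the 1st–99th percentile of that class's
log-probability over *all* supervisor cells: the upper edge then sits at
or below the class-mean density, so a pixel at the naive class mean
saturates blue, while cross-class values land near the bottom of the
scale. Band composites integrate intensity over `center ± 8 cm⁻¹`
windows (753/2956/2852 cm⁻¹ → blue/green/red by default) with
per-channel min–max scaling; a constant channel renders as zeros.

## The synthetic generator

`raman_cellstate.synth` emulates what the pipeline assumes about real
data:

* **Line shapes** — Lorentzian bands (standard for Raman), HWHM 6–11
  cm⁻¹ for cellular bands, amplitudes relative to phenylalanine
  (1004 cm⁻¹ = 1.0). The naive and activated profiles share common
  bands and differ at 1089, 1332, 1375, 1483 cm⁻¹ and in the 753 cm⁻¹
  cytochrome c amplitude (higher when activated). A `separation` knob
  scales the between-class amplitude contrast around the pair means
  (1 = default profiles, 0 = identical classes).
* **Axis** — 600–3100 cm⁻¹ at 2 cm⁻¹ spacing; the silent region
  1800–2700 cm⁻¹ stays in the axis but holds no bands.
* **Baseline and substrate** — a low-order polynomial baseline under
  cellular spectra; non-cell pixels draw from a silica-substrate profile
  (broad glass bands, a weak high-wavenumber water shoulder). Cell
  pixels carry substrate *plus* cellular signal — the substrate reaches
  the detector through the focal volume everywhere, which is exactly why
  the pipeline subtracts a per-image background.
* **Noise** — i.i.d. per-band Gaussian, sd 0.05 by default (SNR ≈ 20–25
  on the strongest bands, typical of minutes-long single-cell
  acquisitions).
* **Scenes** — disjoint disk-shaped cells (v1 rejects overlaps) labeled
  1..N in listed order on a rectangular substrate.
* **Time courses** — stage means are convex mixtures
  `(1−α)·naive + α·activated` with `α = t/24` by default over 0, 2, 6,
  12, 24 h; linearity in `α` is the generator's model of gradual
  activation.

Everything is a pure function of (specification, seed).

What the generator does **not** emulate: photon shot noise and detector
etaloning, cosmic rays, cell morphology beyond disks, band-correlated
biological variability (covariance structure beyond the class mean
shift), wavenumber miscalibration between instruments, and apoptotic
or otherwise aberrant cells. Passing tests therefore demonstrate the
correctness and calibration of the *analysis*, not that real cells of
any particular type are separable; real-data performance depends on
effect sizes the generator only parallels.

## Validation design and problem sizes

The validation suite (tests/test_acceptance.py, scripts/acceptance.py)
runs at desk scale, sized to finish in about a minute on one CPU:

* NIPALS vs eigendecomposition: 50 random 20×50 matrices, k = 5,
  |cos| > 0.9999 per loading and variance fractions to 1e-6 (the check
  passes `max_iter=4000` so near-degenerate noise eigenpairs converge to
  oracle precision).
* Fisher recovery: shared Σ = [[1.5, 0.6], [0.6, 0.8]],
  Δμ = [1.5, 1.0] (Mahalanobis ≈ 1.34), n = 2000/class, |cos| > 0.99
  against `Σ⁻¹Δμ`.
* LOO calibration: 1-D equal-variance Gaussians at Mahalanobis 0/1/2/4,
  n = 400/class, k = 1, against `Φ(−Δ/2)` with 99% binomial intervals,
  monotone across the sweep.
* End-to-end imaging: one disk cell per 20×20 image — one cell per
  image keeps cells independent (cells sharing an image share its
  background estimate; with single-class images that batch effect would
  confound with the class label and leak into LOO). Moderate contrast
  (separation 0.5) at the 96+60 study scale must give ≤ 5% LOO error;
  the identical-class null uses a balanced 78+78 design, where 50% is
  the correct chance reference (with 96/60 imbalance the equal-cost
  midpoint threshold degenerates to majority voting under the null).
* Trajectory: stages α ∈ {0, 2/24, 1/4, 1/2, 1}, 40 cells each,
  strictly increasing means, affine in α with R² > 0.95.
* Colorization contract and CLI rerun determinism as described above.

## Known limitations

* Two classes only; no multi-class discriminant, ROC analysis, or
  automatic choice of `k`.
* No cosmic-ray despiking, baseline fitting, or axis resampling — inputs
  are assumed despiked and on one calibration.
* Cell segmentation and viability judgment are upstream: cells are
  whatever the mask says.
* Hyperstack HDF5/NPZ containers store arrays at their native dtype
  (float64 for synthetic cubes) so round trips are lossless; convert to
  float32 externally if file size matters.
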