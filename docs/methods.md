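# Methods

This note documents the models, conventions and numerical choices behind
`ddcqa`, in the order data flows through the package.

## Phantom and module model

A DDC module is an 80 mm diameter, 40 mm deep epoxy cylinder holding 30
cylindrical rods: one per combination of diameter
s ∈ {3, 4, 5, 6, 8, 9} mm and nominal contrast
ΔHU ∈ {16, 32, 48, 64, 80} above the epoxy base. Two material variants
exist: iodine-doped rods (NaI solution; contrast depends on tube voltage)
and sucrose-doped "native" rods (energy-independent). The bundled
`materials.csv` table records the weight-percent recipes per target
contrast; rows sum to 100 % and the additive fraction increases strictly
with contrast.

Rod placement is randomised so observers cannot infer unseen rods from a
regular pattern. `generate_layout` uses rejection sampling, placing rods
largest-first with uniform draws over the admissible disc, capped at 10⁵
attempts per rod. Two spacing parameters keep the module manufacturable and
the ROIs separable: a minimum inter-rod gap (default 1 mm) and an edge
margin to the barrel (default 3 mm). These defaults are package choices —
rods merely need to sit away from the phantom periphery, in a region of
similar SNR — and at this packing density (~21 % of the usable area)
rejection sampling never comes near the attempt cap. The eight fiducial
cutout angles and the barcode id are carried as metadata; registration keys
on the (unique) random rod pattern itself, so the milling geometry is not
rasterised.

Body phantom cross-sections are elliptical PMMA slices in five sizes,
summarised by the AAPM effective diameter √(AP·LAT). Labels round to the
nearest cm but are overridable, since e.g. the 24×32 cm slice (√ = 27.7 cm)
is conventionally labelled "27 cm".

## CT simulation

`simulate_volume` renders a module slice as:

1. **Noiseless HU map.** Epoxy base 60 HU (the measured CT number of the
   Translux D150 base at 120 kV; configurable), PMMA body 120 HU outside the
   barrel, plus each rod's rendered contrast. Rasterisation uses 4×4
   sub-pixel supersampling, so edge pixels carry partial-volume fractions
   and interior pixels are exact.
2. **kV response.** Iodine rod contrasts are scaled by a per-kV factor
   f(kV) with f(120) = 1; the default table {80: 1.30, 100: 1.15,
   120: 1.00, 140: 0.90} has the right qualitative shape (iodine contrast
   falls with kV) but is a placeholder — real factors are scanner-specific
   and must come from configuration. Native rods are never scaled.
3. **PSF.** An isotropic Gaussian blur of configurable FWHM (default
   0.8 mm) stands in for the reconstruction-kernel response. Kernel labels
   (I30f/B30f) are metadata only; kernel MTF differences are not modelled.
4. **Noise.** Stationary white Gaussian noise with
   σ = σ_ref √(CTDI_ref / CTDI_vol), the usual dose law. Defaults
   σ_ref = 10 HU at 10 mGy give ~10.5 HU at the 9 mGy reference protocol —
   a realistic abdominal level. Correlated/streak noise, beam hardening,
   scatter, AEC and projection/reconstruction physics are out of scope.

Ground truth carries per-rod interior masks (pixels at full coverage, so
their noise-free mean equals base + rendered contrast exactly), the rendered
contrasts, a background mask, and the true rigid transform. Default image
geometry is 192×192 px at 0.5 mm spacing (a 96 mm field around the module)
and 5 slices of 2 mm; identical seeds give bit-identical volumes.

## Simulated observer

The simulated observer clicks each rod independently with probability
logistic((d − threshold)/width), where d = ΔHU·s/σ is a Rose-criterion-style
detectability index. Defaults threshold = 25, width = 5 were chosen so that
at ~10 HU noise the resulting curves have realistic magnitude (9 mm rods
detected around 48 HU, 3 mm rods mostly missed below 80 HU). This is a
testing device with the right monotonicities — detection improves with
size, contrast and dose — not a validated human-observer model; spatial
uncertainty, search behaviour and inter-observer correlation are not
modelled. An optional Poisson false-click rate adds uniformly placed
background clicks.

Because Δ_min is clamped to the nominal contrast grid and censored at 80 HU
("–" when nothing of a size is seen), fits to simulated curves are only
informative while detection thresholds stay inside the 16–80 HU range.
The noise levels used in the trend tests (4, 7, 10 HU) were chosen inside
that range; at much higher noise the censoring flattens the fitted line and
the intercept is no longer comparable.

## ROI extraction and verification

* **Registration.** The pose is found by maximising normalised
  cross-correlation between the mean slice and a noiselessly rendered
  template: a coarse 2° rotation grid over ±180°, a fine 0.5° grid around
  the best coarse angle, parabolic sub-step interpolation, and integer
  translation via FFT cross-correlation (default search radius 10 mm). A
  best score below the configurable floor (0.2) raises a registration
  error — pure noise must fail, not return a pose. The default search is
  rotation + translation only; the phantom is assumed axially placed.
* **Erosion.** Each ROI's periphery is discarded by morphological erosion
  with a disc of 5 px diameter — the structuring element contains all
  offsets whose centre lies within 2.5 px (21 pixels; the 5×5 square minus
  its corners). An ROI whose eroded mask is empty is flagged
  "unmeasurable" rather than crashing the run. After this erosion every
  surviving rod pixel is at full coverage, which is what makes noise-free
  contrast recovery exact.
* **Background.** The "surrounding epoxy" region is not standardised
  anywhere, so the package fixes a convention: all pixels at least 2 mm
  inside the barrel and 2 mm clear of every rod footprint, then eroded like
  any other ROI. The choice is recorded in output metadata.
* **Slices.** By default one slice at each end of the stack is dropped
  (module-edge partial volume); any explicit slice list overrides this.
* **Statistics.** Mean, SD, min, max, median and pixel count are reported
  per slice and pooled; contrast is rod mean minus background mean.
* **Analytics.** Linearity is per-diameter OLS of measured on target
  contrast (ideal: slope 1, intercept 0); drift summarises per-date means
  against their grand mean ± SD; energy response compares per-kV slopes,
  separating the flat native response from the kV-ordered iodine response.

## DDC evaluation and fitting

Clicks are assigned to the rod whose footprint, dilated by 1 mm, contains
them (nearest centre on ties); anything else is a false click and never
enters a curve. Δ_min(s) is the minimum *nominal* contrast among detected
rods of diameter s — nominal, not measured, contrasts are the curve's
y-values — and MISSING where nothing of that size was seen. MISSING points
are excluded from all fits; no censoring imputation is applied.

The model uses the **natural logarithm** of the diameter. The choice is
verifiable from the reference estimates themselves: with α ≈ 116 HU and
β ≈ −32 HU per log unit, ln predicts ≈ 45 HU at s = 9 mm (consistent with
the observed 48 HU), whereas log₁₀ would predict ≈ 85 HU.

`fit_pooled` is OLS of Δ_min on ln s over all points of all curves.
`fit_observer_bias` solves the sum-to-zero constrained problem by a
separability identity: the map (α, β, αᵢ′, βᵢ′) → per-observer lines
(α+αᵢ′, β+βᵢ′) is a bijection under the constraints, so independent
per-observer OLS (pooling an observer's repeated curves, which share that
observer's offsets) followed by recombination — α, β as the means of the
per-observer intercepts/slopes, offsets as the differences — *is* the
constrained least-squares solution. The test suite verifies this against a
generic effects-coded solver to 1e−9, including unbalanced missingness.
An observer whose points span fewer than two distinct diameters has an
inestimable slope and is reported by name.

On the bundled five-observer reference set (120 kV, 9 mGy) this fit gives
α = 118.70, β = −33.75. Historical reports of this dataset quote slightly
different values (α = 115.71, β = −32.21, with differing per-observer
offsets); the exact solver variant behind those numbers is not documented,
so the package reports its own constrained-LS solution and the test suite
asserts agreement only to within 10 %.

## Bootstrap

Resamples are drawn **with replacement** (without replacement, k = n would
yield an SE of exactly zero, contradicting the nonzero full-panel errors
observed in practice). Each draw is fitted with the pooled model — the
observer model is undefined when a draw omits or duplicates observers. The
SE is the SD over draws with the 1/(m−1) divisor. Draws spanning fewer than
two distinct diameters are redrawn and counted; more than 50 % degenerate
initial draws abort with an error. The default m = 10⁵ stabilises the SEs
to about one significant digit; the monotonicity tests use m = 10⁴ with a
2.5 % Monte-Carlo slack (the relative MC error of an SD at m = 10⁴ is
~0.7 %). Each fit reduces to additive per-curve sufficient statistics, so
all m fits are vectorised; a full k = 1…5 sweep at m = 10⁵ takes ~2 s.

## Numerical conventions

* Pixel coordinates are 0-based (row, col) with centres at integer
  positions; module-local mm axes are x right / y up, so rows flip sign.
* Display windowing maps [wc − ww/2, wc + ww/2] → [0, 255] with
  round-half-up (HU = wc → 128).
* DICOM output stores int16 with rescale slope/intercept (default 1/−1024);
  integer HU round-trip exactly, fractional HU quantise to the slope. The
  `.npz` archive path is lossless and is what simulation round-trip tests
  use.
* OLS is solved via `numpy.linalg.lstsq` (fits) and
  `scipy.stats.linregress` (verification analytics); erosion via
  `scipy.ndimage.binary_erosion`; test oracles re-derive both by brute
  force or explicit normal equations.

## Problem sizes in tests and the acceptance script

Simulated scans use 192×192 px × 3 slices (1 slice where only geometry
matters); statistical checks use 1000 noise replicates for the contrast
sampling bound, 2000 sessions for psychometric frequency checks, 120
sessions per noise level for trend recovery, and 100 random datasets for
the constraint/separability diagnostics. These sizes give Monte-Carlo
errors comfortably below the asserted tolerances (3-SE bands; binomial or
χ²-based as appropriate).

## Known limitations

* White, uncorrelated noise only; no kernel MTF, beam hardening, scatter or
  iterative-reconstruction nonlinearity.
* The iodine kV-response table is a qualitative placeholder.
* The psychometric observer is not calibrated to humans; absolute α/β from
  simulation should not be compared to human-panel values.
* The bootstrap treats repeated curves from one observer as independent
  draws, which understates within-observer correlation.
* Physical barcode reading from scans is not implemented; module identity
  comes from metadata/configuration.
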