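# Methods

This note records the models behind each estimator, the tunable parameters
and their defaults, what the synthetic generators do and do not emulate, and
the numerical choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Optical constants

`OpticsConfig` carries the instrument and physics constants shared by every
estimator: nucleosome RI n_m = 1.43, nuclear RI n_1 = 1.37, immersion-oil
RI n_i = 1.518, nucleosome dry density ρ₀ = 0.55 g/cm³, illumination
wavenumber k = 1.57×10⁵ cm⁻¹, collection/illumination numerical apertures
NA_c = 1.49 and NA_i = 0.52, the spectral grid 500–700 nm at 2 nm, the
dynamics wavelength 550 nm and frame interval 50 ms. The Fresnel intensity
coefficient Γ defaults to the oil/nucleus normal-incidence reflectance
((n_i − n_1)/(n_i + n_1))² ≈ 2.63×10⁻³ and is overridable, since the
interface it refers to is an instrument detail rather than a constant of
nature. The Gladstone–Dale relation is parameterized as
n(φ) = n_water + α·ρ₀·φ with n_water = 1.334 and the standard biomolecular
specific refractive increment α = 0.18 cm³/g; at φ = 1 this reproduces the
nucleosome RI to within 0.003, an internal-consistency check the tests
assert.

### Reflectance ↔ CVC calibration

The default calibration composes Gladstone–Dale with the Fresnel
reflectance of the chromatin-occupied medium against its aqueous surround,
giving R(φ) strictly increasing from R(0) = 0. The composed map is rational
in φ with an exact φ² factor, so it is fitted on a zero-intercept
φ²…φ⁸ polynomial basis, which keeps the relative reproduction error below
10⁻⁶ uniformly, including the φ → 0 limit. Externally fitted calibrations
(e.g. from full-wave electromagnetic simulation) can be supplied as a
monotone (φ, R) table and are interpolated piecewise-linearly. Inversion is
by dense monotone interpolation; reflectances outside the calibrated range
clip to 0 or 1 with an out-of-range flag.

## Static PWS forward model and Σ→D estimation

The medium inside one pixel column is summarized by `ChromatinMedium`:
packing scaling D, inner/outer correlation scales l_min = 10 nm and
l_max = 1000 nm, RMS RI fluctuation σ_n = 0.05, thickness 2 µm sampled at
256 axial layers, and a camera-pixel speckle factor (below).

Two views of the same 3-D statistics are used, and the distinction matters:

* `sample_ri_profile` draws a **1-D transect** of the isotropic 3-D medium.
  A line through an isotropic field inherits the field's autocorrelation,
  so the transect has B(r) ∝ (r/l_min)^(D−3), synthesized by circulant
  embedding (eigenvalues clipped at zero, variance rescaled to σ_n²
  exactly). The empirical log-log ACF slope recovers D − 3 to within the
  tested ±0.15.
* The interferometric signal, however, integrates the field laterally over
  the coherence area. For axial frequencies above the inverse coherence
  width, the averaged line inherits the **3-D spectral law** q^(−D) over
  the band [2π/l_max, 2π/l_min], with amplitude fixed by holding the 3-D
  variance integral (∝ ∫ q² · q^(−D) dq) at σ_n². This is the profile the
  phase-sum propagates. The overall scale (the lateral-averaging constant)
  is D-independent and folded into the calibration; it is normalized so the
  realized 1-D variance equals σ_n² at the reference scaling D = 2.5.

Feeding the transect directly into the phase sum would make Σ *decrease*
with D — the probed spatial frequency 2 k n_1 sits above the pivot of the
variance-normalized transect spectrum — which contradicts both the physics
of coherence-gated detection and the monotone Σ–D relationship the method
rests on. The two-view construction resolves this while keeping both
statistics exactly specified.

The spectrum itself is a 1-D Born/phase-sum approximation:
I(λ) = |√Γ + a Σ_j δn_j exp(i·2k(λ)·n_1·z_j)|², with a scalar NA-dependent
coupling a = (NA_i/NA_c)/√n_layers. A camera pixel integrates intensity
over `n_speckle` = 9 independent transverse coherence cells (an effective
pixel ≈ 3 coherence widths across, typical of a large-pixel EMCCD behind a
63× objective); this sets the realistic per-pixel noise level of Σ.

`PackingScalingEstimator.fit` samples mean Σ at 16 points of D ∈ [1.7, 3.2]
(200 single-pixel spectra each), applies isotonic regression (ties broken
toward lower D by the left-continuous interpolation convention), and stores
the seed. `predict` inverts per pixel by piecewise-linear interpolation.
Two choices depart from the most literal reading of the inversion contract,
both for unbiasedness at the calibration edges:

* Σ values outside the calibrated range extrapolate with the edge-segment
  slopes before the hard clip to [1, 3.5] (saturating at the end knots
  would one-sidedly truncate pixel noise);
* the regional mean D_n includes clipped pixels at their clipped value by
  default (excluding them biased D_n by up to −0.13 at D = 3.0);
  `include_clipped=False` restores the strict region ∩ valid-mask rule.

With these, closed-loop recovery on 64×64 cubes at 101 wavelengths is
within |D̂_n − D| ≤ 0.07 over D ∈ {1.8, 2.2, 2.6, 3.0} (the tests assert
≤ 0.1).

## Dynamic PWS

### Moving mass

FMM(x, y) = Var_t[I/I₀] / A with the package-defined pre-factor

    A = 2 ρ₀ π w² L s₁² / Γ,   s₁ = k³ NA_c α / (2π²),
    w = 0.61 λ / NA_c,         L = n_1 λ / NA_i²,

a pure function of the config (≈ 1.98×10¹⁷ g⁻¹ at defaults, so a typical
2×10⁻¹⁹ g moving mass produces a ≈ 20 % RMS intensity fluctuation). The
derivation treats each coherently moving macromolecular cluster as a
Rayleigh scatterer of excess polarizability α·m focused over a
diffraction-limited waist; summing independent clusters in the coherence
volume makes the variance exactly linear in m_c·φ_mobile. The literature
constant can be swapped in by overriding config fields — the closed loop
(generator and estimator share A) is unaffected by its absolute value.
Variance uses the raw normalized trace by default; a `detrend` option
removes the fourth-order polynomial trend first.

### Effective diffusion

Per pixel, the normalized autocorrelation of the mean-subtracted trace is
fitted with exp(−τ/τ_d) by unweighted least squares on the log, and
D_e = 1/(4 k_med² τ_d). Three numerical choices matter:

* the fit covers the *initial decay* only — contiguous positive lags within
  the first quarter of the record with C ≥ 0.2. Beyond that the
  finite-record ACF estimate is dominated by the negative mean-subtraction
  bias (≈ (1+ρ)/((1−ρ)n) uniformly over lags), which steepens the apparent
  decay by ~20 % if included;
* single-trace fits remove that bias by fixed-point iteration of the
  analytic correction; decay times beyond the record length are capped as
  unidentifiable;
* region summaries are fitted on the region-averaged ACF of
  *ensemble-detrended* traces (each frame's pixel-mean subtracted), which
  removes both the shared slow drift and the per-trace bias without any
  correction. Recovery is then within ~3 % at 300 frames.

Constant traces are flagged below-floor (NaN map value, never an
exception); estimates are clipped to the stated measurable band
3.5×10⁻⁵ – 0.065 µm²/s with flags.

### Relative CVC

The raw region trace is mean((I−I₀)/I₀). Its inversion is 1/(1+raw) = I₀/I:
strictly decreasing in intensity — preserving the inverse proportionality
between intensity and density — and finite for positive intensities,
whereas inverting the zero-crossing raw trace itself would be singular.
Min–max scaling to [0, 1] follows; a flat trace returns all-0.5 with a
flag rather than raising, since tiny quiet blebs must not abort a pipeline.
Trend fitting is ordinary least-squares polynomial (order 4), ensembles are
pointwise means ± s.e.m. of fitted trends on a common grid, and the
bleb-to-body ratio uses the *unscaled* inversion time-mean per region
(min–max scaling would destroy the level information a ratio needs);
inverting the region-mean trace rather than averaging per-pixel inverses
keeps the statistic robust to the large interference fluctuations.

## SMLM nanodomains

DBSCAN with ε = 50 nm, min_pts = 3 (self-inclusive), Euclidean metric, via
scikit-learn; the test suite holds the labels equal to an independent
O(n²) breadth-first reference on a thousand random instances, including
border-point assignment (both attach border points to the first cluster
that reaches them in ascending-index expansion). Geometry is the
scipy.spatial convex hull; "size" is the area-equivalent circular diameter
2√(area/π), with max pairwise extent as the degenerate (collinear)
fallback, flagged. The filter retains sizes in (2 × mean localization
uncertainty, 800 nm]; the lower bound is computed from the supplied table
(per-table by default) with the ~25 nm figure being descriptive, and a
fixed bound can be passed to reproduce the alternative literal reading.
Region assignment is by cluster centroid (member-majority was considered
and rejected as a default for being sensitive to single stray
localizations); centroids outside all regions land in an explicit
``outside`` bucket. Condition summaries pool domains across cells rather
than averaging per cell.

## Synthetic generators

All generators are pure functions of (spec, seed).

* **Scenes**: ellipse nuclear body (semi-axes 22×16 px at 0.15 µm/px in a
  64×64 frame), circular bleb (radius 6 px) attached through a
  rectangular neck (width 3 px), optional detached micronucleus kept
  4-disconnected by a one-pixel margin. Topology is verified on the
  finished mask — a protrusion that ends up disconnected (neck width 0) is
  relabeled as a micronucleus — so generator labels always agree with the
  connectivity-based classifier.
* **Spectral cubes**: per-pixel spectra from the static forward model at
  the region's D; background carries the flat reference spectrum.
* **Temporal cubes**: per-pixel stationary AR(1) — the exact discretization
  of an Ornstein–Uhlenbeck process, so the ACF exp(−τ/τ_d) is analytically
  known — with variance A·FMM_true and τ_d = 1/(4 k_med² D_e,true), plus a
  slow per-region fractional intensity depression (level × (1 + 0.3·ramp))
  encoding relative CVC; 300 frames at 50 ms by default; intensities
  floored at 2 % of reference for physicality.
* **Localizations**: domain centers uniform over region pixels; members
  uniform in a disk of the region's domain radius plus Gaussian
  localization noise (uncertainty ≈ N(25, 5²) nm, floored at 5). The event
  count per domain scales with area (30 events at the 50-nm reference
  radius), i.e. constant labeling density — without this, large domains
  fall below the DBSCAN density threshold and fragment artificially.
  Uniform-disk membership (rather than a Gaussian of σ = radius) keeps the
  recovered hull diameter within a factor ~2 of the nominal radius, making
  "radius" literal. Uniform background events are added; ground-truth
  membership rides along in a `truth_domain` column.

What the generators do **not** emulate: camera noise beyond the intensity
model, photophysics (blinking, repeated localizations of one fluorophore),
drift, 3-D structure, vectorial/high-NA diffraction, or cell-to-cell
biological variability beyond the per-seed geometry jitter. Passing the
closed-loop tests therefore certifies the estimators under the model's
stated assumptions — correctness of the inference machinery — not
instrument-level accuracy on real cells, whose absolute values depend on
calibrations this package cannot reproduce without the raw imaging data.

### The packaged scenario bundle

`paper_like_scenarios()` encodes the study conditions as effect
*directions* with realistic magnitudes, not cell-population values: every
condition has bleb D and FMM below the body and bleb D_e above it; the
lamin-depleted condition raises body D/FMM and has the largest bleb D and
FMM; HDAC inhibition lowers D everywhere, shrinks nanodomains most, raises
body density and suppresses the bleb-to-body CVC ratio. Bleb moving masses
sit in the observed ~1.4–2.3×10⁻¹⁹ g band and diffusions in the few-10⁻³
µm²/s range.

## Problem sizes

Defaults were chosen once for desk-scale verification: 64×64 scenes, 101
wavelengths, 300 frames, 16-point Σ–D calibration with 200 replicates.
Recovery loops in the tests and the acceptance script run at 100 seeds for
ordering/direction checks and 30–50 seeds for recovery means, on 24×24 to
64×64 scenes depending on the statistic (sizes are stated next to each
loop). The statistical battery's null calibration uses 2000 simulated
t-tests at n = 20 per group.

## Known limitations

* The Σ→D mapping is self-calibrated against the package's own forward
  model; absolute D values on real instruments require the instrument's
  own calibration chain. Monotonicity and closed-loop recovery are the
  properties the comparative conclusions rely on, and those are what the
  tests pin down.
* The FMM pre-factor's absolute scale is a scalar-model derivation;
  swapping in an externally derived constant rescales FMM values linearly
  and nothing else.
* D_e assumes a single-exponential ACF; mixtures of mobilities will be
  summarized by an effective decay rate.
* Rupture classification is accepted from upstream labels only — "no
  longer intact" is a visual criterion with no mask-level definition.
* The CVC calibration's analytic reflectance stands in for a full-wave
  electromagnetic treatment; its monotone invertibility, which is the
  property downstream code uses, holds by construction.
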