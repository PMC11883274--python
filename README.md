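# chromopws

Analysis stack for quantifying higher-order chromatin organization in
nuclear blebs versus the nuclear body, as measured by dual partial-wave
spectroscopic (PWS) microscopy and single-molecule localization microscopy
(SMLM), plus synthetic ground-truth generators so that every estimator is
verifiable end-to-end by parameter recovery.

It is written for microscopists and computational biologists who have (or
want to emulate) three kinds of data:

1. **spectral image cubes** I(x, y, λ), λ = 500–700 nm at 2-nm steps —
   static PWS;
2. **temporal image cubes** I(x, y, t) at a single wavelength (550 nm),
   50-ms frames, with a reference image I₀ — dynamic PWS;
3. **SMLM localization tables** (ThunderSTORM-style CSV of x, y,
   uncertainty, frame) of constitutive heterochromatin (H3K9me3),

together with labeled region masks separating the nuclear body from its
blebs (herniations still connected to the body) and micronuclei
(disconnected objects).

## The models

**Packing scaling D.** Within packing domains chromatin behaves as a
mass-fractal polymer, M ∝ r^D, with D between the solvated-coil limit (5/3)
and the space-filling limit (3). The refractive-index fluctuations of such
a medium have a power-law autocorrelation B(r) ∝ (r/l_min)^(D−3) over the
domain scales l_min ≤ r ≤ l_max. The standard deviation Σ of the
backscattered interference spectrum over wavelength rises monotonically
with D, so a forward model of the instrument yields a Σ(D) calibration that
can be inverted pixel-by-pixel: `PackingScalingEstimator.fit()` builds the
calibration from the package's own interference model (isotonic-regularized,
hence monotone by construction) and `predict()` maps a Σ image to the local
packing-scaling map D_a(x, y); averaging over a region mask gives the
region scalar D_n.

**Fractional moving mass and effective diffusion.** The temporal variance
of the reference-normalized intensity is proportional to the mass of
chromatin moving coherently inside a diffraction-limited volume:
FMM = Var_t[I/I₀] / A, in grams, where the pre-factor A collects the
instrument constants (ρ₀ = 0.55 g/cm³, n_m = 1.43, n_1 = 1.37,
n_i = 1.518, k = 1.57×10⁵ cm⁻¹, Γ, NA_c = 1.49, NA_i = 0.52); the same A
drives the synthetic generator, closing the loop. The decay time τ_d of the
temporal autocorrelation gives the effective diffusion coefficient
D_e = 1/(4 k_med² τ_d) with k_med = 2π n_1/λ (backscatter convention), in
µm²/s, reported inside the instrument's measurable band
(3.5×10⁻⁵ – 0.065 µm²/s).

**Relative chromatin volume concentration (CVC).** Mean intensity is
inversely proportional to local macromolecular density, so region traces
are inverted (I₀/I), min–max scaled to [0, 1], summarized by fourth-order
polynomial trends, cell ensembles ± s.e.m., and per-cell bleb-to-body
ratios. Absolute CVC can be calibrated from mean reflectance through the
Fresnel coefficient and the Gladstone–Dale relation
n(φ) = n_water + α·ρ₀·φ (`ReflectanceCvcModel`).

**Heterochromatin nanodomains.** Localizations are clustered with DBSCAN
(ε = 50 nm, min_pts = 3), sized by the convex hull (equivalent diameter
2·√(area/π)), filtered to the window (2 × mean localization uncertainty,
800 nm], and pooled per condition into body/bleb count and size
distributions.

Morphometry (bleb / micronucleus / rupture classes by mask connectivity,
per-field-of-view bleb percentages, corrected total cell fluorescence) and
the statistical battery (t / Mann–Whitney, Holm–Šídák, ANOVA + Dunnett)
round out the pipeline.

## Worked example

Generate three synthetic control cells (ellipse nucleus + connected bleb),
run every estimator, and print the tidy per-cell table:

```python
import dataclasses
from chromopws import (OpticsConfig, PackingScalingEstimator,
                       paper_like_scenarios, run_condition)

cfg = OpticsConfig()
est = PackingScalingEstimator(cfg=cfg, random_state=0).fit()

spec = dataclasses.replace(paper_like_scenarios()["control"], n_cells=3)
table = run_condition(spec, cfg=cfg, packing_estimator=est, rng_seed=42)
print(table[["cell_id", "d_n_body", "d_n_bleb", "fmm_g_body", "fmm_g_bleb",
             "de_um2_s_body", "de_um2_s_bleb", "cvc_ratio"]])
```

prints

```
    cell_id  d_n_body  d_n_bleb  fmm_g_body  fmm_g_bleb  de_um2_s_body  de_um2_s_bleb  cvc_ratio
control_000      2.58      2.31    2.92e-19    1.74e-19         0.0042        0.00497       1.03
control_001      2.57      2.24     2.9e-19    1.73e-19        0.00413        0.00497       1.03
control_002      2.56      2.33     2.9e-19    1.74e-19        0.00416        0.00511       1.03
```

The generator's ground truth for this condition is D = 2.60 (body) / 2.30
(bleb), FMM = 3.0×10⁻¹⁹ / 1.76×10⁻¹⁹ g and
D_e = 4.0×10⁻³ / 5.09×10⁻³ µm²/s: each column recovers its true value, and
the bleb shows the expected signature — lower packing scaling and moving
mass, higher mobility — while the control bleb-to-body CVC ratio sits just
above 1. The pooled nanodomain table
(`table.attrs["domains"]`) gives median equivalent diameters of ≈ 315 nm in
the body versus ≈ 135 nm in the bleb for this run, the fragmentation
signature seen by SMLM.

The same stages are scriptable from the shell:

```sh
chromopws synth --scenario control --seed 1 --out bundle/
chromopws pws-static --cube bundle/cube_spec.h5 --regions bundle/scene.tif --out damap.h5
chromopws pws-dyn --cube bundle/cube_dyn.h5 --regions bundle/scene.tif --out dyn.h5 --summary dyn.csv
chromopws smlm-domains --locs bundle/locs.csv --scene bundle/scene.tif --out domains.csv
chromopws report --scenario paper_like --seed 1 --out cells.csv
```

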